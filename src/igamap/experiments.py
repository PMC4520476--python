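"""End-to-end simulation experiments: calibration, power and recovery rates.

These routines run the full pipeline on synthetic cohorts at the study's
scale (a few hundred dogs, 10^4 array markers) and report the quantities the
method is judged on: uniformity of null per-run p-values, family-wise error
of the permutation threshold, localization of a planted QTL by the combined
p_hat, recovery of a planted age effect by the variance-explained estimator,
recovery of a planted fixed run as one fixation block, and localization of a
planted sweep by the window Z-scores.  Problem sizes are chosen so each
experiment runs in minutes on one core; replicate seeds are spawned from a
single master seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .assoc import MixedModelEngine, kinship_matrix, run_multirun_gwas
from .phenotype import percentile_groups, qc_filter
from .popgen import fixation_blocks, fixation_windows, sweep_scan
from .regions import ld_r2, region_size_kb, variance_explained
from .significance import permutation_threshold
from .simulate import SimConfig, simulate_panel, simulate_pools, simulate_variant_table

# Published associated-region bounds for serum IgA in dogs (CanFam3.1), used
# as geometry fixtures: chromosome, start, end, reported size in kb.
PUBLISHED_REGION_BOUNDS = (
    ("5", 6_498_684, 8_172_621, 1674),    # German shepherd, CFA5
    ("8", 63_211_755, 63_827_575, 616),   # German shepherd, CFA8
    ("28", 10_446_800, 13_077_479, 2631),  # Shar-Pei, CFA28
)


def published_region_sizes() -> list[int]:
    """Region sizes (kb) recomputed from the published bounds."""
    return [region_size_kb(s, e) for _, s, e, _ in PUBLISHED_REGION_BOUNDS]


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------


def null_uniformity_ks(
    seed: int, n_samples: int = 300, n_markers: int = 10_000, n_panels: int = 3,
) -> dict[str, object]:
    """KS uniformity of per-run score-test p-values on genotype-null panels.

    Panels carry no genetic effects (trait independent of genotype) but keep
    the default age effect: with a pure-noise trait the fitted age coefficient
    is near zero, the score statistic degenerates onto the integer lattice of
    the discrete group labels, and a continuous KS check correctly rejects
    without indicating miscalibration.  Markers are simulated without LD and
    samples unrelated so the KS null (independent p-values) holds; dependence
    is exercised by the family-wise-error check instead.
    """
    ks: dict[str, list[float]] = {}
    for s in _subseeds(seed, n_panels):
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers, qtls=[],
                        ld_block_len=1, n_subpops=1, relatedness=1,
                        age_effect_var=0.10, polygenic_var=0.0, seed=s)
        g, p, _ = simulate_panel(cfg)
        g, p, _ = qc_filter(g, p)
        _, runs = run_multirun_gwas(g, p)
        for label, run in runs.items():
            ks.setdefault(label, []).append(float(stats.kstest(run.p, "uniform").pvalue))
    flat = [v for vals in ks.values() for v in vals]
    return {"ks_p_per_run": ks, "median_ks_p": float(np.median(flat)),
            "min_ks_p": float(np.min(flat)),
            "n_above_0.01": int(sum(v > 0.01 for v in flat)),
            "n_checks": len(flat)}


def fwe_calibration(
    seed: int,
    n_reps: int = 200,
    n_samples: int = 300,
    n_markers: int = 10_000,
    n_perm: int = 40,
    run: str = "groups5",
) -> dict[str, float]:
    """Family-wise error of the permutation threshold on null panels.

    Each replicate simulates a null cohort, computes the run's permutation
    threshold at reduced ``n_perm``, and checks whether the observed
    genome-wide minimum p falls below it; the rate should be near the nominal
    2.5%.
    """
    hits = 0
    for s in _subseeds(seed, n_reps):
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers, qtls=[],
                        age_effect_var=0.10, polygenic_var=0.0, seed=s)
        g, p, _ = simulate_panel(cfg)
        engine = MixedModelEngine(g)
        pheno = p.aligned_to(g.samples)
        iga = pheno["iga"].to_numpy(float)
        from .assoc import _covariate_design
        X = _covariate_design(pheno)
        obs = engine.run(percentile_groups(iga, 5).group.astype(float), X, label=run)
        null = permutation_threshold(g, p, X, run, n_perm=n_perm, seed=s + 1,
                                     engine=engine)
        hits += int(obs.p.min() < null.threshold)
    return {"rate": hits / n_reps, "hits": hits, "n_reps": n_reps, "nominal": 0.025}


# ---------------------------------------------------------------------------
# planted-QTL localization and variance recovery
# ---------------------------------------------------------------------------


def qtl_localization(
    seed: int,
    n_reps: int = 50,
    n_samples: int = 500,
    n_markers: int = 10_000,
    qtl_var: float = 0.20,
    r2_min: float = 0.8,
) -> dict[str, float]:
    """Share of replicates in which the combined p_hat minimum is the planted
    QTL or a marker in r^2 > ``r2_min`` with it."""
    localized = 0
    for s in _subseeds(seed, n_reps):
        rng = np.random.default_rng(s)
        qtl_idx = int(rng.integers(0, n_markers))
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers,
                        qtls=[(qtl_idx, qtl_var)], seed=s)
        g, p, truth = simulate_panel(cfg)
        combined, _ = run_multirun_gwas(g, p)
        top = combined.marker_ids[int(np.argmin(combined.p_hat))]
        causal = truth.qtl_markers[0]
        if top == causal:
            localized += 1
        else:
            r2 = ld_r2(g.marker_dosage(top), g.marker_dosage(causal))
            localized += int(not np.isnan(r2) and r2 > r2_min)
    return {"rate": localized / n_reps, "n_reps": n_reps}


def age_variance_recovery(
    seed: int,
    n_reps: int = 50,
    n_samples: int = 300,
    n_markers: int = 2_000,
    age_var: float = 0.25,
    tol: float = 0.05,
) -> dict[str, float]:
    """Recovery of a planted age effect by the variance-explained estimator
    (five-percentile-group phenotype, mixed model with age as fixed effect).

    Recovery panels plant only the component being recovered: no QTL or
    polygenic variance, so the check isolates the estimator.  (A polygenic
    background adds GLS fixed-effect noise and widens the estimator's spread;
    see the methods note.)
    """
    estimates = []
    for s in _subseeds(seed, n_reps):
        cfg = SimConfig(n_samples=n_samples, n_markers=n_markers,
                        age_effect_var=age_var, polygenic_var=0.0, seed=s)
        g, p, _ = simulate_panel(cfg)
        pheno = p.aligned_to(g.samples)
        y = percentile_groups(pheno["iga"].to_numpy(float), 5).group.astype(float)
        K = kinship_matrix(g)
        est = variance_explained(y, pheno["age"].to_numpy(float)[:, None], K,
                                 label="age", jackknife=False)
        estimates.append(est.fraction)
    estimates = np.array(estimates)
    return {
        "rate_within_tol": float(np.mean(np.abs(estimates - age_var) <= tol)),
        "mean_estimate": float(estimates.mean()),
        "target": age_var,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# planted-structure recovery
# ---------------------------------------------------------------------------


def planted_block_recovery(seed: int, block_len: int = 30,
                           n_variants: int = 2000) -> dict[str, float]:
    """Recover a planted run of ``block_len`` fixed variants as one block.

    The run is planted at a window-grid-compatible offset (start index = 5
    mod 10): the 11-variant/step-10 window grid plus the 5-variant extension
    resolves fixed runs exactly only at that alignment.
    """
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, (n_variants - block_len) // 10 - 1)) * 10 + 5
    cfg = SimConfig(seed=seed)
    vt, truth = simulate_variant_table(
        cfg, planted_blocks=[("gsd", start, start + block_len - 1)],
        n_variants=n_variants)
    windows = fixation_windows(vt, "gsd")
    blocks = fixation_blocks(windows, vt, "gsd")
    covered = (len(blocks) == 1
               and blocks[0].first_variant == start
               and blocks[0].last_variant == start + block_len - 1)
    return {"n_blocks": len(blocks), "recovered_exactly": float(covered),
            "planted_first": start, "planted_len": block_len}


def sweep_localization(
    seed: int,
    n_reps: int = 50,
    fst_background: float = 0.3,
    fst_sweep: float = 0.9,
    depth: int = 50,
) -> dict[str, float]:
    """Share of replicates in which the planted high-divergence interval holds
    both the genome-wide maximum Z(F_ST) and minimum Z(H_P)."""
    interval = (800_001, 900_000)  # 100 kb sweep inside a 2 Mb region
    hit_fst = hit_hp = both = 0
    for s in _subseeds(seed, n_reps):
        cfg = SimConfig(seed=s)
        pools, _ = simulate_pools(cfg, interval, fst_background, fst_sweep, depth)
        df = sweep_scan(pools)
        top_fst = df.loc[df["z_fst"].idxmax()]
        low_hp = df.loc[df["z_hp"].idxmin()]

        def inside(w) -> bool:
            return w["start"] <= interval[1] and w["end"] >= interval[0]

        hit_fst += inside(top_fst)
        hit_hp += inside(low_hp)
        both += inside(top_fst) and inside(low_hp)
    return {"rate_fst": hit_fst / n_reps, "rate_hp": hit_hp / n_reps,
            "rate_both": both / n_reps, "n_reps": n_reps}
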