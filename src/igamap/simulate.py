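"""Synthetic genotype/phenotype panels with the structure the pipeline assumes.

The generator emulates a single-breed SNP-array cohort: block LD from mosaic
copying of founder haplotypes, subpopulation allele-frequency divergence
(Balding-Nichols), cryptic relatedness through full-sib families, and a
right-skewed serum-IgA-like trait (0 to ``iga_scale`` g/l) built from planted
additive QTLs, an age effect, a polygenic term and noise on a Gaussian
liability scale.

Planted effect components are rescaled so that their *realized in-sample*
variance fraction equals the configured fraction exactly (the convention used
by GCTA-style trait simulators); parameter-recovery tests then measure
estimator error rather than the simulator's own sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MarkerMap, PhenotypeTable, PoolCountTable, VariantFrequencyTable


@dataclass
class SimConfig:
    """Study conditions for one simulated breed cohort.

    Defaults mirror a mid-sized array cohort: a few hundred dogs, 10^4 SNPs
    with haplotype-block LD, two cryptic subpopulations at modest divergence,
    full-sib families of four, a moderate polygenic background and an age
    effect inside the range reported across breeds (4-25%).
    """

    n_samples: int = 300
    n_markers: int = 10_000
    n_chrom: int = 10
    ld_block_len: int = 20          # markers per founder haplotype block
    n_founder_haplotypes: int = 30
    n_block_haplotypes: int = 4     # distinct prototype haplotypes per LD block
    n_subpops: int = 2
    subpop_fst: float = 0.05
    relatedness: int = 4            # full-sib family size; 1 = unrelated
    qtls: list[tuple[int, float]] = field(default_factory=list)  # (marker index, var fraction)
    age_effect_var: float = 0.10
    polygenic_var: float = 0.25
    iga_scale: float = 1.4          # g/l; trait spans ~0..iga_scale
    marker_spacing_bp: int = 25_000
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_samples, self.n_markers, self.n_chrom, self.ld_block_len,
            self.n_founder_haplotypes, self.n_subpops, self.relatedness,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts in SimConfig must be positive")
        if not 0 <= self.subpop_fst < 1:
            raise ValueError("subpop_fst must be in [0,1)")
        budget = sum(v for _, v in self.qtls) + self.age_effect_var + self.polygenic_var
        if budget >= 1:
            raise ValueError(f"variance budget {budget:.3f} >= 1")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    qtl_markers: list[str]
    qtl_variances: list[float]
    breeding_values: np.ndarray
    family_of_sample: np.ndarray
    subpop_of_sample: np.ndarray
    liability: np.ndarray
    fixed_block_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    sweep_interval: tuple[str, int, int] | None = None


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("component with zero variance")
    return (v - v.mean()) / sd


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Project out previously planted components, then re-standardize."""
    for b in basis:
        v = v - b * (b @ v) / len(v)
    return _standardize(v)


def _mosaic_haplotype(
    founders: np.ndarray, n_blocks: int, block_len: int, n_markers: int, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype copied block-wise from a founder pool (block LD)."""
    pick = rng.integers(0, founders.shape[0], size=n_blocks)
    per_marker = np.repeat(pick, block_len)[:n_markers]
    return founders[per_marker, np.arange(n_markers)]


def _recombine(h1: np.ndarray, h2: np.ndarray, n_blocks: int, block_len: int,
               rng: np.random.Generator) -> np.ndarray:
    """Child haplotype from a parent: block-wise choice between the two."""
    pick = np.repeat(rng.integers(0, 2, size=n_blocks), block_len)[:len(h1)]
    return np.where(pick == 0, h1, h2).astype(np.int8)


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Simulate one breed cohort; identical seed gives bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_markers
    n_blocks = -(-m // config.ld_block_len)

    # marker map: chromosomes of equal marker count, evenly spaced positions
    per_chrom = -(-m // config.n_chrom)
    chroms, positions = [], []
    for j in range(m):
        c = j // per_chrom
        chroms.append(str(c + 1))
        positions.append((j - c * per_chrom + 1) * config.marker_spacing_bp)
    raw_ids = [f"snp{j:06d}" for j in range(m)]
    markers = MarkerMap(pd.DataFrame({
        "marker_id": raw_ids,
        "chrom": chroms,
        "pos": positions,
        "allele_a": "A",
        "allele_b": "G",
    }))
    # MarkerMap sorts by (chrom, pos); realign generated columns to map order
    raw_pos = {mid: j for j, mid in enumerate(raw_ids)}
    col_order = np.fromiter((raw_pos[mid] for mid in markers.marker_ids),
                            dtype=int, count=m)

    # subpopulation allele frequencies: Balding-Nichols around an ancestral p
    p_anc = rng.uniform(0.10, 0.90, size=m)
    fst = config.subpop_fst
    sub_freqs = []
    for _ in range(config.n_subpops):
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            sub_freqs.append(rng.beta(a, b))
        else:
            sub_freqs.append(p_anc.copy())

    # founder haplotype pools per subpopulation: each block carries only a few
    # distinct prototype sequences, so markers within a block are in strong LD
    # while blocks are independent
    founder_pools = []
    for f in sub_freqs:
        protos = (rng.random((config.n_block_haplotypes, m)) < f).astype(np.int8)
        # array-style ascertainment: markers are chosen to be polymorphic, so
        # redraw prototype columns that came out monomorphic
        for _ in range(12):
            mono = protos.min(axis=0) == protos.max(axis=0)
            if not mono.any():
                break
            protos[:, mono] = (
                rng.random((config.n_block_haplotypes, int(mono.sum()))) < f[mono]
            ).astype(np.int8)
        assign = rng.integers(0, config.n_block_haplotypes,
                              size=(config.n_founder_haplotypes, n_blocks))
        per_marker = np.repeat(assign, config.ld_block_len, axis=1)[:, :m]
        founder_pools.append(protos[per_marker, np.arange(m)[None, :]])

    # families: sib-groups of size `relatedness`, each within one subpopulation
    fam_size = max(1, config.relatedness)
    n_fam = -(-n // fam_size)
    family_of_sample = np.repeat(np.arange(n_fam), fam_size)[:n]
    subpop_of_fam = np.arange(n_fam) % config.n_subpops
    subpop_of_sample = subpop_of_fam[family_of_sample]

    haps = np.empty((n, 2, m), dtype=np.int8)
    i = 0
    for fam in range(n_fam):
        pool = founder_pools[subpop_of_fam[fam]]
        size = min(fam_size, n - i)
        if fam_size == 1:
            haps[i, 0] = _mosaic_haplotype(pool, n_blocks, config.ld_block_len, m, rng)
            haps[i, 1] = _mosaic_haplotype(pool, n_blocks, config.ld_block_len, m, rng)
        else:
            mom = [_mosaic_haplotype(pool, n_blocks, config.ld_block_len, m, rng) for _ in range(2)]
            dad = [_mosaic_haplotype(pool, n_blocks, config.ld_block_len, m, rng) for _ in range(2)]
            for k in range(size):
                haps[i + k, 0] = _recombine(mom[0], mom[1], n_blocks, config.ld_block_len, rng)
                haps[i + k, 1] = _recombine(dad[0], dad[1], n_blocks, config.ld_block_len, rng)
        i += size

    dosage = haps.sum(axis=1).astype(float)[:, col_order]
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    samples = [f"dog{i:04d}" for i in range(n)]
    g = GenotypeMatrix(samples, markers, dosage)

    # ---- phenotype ---------------------------------------------------------
    age = rng.uniform(1.0, 12.0, size=n)
    sex = rng.choice(["F", "M"], size=n)

    components: list[np.ndarray] = []
    weights: list[float] = []
    genetic: list[bool] = []
    qtl_markers, qtl_vars = [], []
    complete = np.nan_to_num(dosage, nan=0.0)
    for idx, vfrac in config.qtls:
        comp = _orthogonalize(complete[:, idx].astype(float), components)
        components.append(comp)
        weights.append(vfrac)
        genetic.append(True)
        qtl_markers.append(markers.marker_ids[idx])
        qtl_vars.append(vfrac)

    if config.polygenic_var > 0:
        u = rng.standard_normal(m) / np.sqrt(m)
        components.append(_orthogonalize(complete @ u, components))
        weights.append(config.polygenic_var)
        genetic.append(True)
    if config.age_effect_var > 0:
        components.append(_orthogonalize(age.astype(float), components))
        weights.append(config.age_effect_var)
        genetic.append(False)

    components.append(_orthogonalize(rng.standard_normal(n), components))
    weights.append(1.0 - sum(weights))
    genetic.append(False)

    liability = sum(np.sqrt(w) * c for w, c in zip(weights, components))
    breeding = np.zeros(n)
    for w, c, is_gen in zip(weights, components, genetic):
        if is_gen:
            breeding = breeding + np.sqrt(w) * c

    # right-skewed non-negative scale, monotone in liability
    iga = config.iga_scale * np.minimum(np.exp(0.8 * liability) / np.exp(2.4), 1.0)

    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": samples,
        "iga": iga,
        "age": age,
        "sex": sex,
        "subpop": [f"sub{s}" for s in subpop_of_sample],
    }))
    truth = SimTruth(
        qtl_markers=qtl_markers,
        qtl_variances=qtl_vars,
        breeding_values=np.asarray(breeding, float),
        family_of_sample=family_of_sample,
        subpop_of_sample=subpop_of_sample,
        liability=liability,
    )
    return g, pheno, truth


# ---------------------------------------------------------------------------
# per-breed variant frequency tables with planted fixed runs
# ---------------------------------------------------------------------------


def simulate_variant_table(
    config: SimConfig,
    planted_blocks: Sequence[tuple[str, int, int]] = (),
    n_variants: int = 2000,
    breeds: Sequence[str] = ("gsd", "lr"),
    chrom: str = "28",
    region_start: int = 9_000_001,
    region_end: int = 12_000_000,
) -> tuple[VariantFrequencyTable, SimTruth]:
    """Variant frequencies over one region; ``planted_blocks`` are
    (breed, first variant index, last variant index) runs in which every
    variant is fixed (frequency exactly 0 or 1) in that breed.

    Background frequencies are drawn from a U-shaped Beta(0.5, 0.5) kept
    strictly inside (0, 1) so that only planted runs are fixed.
    """
    config.validate()
    spans = sorted((b[1], b[2]) for b in planted_blocks)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("overlapping planted blocks")
    for _, s, e in planted_blocks:
        if not (0 <= s <= e < n_variants):
            raise ValueError("planted block outside simulated coordinates")

    rng = np.random.default_rng(config.seed)
    pos = np.sort(rng.choice(np.arange(region_start, region_end), size=n_variants, replace=False))
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "ref": rng.choice(list("ACGT"), size=n_variants),
        "alt": "X",
    })
    df["alt"] = [a if a != r else "T" if r != "T" else "C"
                 for a, r in zip(rng.choice(list("ACGT"), size=n_variants), df["ref"])]
    for b in breeds:
        f = rng.beta(0.5, 0.5, size=n_variants)
        f = np.clip(f, 1e-3, 1 - 1e-3)  # background never exactly fixed
        df[f"freq_{b}"] = f
        df[f"n_{b}"] = 20
    intervals = []
    for breed, s, e in planted_blocks:
        fixed_vals = rng.choice([0.0, 1.0], size=e - s + 1)
        df.loc[s:e, f"freq_{breed}"] = fixed_vals
        intervals.append((chrom, int(pos[s]), int(pos[e])))
    truth = SimTruth([], [], np.zeros(0), np.zeros(0, int), np.zeros(0, int), np.zeros(0),
                     fixed_block_intervals=intervals)
    return VariantFrequencyTable(df, list(breeds)), truth


# ---------------------------------------------------------------------------
# pooled read counts with a planted sweep
# ---------------------------------------------------------------------------


def simulate_pools(
    config: SimConfig,
    sweep_interval: tuple[int, int],
    fst_background: float,
    fst_sweep: float,
    depth: int,
    n_sites: int = 4000,
    chrom: str = "28",
    region_bp: int = 2_000_000,
    pools: tuple[str, str] = ("wolf", "dog"),
) -> tuple[PoolCountTable, SimTruth]:
    """Two-population pooled read counts under a Balding-Nichols divergence
    model: background differentiation ``fst_background`` everywhere, elevated
    to ``fst_sweep`` inside ``sweep_interval`` (bp, 1-based inclusive)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not (0 <= fst_background < fst_sweep <= 1):
        raise ValueError("require 0 <= fst_background < fst_sweep <= 1")
    rng = np.random.default_rng(config.seed)
    pos = np.sort(rng.choice(np.arange(1, region_bp + 1), size=n_sites, replace=False))
    in_sweep = (pos >= sweep_interval[0]) & (pos <= sweep_interval[1])
    p_anc = rng.uniform(0.10, 0.90, size=n_sites)
    fst_site = np.where(in_sweep, fst_sweep, fst_background)

    def draw_pop_freq() -> np.ndarray:
        f = np.empty(n_sites)
        degenerate = fst_site >= 1 - 1e-9
        safe = ~degenerate
        if safe.any():
            fs = np.maximum(fst_site[safe], 1e-12)
            drawn = rng.beta(p_anc[safe] * (1 - fs) / fs, (1 - p_anc[safe]) * (1 - fs) / fs)
            no_drift = fst_site[safe] == 0
            drawn[no_drift] = p_anc[safe][no_drift]
            f[safe] = drawn
        if degenerate.any():
            f[degenerate] = (rng.random(int(degenerate.sum())) < p_anc[degenerate]).astype(float)
        return f

    df = pd.DataFrame({
        "chrom": chrom,
        "pos": pos,
        "ref_allele": "A",
        "alt_allele": "G",
    })
    for pool in pools:
        freq = draw_pop_freq()
        alt = rng.binomial(depth, freq)
        df[f"{pool}_ref"] = depth - alt
        df[f"{pool}_alt"] = alt
    truth = SimTruth([], [], np.zeros(0), np.zeros(0, int), np.zeros(0, int), np.zeros(0),
                     sweep_interval=(chrom, int(sweep_interval[0]), int(sweep_interval[1])))
    return PoolCountTable(df, list(pools)), truth
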