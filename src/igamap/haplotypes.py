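"""EM phasing of short SNP windows and diplotype-group trait tests.

Haplotype frequencies over a window of <= 25 markers are estimated by an EM
algorithm over the unphased genotypes (random restarts from a seeded stream),
and each sample receives its most probable diplotype with a posterior.  Trait
differences between diplotype groups use the Welch two-sample t-test on the
five-percentile-group labels, as in the source analysis design.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, logger

MAX_WINDOW = 25
MAX_CONFIGS = 4096  # cap on per-sample phase configurations enumerated


@dataclass
class HaplotypeSet:
    """Distinct haplotypes over a window, sorted by descending count."""

    marker_ids: np.ndarray
    haplotypes: list[tuple[int, ...]]     # allele sequences (0 = A, 1 = B)
    frequencies: np.ndarray               # EM estimates, sum to 1
    counts: np.ndarray                    # hard-assigned, sum to 2 * n phased
    rare_max_count: int

    def labels(self) -> list[str]:
        return ["rare" if c <= self.rare_max_count else "common" for c in self.counts]


@dataclass
class DiplotypeAssignment:
    sample_id: str
    pair: tuple[int, int]      # indices into HaplotypeSet.haplotypes, sorted
    posterior: float


def _compatible_pairs(genotype: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with one sample's genotypes
    (missing sites free on both haplotypes)."""
    het = [j for j, d in enumerate(genotype) if d == 1]
    missing = [j for j, d in enumerate(genotype) if np.isnan(d)]
    base = np.where(np.nan_to_num(genotype, nan=0.0) == 2, 1, 0).astype(int)
    n_configs = (2 ** max(len(het) - 1, 0)) * (4 ** len(missing))
    if n_configs > MAX_CONFIGS:
        raise OverflowError("too many phase configurations")
    pairs = set()
    het_iter = itertools.product((0, 1), repeat=len(het)) if het else [()]
    miss_iter = itertools.product((0, 1, 2, 3), repeat=len(missing)) if missing else [()]
    for hc in het_iter:
        for mc in miss_iter:
            h1, h2 = base.copy(), base.copy()
            for j in het:
                h1[j] = 1
                h2[j] = 0
            for j, bit in zip(het, hc):
                h1[j], h2[j] = (1, 0) if bit == 0 else (0, 1)
            for j, code in zip(missing, mc):
                h1[j], h2[j] = code >> 1, code & 1
            key = tuple(sorted((tuple(h1.tolist()), tuple(h2.tolist()))))
            pairs.add(key)
    return sorted(pairs)


def phase_em(
    g_window: GenotypeMatrix,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-10,
    rare_max_count: int = 3,
    max_missing_frac: float = 0.2,
) -> tuple[HaplotypeSet, list[DiplotypeAssignment]]:
    """EM haplotype-frequency estimation with posterior diplotype assignment.

    Deterministic for a given seed: restarts draw perturbed initial
    frequencies from a seeded stream and the best final likelihood wins.
    Samples with more than ``max_missing_frac`` missing genotypes in the
    window (or a combinatorial phase explosion) are excluded with a warning.
    """
    m = g_window.n_markers
    if m > MAX_WINDOW:
        raise ValueError(
            f"window of {m} markers exceeds {MAX_WINDOW}; split it into smaller windows")
    rng = np.random.default_rng(seed)

    sample_pairs: list[list] = []
    phased_samples: list[str] = []
    excluded = 0
    for i, sid in enumerate(g_window.samples):
        geno = g_window.dosage[i]
        if np.isnan(geno).mean() > max_missing_frac:
            excluded += 1
            continue
        try:
            pairs = _compatible_pairs(geno)
        except OverflowError:
            excluded += 1
            continue
        sample_pairs.append(pairs)
        phased_samples.append(sid)
    if excluded:
        warnings.warn(f"{excluded} samples excluded from phasing "
                      "(missingness or phase-configuration cap)")
    if not sample_pairs:
        raise ValueError("no samples available for phasing")

    haplotypes = sorted({h for pairs in sample_pairs for pair in pairs for h in pair})
    hap_index = {h: k for k, h in enumerate(haplotypes)}
    H = len(haplotypes)
    # per sample: arrays of pair indices and het multiplicity (2 if h1 != h2)
    pair_idx = [
        np.array([[hap_index[a], hap_index[b]] for a, b in pairs]) for pairs in sample_pairs
    ]
    mult = [np.where(pi[:, 0] != pi[:, 1], 2.0, 1.0) for pi in pair_idx]

    def em(freq0: np.ndarray) -> tuple[np.ndarray, float]:
        f = freq0.copy()
        ll_prev = -np.inf
        for _ in range(max_iter):
            counts = np.zeros(H)
            ll = 0.0
            for pi, mu in zip(pair_idx, mult):
                lik = mu * f[pi[:, 0]] * f[pi[:, 1]]
                tot = lik.sum()
                if tot <= 0:
                    lik = mu / len(mu)
                    tot = lik.sum()
                post = lik / tot
                ll += np.log(tot)
                np.add.at(counts, pi[:, 0], post)
                np.add.at(counts, pi[:, 1], post)
            f = counts / counts.sum()
            if ll - ll_prev < tol:
                break
            ll_prev = ll
        return f, ll

    best_f, best_ll = None, -np.inf
    for r in range(max(1, n_restarts)):
        if r == 0:
            f0 = np.full(H, 1.0 / H)
        else:
            f0 = rng.dirichlet(np.ones(H))
        f, ll = em(f0)
        if ll > best_ll:
            best_f, best_ll = f, ll
    f = best_f

    assignments: list[DiplotypeAssignment] = []
    hard_counts = np.zeros(H)
    for sid, pi, mu in zip(phased_samples, pair_idx, mult):
        lik = mu * f[pi[:, 0]] * f[pi[:, 1]]
        tot = lik.sum()
        post = lik / tot if tot > 0 else np.full(len(mu), 1 / len(mu))
        best = int(np.argmax(post))
        pair = tuple(sorted(pi[best].tolist()))
        assignments.append(DiplotypeAssignment(sid, pair, float(post[best])))
        hard_counts[pair[0]] += 1
        hard_counts[pair[1]] += 1

    order = np.argsort(-hard_counts, kind="stable")
    rank_of = np.empty(H, dtype=int)
    rank_of[order] = np.arange(H)
    hs = HaplotypeSet(
        marker_ids=g_window.markers.marker_ids.copy(),
        haplotypes=[haplotypes[k] for k in order],
        frequencies=f[order],
        counts=hard_counts[order].astype(int),
        rare_max_count=rare_max_count,
    )
    assignments = [
        DiplotypeAssignment(a.sample_id,
                            tuple(sorted((int(rank_of[a.pair[0]]), int(rank_of[a.pair[1]])))),
                            a.posterior)
        for a in assignments
    ]
    logger.info("phased %d samples into %d haplotypes (best loglik %.4f)",
                len(assignments), H, best_ll)
    return hs, assignments


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t with Satterthwaite df; returns (t, df, two-sided p)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def diplotype_group_test(
    assignments: list[DiplotypeAssignment],
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    trait: dict[str, float] | pd.Series,
    min_posterior: float = 0.9,
) -> tuple[float, float, float]:
    """Welch t-test of five-percentile-group labels between two diplotypes.

    ``trait`` maps sample id to its five-group label.  Samples whose best
    diplotype posterior is below ``min_posterior`` are excluded (logged).
    """
    trait = dict(trait) if not isinstance(trait, dict) else trait
    ga, gb = tuple(sorted(group_a)), tuple(sorted(group_b))
    dropped = sum(1 for x in assignments if x.posterior < min_posterior)
    if dropped:
        logger.info("%d samples below posterior %.2f excluded from group test",
                    dropped, min_posterior)
    va = [trait[x.sample_id] for x in assignments
          if x.pair == ga and x.posterior >= min_posterior and x.sample_id in trait]
    vb = [trait[x.sample_id] for x in assignments
          if x.pair == gb and x.posterior >= min_posterior and x.sample_id in trait]
    return welch_t_test(np.array(va), np.array(vb))
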