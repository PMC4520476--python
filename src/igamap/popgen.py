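"""Fixation-window/block detection and pooled-read F_ST / H_P sweep scans.

Within-breed fixation is scored in sliding windows of 11 variants advancing so
that consecutive windows share exactly one variant; windows where every
variant is fixed (frequency exactly 0 or 1 by default) merge into blocks,
extended by up to five additional consecutive fixed variants per side.

Between-population differentiation uses the Weir-Cockerham (1984) two-sample
theta estimated from pooled read counts (reads as haploid samples, so the
heterozygosity terms vanish); per-SNP values are averaged in 50 kb windows
sliding 25 kb, kept only with >= 10 segregating sites, and Z-transformed, as
is the pooled dog heterozygosity H_P = 2*Sum(nMAJ)*Sum(nMIN)/(Sum(nMAJ)+Sum(nMIN))^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PoolCountTable, VariantFrequencyTable, logger


# ---------------------------------------------------------------------------
# within-breed fixation
# ---------------------------------------------------------------------------


@dataclass
class FixationWindow:
    index: int
    first_variant: int      # row index into the variant table
    last_variant: int
    first_pos: int
    last_pos: int
    n_variants: int
    proportion_fixed: float


@dataclass
class FixationBlock:
    chrom: str
    start: int
    end: int
    first_variant: int
    last_variant: int
    n_variants: int
    window_indices: list[int]


def _is_fixed(freq: np.ndarray, rule: str) -> np.ndarray:
    if rule == "exact":
        return (freq == 0.0) | (freq == 1.0)
    if rule == "relaxed":
        return (freq <= 0.05) | (freq >= 0.95)
    raise ValueError(f"unknown fixation rule {rule!r}")


def fixation_windows(
    vtable: VariantFrequencyTable,
    breed: str,
    window_size: int = 11,
    overlap: int = 1,
    fixed_def: str = "exact",
) -> list[FixationWindow]:
    """Proportion of fixed variants in sliding windows of ``window_size``
    variants, consecutive windows sharing ``overlap`` variants."""
    if window_size % 2 == 0:
        raise ValueError("window_size must be odd (one centred variant)")
    freq = vtable.frequencies(breed)
    pos = vtable.table["pos"].to_numpy()
    n = len(freq)
    if n < window_size:
        logger.warning("only %d variants: fewer than one window", n)
        return []
    fixed = _is_fixed(freq, fixed_def)
    step = window_size - overlap
    windows = []
    for w, start in enumerate(range(0, n - window_size + 1, step)):
        stop = start + window_size
        windows.append(FixationWindow(
            index=w,
            first_variant=start,
            last_variant=stop - 1,
            first_pos=int(pos[start]),
            last_pos=int(pos[stop - 1]),
            n_variants=window_size,
            proportion_fixed=float(fixed[start:stop].mean()),
        ))
    return windows


def fixation_blocks(
    windows: list[FixationWindow],
    vtable: VariantFrequencyTable,
    breed: str,
    fixed_def: str = "exact",
    extend: int = 5,
) -> list[FixationBlock]:
    """Merge maximal runs of fully fixed windows; extend each side by up to
    ``extend`` additional consecutive fixed variants.  Block coordinates are
    the outermost member-variant positions."""
    freq = vtable.frequencies(breed)
    pos = vtable.table["pos"].to_numpy()
    chrom = vtable.table["chrom"].to_numpy()
    fixed = _is_fixed(freq, fixed_def)

    full = [w for w in windows if w.proportion_fixed == 1.0]
    blocks: list[FixationBlock] = []
    run: list[FixationWindow] = []
    for w in full:
        if run and w.index == run[-1].index + 1:
            run.append(w)
        else:
            if run:
                blocks.append(_close_block(run, fixed, pos, chrom, extend))
            run = [w]
    if run:
        blocks.append(_close_block(run, fixed, pos, chrom, extend))
    return blocks


def _close_block(run, fixed, pos, chrom, extend) -> FixationBlock:
    first = run[0].first_variant
    last = run[-1].last_variant
    for _ in range(extend):
        if first - 1 >= 0 and fixed[first - 1]:
            first -= 1
        else:
            break
    for _ in range(extend):
        if last + 1 < len(fixed) and fixed[last + 1]:
            last += 1
        else:
            break
    return FixationBlock(
        chrom=str(chrom[first]),
        start=int(pos[first]),
        end=int(pos[last]),
        first_variant=first,
        last_variant=last,
        n_variants=last - first + 1,
        window_indices=[w.index for w in run],
    )


# ---------------------------------------------------------------------------
# pooled frequencies and Weir-Cockerham theta
# ---------------------------------------------------------------------------


def pooled_frequencies(pools: PoolCountTable) -> pd.DataFrame:
    """Per-site, per-pool alt-allele frequency and effective read count;
    sites with zero depth in any pool are flagged unusable, not dropped."""
    out = pools.table[["chrom", "pos"]].copy()
    usable = np.ones(len(out), dtype=bool)
    for p in pools.pools:
        ref, alt = pools.counts(p)
        depth = ref + alt
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"{p}_freq"] = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
        out[f"{p}_depth"] = depth
        usable &= depth > 0
    out["usable"] = usable
    return out


def wc_fst(p1: float, n1: float, p2: float, n2: float) -> float:
    """Two-population Weir-Cockerham theta from allele frequencies and
    (read-count) sample sizes; ``nan`` when the site is monomorphic overall
    or either sample size is zero.  May be slightly negative."""
    if n1 <= 0 or n2 <= 0:
        return float("nan")
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    if pbar <= 0.0 or pbar >= 1.0:
        return float("nan")
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    # haploid read samples: average heterozygosity term is zero
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    denom = a + b
    if denom == 0:
        return float("nan")
    return float(a / denom)


def wc_fst_sites(freq1, n1, freq2, n2) -> np.ndarray:
    """Vectorized :func:`wc_fst` over site arrays."""
    freq1 = np.asarray(freq1, float)
    freq2 = np.asarray(freq2, float)
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pbar = (n1 * freq1 + n2 * freq2) / (n1 + n2)
        nbar = (n1 + n2) / 2
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))
        s2 = (n1 * (freq1 - pbar) ** 2 + n2 * (freq2 - pbar) ** 2) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2)
        theta = a / (a + b)
    bad = (n1 <= 0) | (n2 <= 0) | (pbar <= 0) | (pbar >= 1) | ((a + b) == 0)
    theta = np.where(bad, np.nan, theta)
    return theta


# ---------------------------------------------------------------------------
# sweep scan
# ---------------------------------------------------------------------------


@dataclass
class SweepWindow:
    chrom: str
    start: int
    end: int
    n_segregating: int
    mean_fst: float
    h_p: float
    z_fst: float = float("nan")
    z_hp: float = float("nan")


def sweep_scan(
    pools: PoolCountTable,
    pop_a: str = "wolf",
    pop_b: str = "dog",
    window_bp: int = 50_000,
    step_bp: int = 25_000,
    min_segregating: int = 10,
) -> pd.DataFrame:
    """Windowed F_ST between two pooled populations and pooled heterozygosity
    of ``pop_b``, Z-transformed over all emitted windows.

    Windows are anchored at position 1 of each chromosome (1, 25,001, ...).
    A site contributes when both pools have nonzero depth and the combined
    counts are polymorphic; windows with fewer than ``min_segregating`` such
    sites are dropped.  Raises unless at least 2 windows are emitted.
    """
    t = pools.table
    ref_a, alt_a = pools.counts(pop_a)
    ref_b, alt_b = pools.counts(pop_b)
    na, nb = ref_a + alt_a, ref_b + alt_b
    covered = (na > 0) & (nb > 0)
    seg = covered & ((alt_a + alt_b) > 0) & ((ref_a + ref_b) > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.where(na > 0, alt_a / np.maximum(na, 1), np.nan)
        fb = np.where(nb > 0, alt_b / np.maximum(nb, 1), np.nan)
    fst = wc_fst_sites(fa, na, fb, nb)
    maj_b = np.maximum(ref_b, alt_b)
    min_b = np.minimum(ref_b, alt_b)

    rows: list[SweepWindow] = []
    pos = t["pos"].to_numpy()
    for chrom in pd.unique(t["chrom"]):
        on_c = t["chrom"].to_numpy() == chrom
        cpos = pos[on_c]
        if len(cpos) == 0:
            continue
        last = int(cpos.max())
        start = 1
        while start <= last:
            end = start + window_bp - 1
            in_w = on_c & (pos >= start) & (pos <= end)
            use = in_w & seg & ~np.isnan(fst)
            n_seg = int((in_w & seg).sum())
            if n_seg >= min_segregating and use.any():
                smaj, smin = maj_b[in_w & covered].sum(), min_b[in_w & covered].sum()
                tot = smaj + smin
                hp = 2 * smaj * smin / tot**2 if tot > 0 else np.nan
                rows.append(SweepWindow(str(chrom), start, end, n_seg,
                                        float(np.nanmean(fst[use])), float(hp)))
            start += step_bp

    if len(rows) < 2:
        raise ValueError("fewer than 2 emitted windows; cannot Z-transform")
    df = pd.DataFrame([r.__dict__ for r in rows])
    for col, zcol in (("mean_fst", "z_fst"), ("h_p", "z_hp")):
        v = df[col].to_numpy()
        sd = v.std()
        df[zcol] = (v - v.mean()) / sd if sd > 0 else 0.0
    logger.info("sweep scan: %d windows emitted", len(df))
    return df


def extreme_sweep_windows(df: pd.DataFrame, z_fst_min: float = 4.0,
                          z_hp_max: float = -2.6) -> pd.DataFrame:
    """Candidate sweep windows: Z(F_ST) above and/or Z(H_P) below cutoffs."""
    return df[(df["z_fst"] > z_fst_min) | (df["z_hp"] < z_hp_max)].copy()
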