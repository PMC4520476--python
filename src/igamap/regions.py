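"""Associated-region definition, variance explained, cross-breed fixation.

Regions are built greedily: the best remaining suggestive hit seeds a region,
every marker within 1 Mb whose dosage correlation r^2 with the seed exceeds
0.8 joins it, the span is padded by 50 kb flanks, and member hits are consumed.
Variance explained compares the phenotypic variance of the five-percentile
group labels with the residual variance of the polygenic mixed model after
including the fixed effects of interest (age, top-SNP dosages); the error is
a leave-one-out jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import KinshipMatrix, polygenic_fit
from .io import GenotypeMatrix, MarkerMap, logger


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    samples; ``nan`` (undefined) when either marker is monomorphic there."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete samples")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class Region:
    """An associated interval: flanked span, top SNP, member SNPs."""

    chrom: str
    start: int             # 1-based inclusive, flank included
    end: int
    top_snp: str
    top_p: float
    member_snps: list[str]

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000

    @property
    def size_kb_rounded(self) -> int:
        return int(round(self.size_kb))


def region_size_kb(start: int, end: int) -> int:
    """Reported region size: (end - start)/1000 rounded to the nearest kb."""
    return int(round((end - start) / 1000))


def define_regions(
    hits: list[tuple[str, float]],
    g: GenotypeMatrix,
    marker_map: MarkerMap | None = None,
    r2_min: float = 0.8,
    window_bp: float = 1e6,
    flank_bp: float = 5e4,
) -> list[Region]:
    """Greedy LD-clump of suggestive hits into associated regions.

    ``hits`` are (marker_id, p_hat) pairs; every hit ends up in exactly one
    region.  ``window_bp`` is the radius around the top SNP within which
    markers with r^2 > ``r2_min`` join the region.
    """
    mm = marker_map if marker_map is not None else g.markers
    for marker_id, _ in hits:
        mm.index_of(marker_id)  # raises KeyError when absent
    remaining = sorted(hits, key=lambda h: (h[1], h[0]))
    regions: list[Region] = []
    while remaining:
        top_id, top_p = remaining.pop(0)
        j = mm.index_of(top_id)
        chrom, pos = mm.chrom[j], int(mm.pos[j])
        near = np.flatnonzero(
            (mm.chrom == chrom) & (np.abs(mm.pos.astype(float) - pos) <= window_bp)
        )
        top_dosage = g.dosage[:, g.markers.index_of(top_id)]
        members = []
        for idx in near:
            mid = mm.marker_ids[idx]
            if mid == top_id:
                members.append(mid)
                continue
            r2 = ld_r2(top_dosage, g.dosage[:, g.markers.index_of(mid)])
            if not np.isnan(r2) and r2 > r2_min:
                members.append(mid)
        member_pos = np.array([mm.pos[mm.index_of(m)] for m in members])
        start = int(member_pos.min() - flank_bp)
        end = int(member_pos.max() + flank_bp)
        regions.append(Region(chrom, start, end, top_id, top_p, members))
        remaining = [h for h in remaining if h[0] not in members]
    logger.info("defined %d regions from %d hits", len(regions), len(hits))
    return regions


def regions_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "top_snp": [r.top_snp for r in regions],
            "top_p_hat": [r.top_p for r in regions],
            "n_members": [len(r.member_snps) for r in regions],
            "size_kb": [r.size_kb_rounded for r in regions],
        }
    )


@dataclass
class VarianceEstimate:
    label: str
    fraction: float
    jackknife_se: float


def variance_explained(
    y: np.ndarray,
    design: np.ndarray,
    K: KinshipMatrix,
    label: str = "design",
    jackknife: bool = True,
) -> VarianceEstimate:
    """Fraction of phenotypic variance explained by fixed effects.

    ``y`` is the five-percentile-group label vector, ``design`` the fixed
    effects of interest (age and/or top-SNP dosages, no intercept column).
    The fraction is 1 - var(y - X beta)/var(y) with beta from the polygenic
    mixed model; the standard error is a leave-one-out jackknife with the
    variance ratio held at the full-data REML estimate.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(design, float).T).T
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < X.shape[1] + 1:
        raise ValueError("collinear design")
    fit = polygenic_fit(y, X, K)
    fraction = _fraction(y, fit.residuals)
    se = 0.0
    if jackknife:
        n = len(y)
        h2 = fit.heritability
        V = h2 * K.values + (1 - h2) * np.eye(n)
        Xi = np.column_stack([np.ones(n), X])
        thetas = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            Vi = V[np.ix_(keep, keep)]
            Xk, yk = Xi[keep], y[keep]
            Vinv_X = np.linalg.solve(Vi, Xk)
            beta = np.linalg.solve(Xk.T @ Vinv_X, Vinv_X.T @ yk)
            thetas[i] = _fraction(yk, yk - Xk @ beta)
        se = float(np.sqrt((n - 1) / n * ((thetas - thetas.mean()) ** 2).sum()))
    return VarianceEstimate(label, fraction, se)


def _fraction(y: np.ndarray, residuals: np.ndarray) -> float:
    return float(np.clip(1 - residuals.var() / y.var(), 0.0, 1.0))


def cross_breed_fixation_check(
    top_snps: list[tuple[str, str]],
    panels: dict[str, GenotypeMatrix],
    fixed_min: float = 0.95,
) -> pd.DataFrame:
    """Risk-allele frequency of each top SNP in each breed panel.

    ``top_snps`` are (marker_id, risk_allele) pairs where the risk allele is
    ``"a"`` or ``"b"`` of the marker's coding.  A SNP is flagged fixed in a
    breed iff its risk-allele frequency there is strictly above ``fixed_min``;
    SNPs absent from a panel get a missing frequency, never 0.
    """
    rows = []
    for marker_id, risk in top_snps:
        if risk not in ("a", "b"):
            raise ValueError("risk allele must be 'a' or 'b'")
        for breed, g in panels.items():
            try:
                d = g.marker_dosage(marker_id)
            except KeyError:
                rows.append({"marker_id": marker_id, "breed": breed,
                             "risk_freq": np.nan, "fixed": False})
                continue
            with np.errstate(invalid="ignore"):
                freq_b = np.nanmean(d) / 2
            freq = freq_b if risk == "b" else 1 - freq_b
            rows.append({"marker_id": marker_id, "breed": breed,
                         "risk_freq": float(freq),
                         "fixed": bool(freq > fixed_min)})
    return pd.DataFrame(rows)
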