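"""Sample/marker quality control and percentile-group phenotype construction.

The trait (serum IgA, g/l) has no accepted deficiency cut-off, so association
runs use its empirical percentile bin as the phenotype: three runs with k = 3,
4, 5 equal-probability groups (group number analysed as a numeric trait) and
one extreme-quartile case/control run.  Empirical quantiles use the inclusive
linear-interpolation definition (type 7) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, PhenotypeTable, logger

CASE, CONTROL, EXCLUDED = 1, 0, -1


@dataclass
class GroupAssignment:
    """Percentile-group labels: 1..k, or case/control/excluded (1/0/-1)."""

    sample_ids: np.ndarray
    group: np.ndarray
    k: int


def percentile_groups(values: np.ndarray, k: int,
                      sample_ids: np.ndarray | None = None) -> GroupAssignment:
    """Assign each value to its empirical k-quantile group.

    Group g holds values in the ((g-1)/k, g/k] quantile interval; ties at a
    boundary all go to the lower group, so the mapping is monotone and
    invariant to strictly increasing transforms of the values.
    """
    values = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.isnan(values).any():
        raise ValueError("values must be non-missing")
    if k > len(np.unique(values)):
        raise ValueError(f"k={k} exceeds the number of distinct values")
    cuts = np.quantile(values, np.arange(1, k) / k, method="linear")
    group = 1 + (values[:, None] > cuts[None, :]).sum(axis=1)
    if sample_ids is None:
        sample_ids = np.arange(len(values))
    return GroupAssignment(np.asarray(sample_ids), group.astype(int), k)


def extreme_case_control(values: np.ndarray,
                         sample_ids: np.ndarray | None = None) -> GroupAssignment:
    """Cases below the 25th percentile, controls above the 75th, middle excluded."""
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise ValueError("need at least 8 samples for the extreme design")
    q25, q75 = np.quantile(values, [0.25, 0.75], method="linear")
    group = np.full(len(values), EXCLUDED, dtype=int)
    group[values < q25] = CASE
    group[values > q75] = CONTROL
    if (group == CASE).sum() < 2 or (group == CONTROL).sum() < 2:
        raise ValueError("fewer than 2 cases or 2 controls")
    if sample_ids is None:
        sample_ids = np.arange(len(values))
    return GroupAssignment(np.asarray(sample_ids), group, 2)


def covariate_correlation(trait: np.ndarray, covariate: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment r and its two-sided p (t transform)."""
    trait = np.asarray(trait, float)
    covariate = np.asarray(covariate, float)
    ok = ~(np.isnan(trait) | np.isnan(covariate))
    trait, covariate = trait[ok], covariate[ok]
    if len(trait) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if trait.std() == 0 or covariate.std() == 0:
        raise ValueError("zero variance in trait or covariate")
    r, p = stats.pearsonr(trait, covariate)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def _ibs_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise allele-sharing over non-missing markers (pairwise complete)."""
    obs = ~np.isnan(dosage)
    d = np.nan_to_num(dosage, nan=-9.0)
    ind = [(d == k).astype(float) for k in (0.0, 1.0, 2.0)]
    same = ind[0] @ ind[0].T + ind[1] @ ind[1].T + ind[2] @ ind[2].T
    half = ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    n_obs = obs.astype(float) @ obs.astype(float).T
    if (n_obs == 0).any():
        raise ValueError("a sample pair shares no genotyped markers")
    return (same + 0.5 * half) / n_obs


def qc_filter(
    g: GenotypeMatrix,
    p: PhenotypeTable,
    maf_min: float = 0.05,
    marker_call_min: float = 0.95,
    sample_call_min: float = 0.95,
    ibs_max: float = 0.95,
    het_max: float = 0.95,
    age_min: float = 1.0,
) -> tuple[GenotypeMatrix, PhenotypeTable, pd.DataFrame]:
    """Iterative marker/sample filtering to a fixpoint.

    Markers drop when MAF < ``maf_min`` or call rate <= ``marker_call_min``;
    samples drop for missing trait/covariates, age < ``age_min``, call rate
    <= ``sample_call_min``, pairwise IBS > ``ibs_max`` (one of each pair) or
    autosomal heterozygosity > ``het_max``.  Returns the filtered data and a
    report listing every exclusion with its reason.
    """
    for thr in (maf_min, marker_call_min, sample_call_min, ibs_max, het_max):
        if not 0 <= thr <= 1:
            raise ValueError("thresholds must lie in [0,1]")
    if age_min < 0:
        raise ValueError("age_min must be >= 0")

    exclusions: list[dict] = []
    pt = p.aligned_to(g.samples)

    # sample-level phenotype checks happen once: they do not depend on markers
    keep_s = np.ones(g.n_samples, dtype=bool)
    for i, row in pt.iterrows():
        if pd.isna(row["iga"]) or pd.isna(row["age"]) or pd.isna(row["sex"]):
            keep_s[i] = False
            exclusions.append({"kind": "sample", "id": row["sample_id"],
                               "reason": "missing trait or covariate", "value": np.nan})
        elif row["age"] < age_min:
            keep_s[i] = False
            exclusions.append({"kind": "sample", "id": row["sample_id"],
                               "reason": f"age below {age_min}", "value": row["age"]})
    g = g.subset(sample_idx=keep_s)

    while True:
        changed = False
        d = g.dosage
        # markers
        call = 1 - np.isnan(d).mean(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(d, axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        maf = np.nan_to_num(maf, nan=0.0)
        drop_m = (maf < maf_min) | (call <= marker_call_min)
        if drop_m.any():
            for j in np.flatnonzero(drop_m):
                reason = ("MAF below threshold" if maf[j] < maf_min
                          else "call rate at or below threshold")
                exclusions.append({"kind": "marker", "id": g.markers.marker_ids[j],
                                   "reason": reason,
                                   "value": maf[j] if maf[j] < maf_min else call[j]})
            if drop_m.all():
                raise ValueError("QC removed all markers")
            g = g.subset(marker_idx=~drop_m)
            changed = True
            d = g.dosage

        # samples
        call_s = 1 - np.isnan(d).mean(axis=1)
        het = np.nanmean(d == 1, axis=1)
        drop_s = (call_s <= sample_call_min) | (het > het_max)
        ibs = _ibs_matrix(d)
        np.fill_diagonal(ibs, 0.0)
        # drop one of each too-similar pair (the one with the lower call rate)
        for i, j in zip(*np.where(np.triu(ibs > ibs_max))):
            victim = i if call_s[i] <= call_s[j] else j
            if not drop_s[victim]:
                drop_s[victim] = True
                exclusions.append({"kind": "sample", "id": g.samples[victim],
                                   "reason": "IBS above threshold", "value": ibs[i, j]})
        for i in np.flatnonzero((call_s <= sample_call_min) | (het > het_max)):
            reason = ("call rate at or below threshold" if call_s[i] <= sample_call_min
                      else "heterozygosity above threshold")
            exclusions.append({"kind": "sample", "id": g.samples[i], "reason": reason,
                               "value": call_s[i] if call_s[i] <= sample_call_min else het[i]})
        if drop_s.any():
            if drop_s.all():
                raise ValueError("QC removed all samples")
            g = g.subset(sample_idx=~drop_s)
            changed = True

        if not changed:
            break

    pt = p.aligned_to(g.samples)
    report = pd.DataFrame(exclusions, columns=["kind", "id", "reason", "value"])
    logger.info("QC kept %d samples x %d markers (%d exclusions)",
                g.n_samples, g.n_markers, len(report))
    return g, PhenotypeTable(pt), report
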