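"""Empirical genome-wide significance by phenotype permutation.

For each phenotype run the trait (together with its covariates, as a row) is
permuted against the genotypes and the full mixed-model scan repeated; the
2.5% quantile of the per-permutation genome-wide minimum p — the 97.5% upper
empirical confidence bound on the strongest null signal — is that run's
genome-wide threshold.  The strictest threshold across runs is applied to the
combined p_hat.  Suggestive hits use the fixed nominal cutoff p < 0.0005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assoc import CombinedResult, MixedModelEngine
from .io import GenotypeMatrix, PhenotypeTable, logger
from .phenotype import CASE, EXCLUDED, extreme_case_control, percentile_groups

SUGGESTIVE_P = 5e-4  # nominal significance; hits require p_hat strictly below


@dataclass
class PermutationNull:
    """Null distribution of genome-wide minimum p for one phenotype run."""

    run_label: str
    n_perm: int
    min_p: np.ndarray
    threshold: float
    seed: int


@dataclass
class Thresholds:
    suggestive: float
    genome_wide: float

    def __post_init__(self) -> None:
        if self.genome_wide > self.suggestive:
            logger.warning("genome-wide cutoff %.3g exceeds suggestive %.3g",
                           self.genome_wide, self.suggestive)


def _run_trait(iga: np.ndarray, run: str) -> tuple[np.ndarray, np.ndarray]:
    """(numeric trait, inclusion mask) for one run label."""
    if run.startswith("groups"):
        k = int(run.removeprefix("groups"))
        ga = percentile_groups(iga, k)
        return ga.group.astype(float), np.ones(len(iga), dtype=bool)
    if run == "extremes":
        ga = extreme_case_control(iga)
        return (ga.group == CASE).astype(float), ga.group != EXCLUDED
    raise ValueError(f"unknown run label {run!r}")


def permutation_threshold(
    g: GenotypeMatrix,
    p: PhenotypeTable,
    covariates: np.ndarray | None,
    run: str,
    n_perm: int,
    seed: int,
    engine: MixedModelEngine | None = None,
) -> PermutationNull:
    """Permute trait+covariate rows against genotypes ``n_perm`` times, rerun
    the scan, and take the 2.5% quantile of the per-permutation minimum p."""
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    rng = np.random.default_rng(seed)
    pheno = p.aligned_to(g.samples)
    iga = pheno["iga"].to_numpy(float)
    if covariates is None:
        from .assoc import _covariate_design

        covariates = _covariate_design(pheno)
    engine = engine if engine is not None else MixedModelEngine(g)

    minima = np.empty(n_perm)
    n = len(iga)
    for b in range(n_perm):
        perm = rng.permutation(n)
        trait, mask = _run_trait(iga[perm], run)
        X = covariates[perm] if covariates is not None else None
        res = engine.run(trait, X, sample_mask=mask, label=f"{run}-perm{b}")
        minima[b] = res.p.min()
    # (n_perm + 1) plotting position: under exchangeability of the observed
    # scan with the permuted scans this makes the family-wise error equal the
    # nominal 2.5% exactly, which the interpolated sample quantile does not at
    # small n_perm (it sits near the 2nd order statistic, doubling the rate)
    threshold = float(np.quantile(minima, 0.025, method="weibull"))
    logger.info("permutation null (%s): %d perms, threshold %.3g", run, n_perm, threshold)
    return PermutationNull(run, n_perm, minima, threshold, seed)


def genome_wide_calls(combined: CombinedResult, nulls: list[PermutationNull]) -> np.ndarray:
    """Markers whose p_hat falls below the strictest run threshold."""
    if not nulls:
        raise ValueError("at least one permutation null is required")
    threshold = min(nu.threshold for nu in nulls)
    return combined.marker_ids[combined.p_hat < threshold]


def suggestive_hits(combined: CombinedResult) -> np.ndarray:
    """Markers with p_hat strictly below the nominal 0.0005 cutoff."""
    return combined.marker_ids[combined.p_hat < SUGGESTIVE_P]
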