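"""Permutation-based genome-wide significance thresholds per run.

Trait+covariate rows are permuted against genotypes and the scan repeated;
the threshold is the 2.5% point of the per-permutation genome-wide minimum p
((n_perm+1) plotting position), and the strictest run threshold is applied to
the combined p_hat.  Production analyses use 1,000 permutations; this driver
uses 100 per run to stay desk-scale.
"""

from pathlib import Path

import pandas as pd

from igamap import io
from igamap.assoc import MixedModelEngine
from igamap.significance import SUGGESTIVE_P, genome_wide_calls, permutation_threshold, suggestive_hits

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
N_PERM = 100
SEED = 77

if __name__ == "__main__":
    g = io.read_genotypes(SCRATCH / "qc_cohort.tsv", dialect="dosage_tsv")
    p = io.read_phenotypes(SCRATCH / "qc_phenotypes.tsv")
    engine = MixedModelEngine(g)
    nulls = []
    for i, run in enumerate(("groups3", "groups4", "groups5", "extremes")):
        null = permutation_threshold(g, p, None, run, n_perm=N_PERM,
                                     seed=SEED + i, engine=engine)
        nulls.append(null)
        pd.DataFrame({"min_p": null.min_p}).to_csv(
            SCRATCH / f"perm_minima_{run}.tsv", sep="\t", index=False)
    thr = pd.DataFrame({
        "run": [n.run_label for n in nulls],
        "n_perm": N_PERM,
        "threshold": [n.threshold for n in nulls],
    })
    thr.to_csv(RESULTS / "permutation_thresholds.tsv", sep="\t", index=False)
    print(thr.to_string(index=False))

    combined_df = pd.read_csv(SCRATCH / "gwas_combined.tsv", sep="\t")
    from igamap.assoc import CombinedResult
    combined = CombinedResult(combined_df["marker_id"].to_numpy(),
                              combined_df["p_hat"].to_numpy(float), 4,
                              ("groups3", "groups4", "groups5", "extremes"))
    gw = genome_wide_calls(combined, nulls)
    sug = suggestive_hits(combined)
    pd.DataFrame({"marker_id": sug}).to_csv(RESULTS / "suggestive_hits.tsv",
                                            sep="\t", index=False)
    print(f"strictest threshold: {min(n.threshold for n in nulls):.2e}")
    print(f"suggestive hits (p_hat < {SUGGESTIVE_P}): {len(sug)}")
    print(f"genome-wide significant markers: {len(gw)}")
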