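"""LD-defined associated regions and variance explained by age and top SNPs.

Suggestive hits are clumped into regions (r^2 > 0.8 within 1 Mb of the top
SNP, 50 kb flanks) and the fraction of five-group phenotypic variance
explained by age and by the top SNP per region is estimated from the mixed
model, with leave-one-out jackknife errors.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from igamap import io
from igamap.assoc import kinship_matrix
from igamap.phenotype import percentile_groups
from igamap.regions import define_regions, regions_frame, variance_explained
from igamap.significance import SUGGESTIVE_P

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    g = io.read_genotypes(SCRATCH / "qc_cohort.tsv", dialect="dosage_tsv")
    p = io.read_phenotypes(SCRATCH / "qc_phenotypes.tsv")
    combined = pd.read_csv(SCRATCH / "gwas_combined.tsv", sep="\t")
    hits = [(r.marker_id, r.p_hat) for r in combined.itertuples()
            if r.p_hat < SUGGESTIVE_P]
    regions = define_regions(hits, g)
    rf = regions_frame(regions)
    rf.to_csv(RESULTS / "regions.tsv", sep="\t", index=False)
    io.write_bed([(r.chrom, r.start, r.end, r.top_snp) for r in regions],
                 RESULTS / "regions.bed")
    print(f"{len(hits)} suggestive hits -> {len(regions)} regions")
    if len(rf):
        print(rf.to_string(index=False))

    ph = p.aligned_to(g.samples)
    y = percentile_groups(ph["iga"].to_numpy(float), 5).group.astype(float)
    K = kinship_matrix(g)
    rows = []
    est = variance_explained(y, ph["age"].to_numpy(float)[:, None], K, label="age")
    rows.append(est)
    for r in regions[:3]:
        d = g.marker_dosage(r.top_snp)
        d = np.nan_to_num(d, nan=np.nanmean(d))
        rows.append(variance_explained(y, d[:, None], K, label=f"top:{r.top_snp}"))
    ve = pd.DataFrame([{"label": e.label, "fraction": e.fraction,
                        "jackknife_se": e.jackknife_se} for e in rows])
    ve.to_csv(RESULTS / "variance_explained.tsv", sep="\t", index=False)
    for e in rows:
        print(f"variance explained by {e.label}: {100 * e.fraction:.1f}% "
              f"(jackknife se {100 * e.jackknife_se:.1f})")
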