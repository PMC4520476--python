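"""Phase the top associated window and test IgA between diplotype groups.

The markers around the best region's top SNP are phased by EM; dogs are
grouped by their most probable diplotype and the two largest homozygous /
heterozygous groups are compared on the five-percentile-group labels with
Welch t-tests, mirroring the risk-vs-protective haplotype comparisons of the
source analysis design.
"""

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from igamap import io
from igamap.haplotypes import diplotype_group_test, phase_em
from igamap.phenotype import percentile_groups

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

if __name__ == "__main__":
    g = io.read_genotypes(SCRATCH / "qc_cohort.tsv", dialect="dosage_tsv")
    p = io.read_phenotypes(SCRATCH / "qc_phenotypes.tsv")
    regions = pd.read_csv(RESULTS / "regions.tsv", sep="\t")
    if len(regions) == 0:
        raise SystemExit("no regions defined; run 03-05 first")
    top_snp = regions.iloc[0]["top_snp"]
    j = g.markers.index_of(top_snp)
    # phase the SNPs in strong LD (r^2 > 0.8) with the top SNP within 1 Mb,
    # topped up with immediate neighbours if the region is a singleton
    from igamap.regions import ld_r2
    chrom, pos = g.markers.chrom[j], g.markers.pos[j]
    near = np.flatnonzero((g.markers.chrom == chrom)
                          & (np.abs(g.markers.pos - pos) <= 1_000_000))
    top_d = g.dosage[:, j]
    idx = [k for k in near
           if k == j or (lambda v: not np.isnan(v) and v > 0.8)(
               ld_r2(top_d, g.dosage[:, k]))]
    if len(idx) < 3:
        idx = sorted(set(idx) | set(range(max(0, j - 2), min(g.n_markers, j + 3))))
    sub = g.subset(marker_idx=np.array(idx))
    hs, assign = phase_em(sub, seed=1)

    hap_table = pd.DataFrame({
        "haplotype": ["".join(map(str, h)) for h in hs.haplotypes],
        "frequency": hs.frequencies,
        "count": hs.counts,
        "label": hs.labels(),
    })
    hap_table.to_csv(RESULTS / "haplotypes.tsv", sep="\t", index=False)
    n_rare = sum(1 for l in hs.labels() if l == "rare")
    print(f"window of {sub.n_markers} SNPs around {top_snp}: "
          f"{len(hs.haplotypes)} haplotypes, {n_rare} rare (N <= {hs.rare_max_count})")

    ph = p.aligned_to(g.samples)
    groups5 = percentile_groups(ph["iga"].to_numpy(float), 5).group
    trait = dict(zip(ph["sample_id"], groups5.astype(float)))
    pairs = Counter(a.pair for a in assign)
    common = [pair for pair, n in pairs.most_common() if n >= 5]
    rows = []
    for i in range(len(common)):
        for k in range(i + 1, len(common)):
            try:
                t, df, pv = diplotype_group_test(assign, common[i], common[k], trait)
            except ValueError:
                continue
            rows.append({"diplotype_a": f"{common[i][0]+1}/{common[i][1]+1}",
                         "diplotype_b": f"{common[k][0]+1}/{common[k][1]+1}",
                         "t": t, "df": df, "p": pv,
                         "n_a": pairs[common[i]], "n_b": pairs[common[k]]})
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "diplotype_tests.tsv", sep="\t", index=False)
    if len(out):
        best = out.loc[out["p"].idxmin()]
        print(f"strongest diplotype contrast: {best.diplotype_a} vs "
              f"{best.diplotype_b}, Welch t={best.t:.2f}, p={best.p:.2g}")
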