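"""Readers and writers for the on-disk formats used throughout the pipeline.

Genotypes travel as a :class:`GenotypeMatrix` (samples x markers dosage of the
B allele, ``nan`` = missing) tied to a :class:`MarkerMap`.  Two text dialects
are supported: PLINK-style PED/MAP and a simpler dosage TSV.  Phenotypes,
pooled read counts and per-breed variant frequencies are thin wrappers around
pandas DataFrames with validated invariants.  All coordinates are 1-based
inclusive; BED exports convert to 0-based half-open at the writer boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("igamap")

MISSING = np.nan  # missing dosage sentinel, distinct from any valid dosage


class ParseError(ValueError):
    """Malformed input file (carries the offending line where known)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Marker annotation: id, chromosome, 1-based position, alleles A/B."""

    table: pd.DataFrame  # columns: marker_id, chrom, pos, allele_a, allele_b

    REQUIRED = ("marker_id", "chrom", "pos", "allele_a", "allele_b")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ParseError(f"marker map missing columns {missing}")
        t = self.table
        if (t["pos"] < 1).any():
            raise ParseError("marker positions must be >= 1")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ParseError(f"duplicate marker id {dup!r}")
        if (t["allele_a"] == t["allele_b"]).any():
            bad = t.loc[t["allele_a"] == t["allele_b"], "marker_id"].iloc[0]
            raise ParseError(f"marker {bad!r} has identical alleles")
        order = np.lexsort((t["pos"].to_numpy(), t["chrom"].to_numpy()))
        self.table = t.iloc[order].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_ids == marker_id)
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(hits[0])


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix counting copies of allele B."""

    samples: list[str]
    markers: MarkerMap
    dosage: np.ndarray  # float, values in {0,1,2,nan}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ParseError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ParseError("duplicate sample ids")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ParseError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        marker_idx: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        d = self.dosage
        samples = self.samples
        mm = self.markers.table
        if sample_idx is not None:
            idx = np.atleast_1d(np.asarray(sample_idx))
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
            d = d[idx]
            samples = [self.samples[i] for i in idx]
        if marker_idx is not None:
            midx = np.atleast_1d(np.asarray(marker_idx))
            if midx.dtype == bool:
                midx = np.flatnonzero(midx)
            d = d[:, midx]
            mm = mm.iloc[midx]
        return GenotypeMatrix(list(samples), MarkerMap(mm.reset_index(drop=True)), d.copy())

    def marker_dosage(self, marker_id: str) -> np.ndarray:
        return self.dosage[:, self.markers.index_of(marker_id)]


@dataclass
class PhenotypeTable:
    """Per-sample trait value and covariates (IgA g/l, age, sex, ...)."""

    table: pd.DataFrame  # sample_id, iga, age, sex [, subpop, disease]

    def __post_init__(self) -> None:
        for col in ("sample_id", "iga", "age", "sex"):
            if col not in self.table.columns:
                raise ParseError(f"phenotype table missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            raise ParseError("duplicate sample ids in phenotype table")
        iga = self.table["iga"]
        if (iga.dropna() < 0).any():
            raise ParseError("IgA concentrations must be non-negative")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    def aligned_to(self, samples: Sequence[str]) -> pd.DataFrame:
        """Rows reordered to match a genotype sample order."""
        t = self.table.set_index("sample_id")
        missing = [s for s in samples if s not in t.index]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}")
        return t.loc[list(samples)].reset_index()


@dataclass
class PoolCountTable:
    """Per-site ref/alt read counts for >= 2 sequencing pools."""

    table: pd.DataFrame  # chrom, pos, ref_allele, alt_allele, {pool}_ref, {pool}_alt
    pools: list[str]

    def __post_init__(self) -> None:
        if len(self.pools) < 2:
            raise ParseError("pool count table needs at least 2 pools")
        for p in self.pools:
            for suffix in ("ref", "alt"):
                col = f"{p}_{suffix}"
                if col not in self.table.columns:
                    raise ParseError(f"missing count column {col!r}")
                if (self.table[col] < 0).any():
                    raise ParseError(f"negative count in column {col!r}")
        order = np.lexsort((self.table["pos"].to_numpy(), self.table["chrom"].to_numpy()))
        self.table = self.table.iloc[order].reset_index(drop=True)
        if len(self.table) == 0:
            logger.warning("pool count table is empty")

    def counts(self, pool: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.table[f"{pool}_ref"].to_numpy(float),
            self.table[f"{pool}_alt"].to_numpy(float),
        )


@dataclass
class VariantFrequencyTable:
    """Per-breed alternate-allele frequencies (SNPs and indels alike)."""

    table: pd.DataFrame  # chrom, pos, ref, alt, freq_{breed}, n_{breed}
    breeds: list[str]

    def __post_init__(self) -> None:
        for b in self.breeds:
            col = f"freq_{b}"
            if col not in self.table.columns:
                raise ParseError(f"missing frequency column {col!r}")
            f = self.table[col]
            if ((f < 0) | (f > 1)).any():
                raise ParseError(f"frequencies outside [0,1] in {col!r}")
        order = np.lexsort((self.table["pos"].to_numpy(), self.table["chrom"].to_numpy()))
        self.table = self.table.iloc[order].reset_index(drop=True)

    def frequencies(self, breed: str) -> np.ndarray:
        return self.table[f"freq_{breed}"].to_numpy(float)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def _read_map(path: Path) -> MarkerMap:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{i}: MAP line needs 4 fields, got {len(parts)}")
        rows.append((parts[1], parts[0], int(parts[3])))
    return rows  # raw; alleles filled in from PED


def read_genotypes(path: str | Path, dialect: str = "ped_map") -> GenotypeMatrix:
    """Load genotypes from ``ped_map`` (pair of files, pass the .ped path or the
    stem) or ``dosage_tsv`` (samples x markers table with a companion .map)."""
    path = Path(path)
    if dialect == "ped_map":
        return _read_ped_map(path)
    if dialect == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_ped_map(path: Path) -> GenotypeMatrix:
    stem = path.with_suffix("")
    ped_path, map_path = stem.with_suffix(".ped"), stem.with_suffix(".map")
    map_rows = _read_map(map_path)
    n_markers = len(map_rows)

    samples: list[str] = []
    geno_rows: list[list[tuple[str, str]]] = []
    for i, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise ParseError(
                f"{ped_path}:{i}: expected {6 + 2 * n_markers} fields, got {len(parts)}"
            )
        samples.append(parts[1])
        geno_rows.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_markers)])
    if len(set(samples)) != len(samples):
        raise ParseError(f"{ped_path}: duplicate sample id")

    # infer the two alleles per marker; A = first allele seen, B = second
    allele_a, allele_b = [], []
    for j in range(n_markers):
        seen: list[str] = []
        for row in geno_rows:
            for a in row[j]:
                if a != "0" and a not in seen:
                    seen.append(a)
        if len(seen) > 2:
            raise ParseError(f"marker {map_rows[j][0]!r} has >2 alleles: {seen}")
        seen = sorted(seen)  # deterministic A/B assignment
        allele_a.append(seen[0] if seen else "A")
        allele_b.append(seen[1] if len(seen) > 1 else ("B" if not seen or seen[0] != "B" else "C"))

    dosage = np.full((len(samples), n_markers), MISSING)
    for i, row in enumerate(geno_rows):
        for j, (a1, a2) in enumerate(row):
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == allele_b[j]) + (a2 == allele_b[j])

    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [r[0] for r in map_rows],
                "chrom": [r[1] for r in map_rows],
                "pos": [r[2] for r in map_rows],
                "allele_a": allele_a,
                "allele_b": allele_b,
            }
        )
    )
    # MarkerMap sorts by (chrom,pos); reorder dosage columns to match
    raw_ids = [r[0] for r in map_rows]
    order = [raw_ids.index(m) for m in mm.marker_ids]
    return GenotypeMatrix(samples, mm, dosage[:, order])


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    stem = Path(path).with_suffix("")
    df = pd.read_csv(stem.with_suffix(".tsv"), sep="\t", index_col=0)
    mdf = pd.read_csv(stem.with_suffix(".markers.tsv"), sep="\t")
    mm = MarkerMap(mdf)
    if list(df.columns) != list(mdf["marker_id"]):
        df = df[[m for m in mdf["marker_id"]]]
    df = df[list(mm.marker_ids)]
    return GenotypeMatrix([str(s) for s in df.index], mm, df.to_numpy(float))


def write_genotypes(g: GenotypeMatrix, path: str | Path, dialect: str = "ped_map") -> None:
    path = Path(path)
    stem = path.with_suffix("")
    if dialect == "ped_map":
        t = g.markers.table
        with open(stem.with_suffix(".map"), "w") as fh:
            for _, r in t.iterrows():
                fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.pos}\n")
        aa = t["allele_a"].to_numpy()
        bb = t["allele_b"].to_numpy()
        with open(stem.with_suffix(".ped"), "w") as fh:
            for i, s in enumerate(g.samples):
                fields = [s, s, "0", "0", "0", "-9"]
                for j, d in enumerate(g.dosage[i]):
                    if np.isnan(d):
                        fields += ["0", "0"]
                    elif d == 0:
                        fields += [aa[j], aa[j]]
                    elif d == 1:
                        fields += [aa[j], bb[j]]
                    else:
                        fields += [bb[j], bb[j]]
                fh.write(" ".join(fields) + "\n")
    elif dialect == "dosage_tsv":
        df = pd.DataFrame(g.dosage, index=g.samples, columns=g.markers.marker_ids)
        df.to_csv(stem.with_suffix(".tsv"), sep="\t")
        g.markers.table.to_csv(stem.with_suffix(".markers.tsv"), sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# phenotype / pool / variant-frequency I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    p.table.to_csv(path, sep="\t", index=False)


def read_pool_counts(path: str | Path) -> PoolCountTable:
    df = pd.read_csv(path, sep="\t")
    fixed = {"chrom", "pos", "ref_allele", "alt_allele"}
    missing = fixed - set(df.columns)
    if missing:
        raise ParseError(f"pool count table missing columns {sorted(missing)}")
    pools = sorted({c.rsplit("_", 1)[0] for c in df.columns if c.endswith(("_ref", "_alt"))})
    return PoolCountTable(df, pools)


def write_pool_counts(t: PoolCountTable, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index=False)


def read_variant_frequencies(path: str | Path) -> VariantFrequencyTable:
    df = pd.read_csv(path, sep="\t")
    breeds = [c[len("freq_"):] for c in df.columns if c.startswith("freq_")]
    return VariantFrequencyTable(df, breeds)


def write_variant_frequencies(t: VariantFrequencyTable, path: str | Path) -> None:
    t.table.to_csv(path, sep="\t", index=False)


def read_variant_frequencies_vcf(
    path: str | Path, breed_of_sample: Mapping[str, str]
) -> VariantFrequencyTable:
    """Derive per-breed alt-allele frequencies from the GT field of a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    breeds = sorted(set(breed_of_sample.values()))
    sample_breed = np.array([breed_of_sample.get(s, "") for s in vcf.samples])
    rows = []
    for v in vcf:
        row: dict[str, object] = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "ref": v.REF,
            "alt": v.ALT[0] if v.ALT else ".",
        }
        gts = np.array(v.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        alt_copies = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=-1)
        for b in breeds:
            mask = (sample_breed == b) & (alt_copies >= 0)
            n = int(mask.sum())
            row[f"freq_{b}"] = float(alt_copies[mask].sum() / (2 * n)) if n else np.nan
            row[f"n_{b}"] = n
        rows.append(row)
    return VariantFrequencyTable(pd.DataFrame(rows), breeds)


# ---------------------------------------------------------------------------
# BED export and run metadata
# ---------------------------------------------------------------------------


def write_bed(intervals: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """Intervals given 1-based inclusive; written 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_log(
    path: str | Path,
    stage: str,
    params: Mapping[str, object],
    inputs: Sequence[str | Path] = (),
    seed: int | None = None,
) -> None:
    meta = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "params": dict(params),
        "input_hashes": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
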