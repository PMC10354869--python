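"""Readers/writers for VCF, GFF3 and phenotype tables, and the in-memory panel types.

Coordinates are 1-based inclusive throughout (VCF/GFF3 convention).  Genotypes
are stored as ALT-allele dosages 0/1/2 with ``NaN`` marking missing calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_MAP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypePanel:
    """A panel of diploid individuals genotyped at biallelic SNPs.

    Parameters
    ----------
    dosages:
        ``(n_individuals, n_snps)`` float array of ALT-allele counts in
        {0, 1, 2}; missing calls are ``NaN``.
    snp_map:
        Per-SNP table with columns ``chrom, pos, id, ref, alt``; positions are
        1-based and strictly increasing within each chromosome.
    individuals:
        Per-individual table with columns ``id``, ``sex`` (``M``/``F``/
        ``unknown``) and ``group`` (germplasm-class label, may be empty).
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (individuals x SNPs)")
        n, p = self.dosages.shape
        if len(self.snp_map) != p:
            raise ValueError(f"snp_map has {len(self.snp_map)} rows for {p} SNP columns")
        if len(self.individuals) != n:
            raise ValueError(
                f"individual table has {len(self.individuals)} rows for {n} dosage rows"
            )
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage out of {{0,1,2,NaN}} at individual {bad[0]}, SNP {bad[1]}"
            )
        self.snp_map = self.snp_map.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        for chrom, sub in self.snp_map.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.individuals["id"].duplicated().any():
            dup = self.individuals["id"][self.individuals["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP ALT allele frequency computed on non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take_snps(self, index: np.ndarray) -> "GenotypePanel":
        """New panel restricted to the SNP columns in ``index`` (order kept)."""
        return GenotypePanel(
            dosages=self.dosages[:, index],
            snp_map=self.snp_map.iloc[np.asarray(index)].reset_index(drop=True),
            individuals=self.individuals.copy(),
        )

    def sex_indicator(self) -> np.ndarray:
        """0/1 male indicator used as the sex fixed-effect column."""
        return (self.individuals["sex"].to_numpy() == "M").astype(float)


@dataclass
class OrdinalPhenotypeTable:
    """Ordinal scores (1..C) for named traits, one row per individual.

    ``data`` holds columns ``id``, ``sex`` and one integer column per trait;
    missing scores are ``NaN`` (stored as float).
    """

    data: pd.DataFrame
    n_categories: int = 9

    def __post_init__(self) -> None:
        for col in ("id", "sex"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        if self.data["id"].duplicated().any():
            dup = self.data["id"][self.data["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate individual id {dup!r} in phenotype table")
        self.data = self.data.reset_index(drop=True)
        for trait in self.trait_names:
            v = self.data[trait].to_numpy(dtype=float)
            obs = v[~np.isnan(v)]
            if len(obs) and (np.any(obs != np.round(obs)) or obs.min() < 1 or obs.max() > self.n_categories):
                bad = self.data.index[
                    ~self.data[trait].isna()
                    & (
                        (self.data[trait] < 1)
                        | (self.data[trait] > self.n_categories)
                        | (self.data[trait] != np.round(self.data[trait].astype(float)))
                    )
                ][0]
                raise ValueError(
                    f"trait {trait!r} row {bad}: score {self.data.loc[bad, trait]!r} "
                    f"outside 1..{self.n_categories}"
                )

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("id", "sex")]

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def scores(self, trait: str) -> np.ndarray:
        """Float vector of scores for ``trait`` (NaN = missing)."""
        return self.data[trait].to_numpy(dtype=float)

    def category_counts(self, trait: str) -> np.ndarray:
        """Observed count per category 1..C (length C)."""
        v = self.scores(trait)
        v = v[~np.isnan(v)].astype(int)
        return np.bincount(v, minlength=self.n_categories + 1)[1:]

    def write(self, path) -> None:
        out = self.data.copy()
        for trait in self.trait_names:
            out[trait] = out[trait].astype("Int64")
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval from a GFF3 annotation (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def read_vcf(path, skip_non_biallelic: bool = True) -> GenotypePanel:
    """Load unphased diploid genotypes from a VCF into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are skipped (default) or raise when
    ``skip_non_biallelic=False``.  SNP ids are synthesized as ``<CHROM>_<POS>``
    when the ID column is ``.``.
    """
    import cyvcf2

    try:
        reader = cyvcf2.VCF(str(path))
    except Exception as exc:  # htslib raises bare OSError on malformed input
        raise ValueError(f"failed to open VCF {path}: {exc}") from exc

    samples = list(reader.samples)
    rows: list[dict] = []
    columns: list[np.ndarray] = []
    lineno = len(reader.raw_header.splitlines())
    try:
        for variant in reader:
            lineno += 1
            if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
                if skip_non_biallelic:
                    continue
                raise ValueError(
                    f"non-biallelic or non-SNP record at line {lineno}: "
                    f"{variant.CHROM}:{variant.POS}"
                )
            gts = np.array(variant.genotypes, dtype=int)[:, :2]
            dos = gts.sum(axis=1).astype(float)
            dos[(gts < 0).any(axis=1)] = np.nan
            columns.append(dos)
            rows.append(
                {
                    "chrom": variant.CHROM,
                    "pos": variant.POS,
                    "id": variant.ID or f"{variant.CHROM}_{variant.POS}",
                    "ref": variant.REF,
                    "alt": variant.ALT[0],
                }
            )
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"VCF parse error near line {lineno} of {path}: {exc}") from exc
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")
    snp_map = pd.DataFrame(rows, columns=SNP_MAP_COLUMNS)
    individuals = pd.DataFrame(
        {"id": samples, "sex": "unknown", "group": ""}
    )
    return GenotypePanel(
        dosages=np.column_stack(columns), snp_map=snp_map, individuals=individuals
    )


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a minimal VCF 4.2 file, sorted by (chrom, pos)."""
    order = np.lexsort((panel.snp_map["pos"].to_numpy(), panel.snp_map["chrom"].to_numpy()))
    snp_map = panel.snp_map.iloc[order]
    dosages = panel.dosages[:, order]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ordgen\n")
        for chrom in pd.unique(snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(panel.individuals["id"].astype(str))
        fh.write("\t".join(header) + "\n")
        for j, (_, rec) in enumerate(snp_map.iterrows()):
            ref, alt = rec["ref"], rec["alt"]
            if not ref or not alt or pd.isna(ref) or pd.isna(alt):
                warnings.warn(
                    f"SNP {rec['id']} lacks alleles; writing placeholder A/T",
                    stacklevel=2,
                )
                ref, alt = "A", "T"
            gts = [
                _GT_STRINGS.get(d, "./.") if not np.isnan(d) else "./."
                for d in dosages[:, j]
            ]
            fields = [
                str(rec["chrom"]),
                str(int(rec["pos"])),
                str(rec["id"]),
                ref,
                alt,
                ".",
                "PASS",
                ".",
                "GT",
            ] + gts
            fh.write("\t".join(fields) + "\n")


def read_phenotypes(path, n_categories: int = 9) -> OrdinalPhenotypeTable:
    """Read a tab-separated phenotype table (columns: id, sex, trait...)."""
    data = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA", ""])
    if "id" not in data.columns or "sex" not in data.columns:
        raise ValueError(f"{path}: phenotype TSV must have 'id' and 'sex' columns")
    data["sex"] = data["sex"].fillna("unknown")
    return OrdinalPhenotypeTable(data=data, n_categories=n_categories)


def read_gff3(path) -> list[GeneRecord]:
    """Parse a GFF3 file, keeping only ``gene`` features, sorted by (chrom, start)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            force=True,
        )
    except Exception as exc:
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc
    records = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        records.append(
            GeneRecord(
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                gene_id=gene_id,
            )
        )
    records.sort(key=lambda g: (g.chrom, g.start, g.end))
    return records


def impute_missing_naive(panel: GenotypePanel) -> GenotypePanel:
    """Per-SNP mode imputation of missing dosages (ties keep the lower dosage).

    A deliberately simple stand-in for haplotype-based imputation: adequate for
    panels with controlled, low missingness.  All-missing SNPs are dropped with
    a warning.
    """
    dosages = panel.dosages.copy()
    n_missing = int(np.isnan(dosages).sum())
    keep = []
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        miss = np.isnan(col)
        if miss.all():
            warnings.warn(
                f"SNP {panel.snp_map['id'].iloc[j]} is all-missing; dropped",
                stacklevel=2,
            )
            continue
        keep.append(j)
        if miss.any():
            counts = np.bincount(col[~miss].astype(int), minlength=3)
            col[miss] = float(np.argmax(counts))  # argmax takes the lowest dosage on ties
    logger.info("imputed %d missing calls by per-SNP mode", n_missing)
    return GenotypePanel(
        dosages=dosages[:, keep],
        snp_map=panel.snp_map.iloc[keep].reset_index(drop=True),
        individuals=panel.individuals.copy(),
    )
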