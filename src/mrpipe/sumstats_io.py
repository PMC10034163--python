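"""Reading, validating and writing GWAS summary statistics and auxiliary tables.

All files are tab-separated UTF-8 text with a header row. Missing allele
frequency and sample size are encoded as ``NA``. Column names of summary-stat
files are adapted through a schema mapping so arbitrary source headers can be
read without rewriting files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "SummaryStats",
    "ReferencePanel",
    "AnnotationCatalog",
    "SumstatsError",
    "DEFAULT_SCHEMA",
    "read_sumstats",
    "write_sumstats",
    "read_reference_panel",
    "read_annotation_catalog",
    "write_results_table",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical field -> default file column name
DEFAULT_SCHEMA: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

#: canonical column order of the in-memory summary-stat table
SUMSTAT_COLUMNS = list(DEFAULT_SCHEMA)


class SumstatsError(ValueError):
    """Raised for unreadable or structurally invalid input files."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal GWAS association.

    ``beta`` is the effect per copy of ``effect_allele``; ``eaf`` its
    frequency (may be missing, encoded as NaN); positions are 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def is_valid(self) -> bool:
        return not self.invalid_reason()

    def invalid_reason(self) -> str | None:
        """Return why this record violates the row invariants, or None."""
        if self.effect_allele not in VALID_ALLELES:
            return f"effect_allele {self.effect_allele!r} not in A/C/G/T"
        if self.other_allele not in VALID_ALLELES:
            return f"other_allele {self.other_allele!r} not in A/C/G/T"
        if self.effect_allele == self.other_allele:
            return "effect_allele == other_allele"
        if not (self.se > 0):
            return f"se={self.se} not > 0"
        if not (0 < self.pval <= 1):
            return f"pval={self.pval} not in (0,1]"
        if not math.isnan(self.eaf) and not (0 <= self.eaf <= 1):
            return f"eaf={self.eaf} not in [0,1]"
        if not math.isnan(self.n) and not (self.n > 0):
            return f"n={self.n} not > 0"
        return None


@dataclass
class SummaryStats:
    """A trait's full set of variant associations plus trait metadata.

    The table uses the canonical columns of :data:`SUMSTAT_COLUMNS` and is
    unique by ``variant_id``.
    """

    trait_id: str
    trait_type: str  # "microbe_taxon" or "protein"
    table: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        dup = self.table["variant_id"].duplicated()
        if dup.any():
            name = self.table.loc[dup, "variant_id"].iloc[0]
            raise SumstatsError(f"duplicate variant_id {name!r} in {self.trait_id}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> Iterator[VariantAssociation]:
        for row in self.table.itertuples(index=False):
            yield VariantAssociation(
                row.variant_id, row.chrom, int(row.pos), row.effect_allele,
                row.other_allele, float(row.eaf), float(row.beta),
                float(row.se), float(row.pval), float(row.n),
            )

    def replace_table(self, table: pd.DataFrame) -> "SummaryStats":
        """New SummaryStats sharing metadata but with a different table."""
        return SummaryStats(self.trait_id, self.trait_type, table.reset_index(drop=True),
                            self.n_rejected)


@dataclass
class ReferencePanel:
    """Genotype reference panel: variants x individuals, coded 0/1/2."""

    variants: pd.DataFrame           # variant_id, chrom, pos
    genotypes: np.ndarray            # shape (n_variants, n_individuals), int
    monomorphic: np.ndarray          # boolean per variant
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def genotype(self, variant_id: str) -> np.ndarray:
        return self.genotypes[self._index[variant_id]]

    def r2(self, id_a: str, id_b: str) -> float:
        """Squared Pearson correlation of 0/1/2 genotype codes.

        The standard composite-LD estimate when phase is unknown; 0.0 for a
        monomorphic variant (zero variance).
        """
        ga = self.genotypes[self._index[id_a]].astype(float)
        gb = self.genotypes[self._index[id_b]].astype(float)
        va, vb = ga.var(), gb.var()
        if va == 0 or vb == 0:
            return 0.0
        cov = ((ga - ga.mean()) * (gb - gb.mean())).mean()
        return float(cov * cov / (va * vb))


@dataclass
class AnnotationCatalog:
    """Local variant-annotation catalog.

    Stands in for external trait-association / regulatory-annotation /
    frequency lookups: one row per (variant, trait) association plus
    per-variant eQTL, regulatory-annotation and reference-frequency fields.
    """

    table: pd.DataFrame  # SNP, TRAIT, P, IS_EQTL, REGULOME_ANNOTATED, EAF_REF[, EA_REF]

    def trait_associations(self, variant_id: str) -> pd.DataFrame:
        sub = self.table[self.table["SNP"] == variant_id]
        return sub[sub["TRAIT"].notna() & sub["P"].notna()][["TRAIT", "P"]]

    def _first(self, variant_id: str, column: str):
        sub = self.table.loc[self.table["SNP"] == variant_id, column]
        sub = sub[sub.notna()]
        return None if sub.empty else sub.iloc[0]

    def is_eqtl(self, variant_id: str) -> bool:
        return bool(self._first(variant_id, "IS_EQTL"))

    def regulome_annotated(self, variant_id: str) -> bool:
        return bool(self._first(variant_id, "REGULOME_ANNOTATED"))

    def eaf_reference(self, variant_id: str) -> tuple[float, str | None] | None:
        """Reference allele frequency and the allele it refers to, if known."""
        eaf = self._first(variant_id, "EAF_REF")
        if eaf is None:
            return None
        allele = self._first(variant_id, "EA_REF") if "EA_REF" in self.table else None
        return float(eaf), (str(allele) if allele is not None else None)


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise SumstatsError(f"no such file: {p}")
    return p


def read_sumstats(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_type: str = "microbe_taxon",
) -> SummaryStats:
    """Read a TSV of GWAS summary statistics into a validated SummaryStats.

    ``schema`` maps canonical field names (see :data:`DEFAULT_SCHEMA`) to the
    file's column names; omitted fields fall back to the defaults. Rows
    violating the per-row invariants are rejected and counted in
    ``n_rejected``; a duplicated variant_id or zero valid rows is fatal.
    """
    p = _require(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(p, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in colmap.values() if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{p}: missing mapped column(s) {missing}; header is {list(raw.columns)}")

    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["pos"].notna()
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & (df["n"].isna() | (df["n"] > 0))
    )
    n_rejected = int((~ok).sum())
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise SumstatsError(f"{p}: no valid rows after filtering ({n_rejected} rejected)")
    df["pos"] = df["pos"].astype(np.int64)

    dup = df["variant_id"].duplicated()
    if dup.any():
        raise SumstatsError(f"{p}: duplicated variant_id {df.loc[dup, 'variant_id'].iloc[0]!r}")
    return SummaryStats(trait_id or p.stem, trait_type, df, n_rejected=n_rejected)


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write a SummaryStats back to TSV under the default column names."""
    out = stats.table.rename(columns=DEFAULT_SCHEMA)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_reference_panel(path: str | Path) -> ReferencePanel:
    """Read a genotype reference panel TSV.

    First three columns are SNP/CHR/POS; every further column is one
    individual's 0/1/2 genotype. Any non-{0,1,2} entry is fatal; monomorphic
    variants are flagged but retained.
    """
    p = _require(path)
    raw = pd.read_csv(p, sep="\t")
    if raw.shape[1] < 4:
        raise SumstatsError(f"{p}: panel needs SNP/CHR/POS plus at least one genotype column")
    variants = raw.iloc[:, :3].copy()
    variants.columns = ["variant_id", "chrom", "pos"]
    variants["variant_id"] = variants["variant_id"].astype(str)
    variants["chrom"] = variants["chrom"].astype(str)
    geno = raw.iloc[:, 3:].to_numpy()
    if not np.isin(geno, (0, 1, 2)).all():
        bad = geno[~np.isin(geno, (0, 1, 2))].flat[0]
        raise SumstatsError(f"{p}: genotype entry {bad!r} is not 0/1/2")
    geno = geno.astype(np.int8)
    mono = geno.std(axis=1) == 0
    return ReferencePanel(variants.reset_index(drop=True), geno, mono)


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    meta = panel.variants.rename(columns={"variant_id": "SNP", "chrom": "CHR", "pos": "POS"})
    geno = pd.DataFrame(panel.genotypes,
                        columns=[f"IND{i + 1}" for i in range(panel.genotypes.shape[1])])
    pd.concat([meta.reset_index(drop=True), geno], axis=1).to_csv(path, sep="\t", index=False)


CATALOG_COLUMNS = ["SNP", "TRAIT", "P", "IS_EQTL", "REGULOME_ANNOTATED", "EAF_REF"]


def read_annotation_catalog(path: str | Path) -> AnnotationCatalog:
    """Read the variant annotation catalog TSV (multiple rows per SNP allowed).

    The optional EA_REF column names the allele EAF_REF refers to; without it
    the reference frequency is taken as already oriented to the summary-stat
    effect allele.
    """
    p = _require(path)
    df = pd.read_csv(p, sep="\t", na_values=["NA"])
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"{p}: catalog missing column(s) {missing}")
    bad = df["P"].notna() & ~((df["P"] > 0) & (df["P"] <= 1))
    if bad.any():
        raise SumstatsError(f"{p}: catalog pval outside (0,1] for SNP {df.loc[bad, 'SNP'].iloc[0]!r}")
    df["SNP"] = df["SNP"].astype(str)
    if "EA_REF" in df.columns:
        df["EA_REF"] = df["EA_REF"].astype("string").str.upper()
    return AnnotationCatalog(df)


def write_results_table(results, path: str | Path) -> None:
    """Write MR results to TSV: one row per (exposure, outcome, method).

    ``results`` is either a non-empty sequence of
    :class:`mrpipe.estimators.MRResult` or an already-assembled DataFrame
    (as produced by the pipeline).
    """
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise SumstatsError("results table is empty")
        results.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        return
    results = list(results)
    if not results:
        raise SumstatsError("no results to write")
    rows = []
    for r in results:
        row = {
            "exposure": r.extra.get("exposure", ""),
            "outcome": r.extra.get("outcome", ""),
            "method": r.method,
            "n_snp": r.n_snp,
            "beta": r.beta,
            "se": r.se,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pval": r.pval,
            "p_fdr": r.extra.get("p_fdr", np.nan),
            "n_outliers_removed": r.extra.get("n_outliers_removed", 0),
            "egger_intercept": r.extra.get("intercept", np.nan),
            "egger_intercept_pval": r.extra.get("intercept_pval", np.nan),
            "q": r.extra.get("Q", np.nan),
            "q_pval": r.extra.get("Q_pval", np.nan),
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
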