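"""Instrument selection for one exposure under a named threshold profile.

The selection cascade: p-value screen, LD clumping against a reference
panel, allele-frequency supplementation from a local catalog, a confounder
screen over past trait associations, an annotation-based pQTL filter for
protein exposures, and per-variant instrument-strength metrics (F statistic
and variance explained) with a weak-instrument cutoff. Every filter logs what
it removed so the provenance of the final instrument set is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats_io import AnnotationCatalog, ReferencePanel, SummaryStats, VariantAssociation

__all__ = [
    "ThresholdProfile",
    "InstrumentSet",
    "FilterRecord",
    "filter_by_pvalue",
    "ld_clump",
    "f_statistic",
    "variance_explained",
    "filter_weak_instruments",
    "screen_confounders",
    "supplement_eaf",
    "filter_pqtl_instruments",
    "select_instruments",
]

DEFAULT_CONFOUNDER_TERMS = ("cancer", "tumor", "tumour")


@dataclass(frozen=True)
class ThresholdProfile:
    """A named instrument-selection stringency.

    ``loose`` (p < 1e-5, clump r2 < 0.01) is the exploratory profile common
    in microbiome MR, where genome-wide-significant signals are scarce;
    ``strict`` (p < 5e-6, clump r2 < 0.001) is the validation profile. Both
    clump within a +/-10,000 kb window.
    """

    name: str
    p_threshold: float
    clump_r2: float
    clump_window_kb: int = 10_000

    @classmethod
    def loose(cls) -> "ThresholdProfile":
        return cls("loose", 1e-5, 0.01, 10_000)

    @classmethod
    def strict(cls) -> "ThresholdProfile":
        return cls("strict", 5e-6, 0.001, 10_000)

    @classmethod
    def named(cls, name: str) -> "ThresholdProfile":
        try:
            return {"loose": cls.loose, "strict": cls.strict}[name]()
        except KeyError:
            raise ValueError(f"unknown profile {name!r}; expected loose or strict") from None


@dataclass(frozen=True)
class FilterRecord:
    """One filter step's effect on the candidate set."""

    step: str
    n_before: int
    n_after: int
    removed_ids: tuple[str, ...]


@dataclass
class InstrumentSet:
    """Selected instruments with strength metrics and a provenance log."""

    exposure_id: str
    profile: ThresholdProfile
    stats: SummaryStats
    f_stats: pd.Series          # per-variant F, indexed by variant_id
    r2_explained: pd.Series     # per-variant variance explained (NaN if eaf missing)
    provenance: list[FilterRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.stats)


def _beta_se(v) -> tuple[float, float]:
    if isinstance(v, VariantAssociation):
        return v.beta, v.se
    return float(v[0]), float(v[1])


def f_statistic(v) -> float:
    """Per-variant instrument strength F = beta^2 / se^2.

    Accepts a VariantAssociation or a (beta, se) pair. Sign-invariant; F >= 10
    is the conventional weak-instrument screen.
    """
    beta, se = _beta_se(v)
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return beta * beta / (se * se)


def variance_explained(v) -> float:
    """Variance in the exposure explained by one variant: 2 f (1-f) beta^2.

    Assumes a variance-standardised trait; requires the effect-allele
    frequency (run supplement_eaf first if it is missing).
    """
    if isinstance(v, VariantAssociation):
        eaf, beta = v.eaf, v.beta
    else:
        eaf, beta = float(v[0]), float(v[1])
    if eaf is None or np.isnan(eaf):
        raise ValueError("eaf is missing; run supplement_eaf before variance_explained")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def _record(log: list[FilterRecord] | None, step: str, before: pd.DataFrame,
            after: pd.DataFrame) -> None:
    if log is None:
        return
    removed = tuple(before.loc[~before["variant_id"].isin(after["variant_id"]), "variant_id"])
    log.append(FilterRecord(step, len(before), len(after), removed))


def filter_by_pvalue(stats: SummaryStats, profile: ThresholdProfile,
                     log: list[FilterRecord] | None = None) -> SummaryStats:
    """Keep variants with pval strictly below the profile threshold (order kept)."""
    table = stats.table
    out = table[table["pval"] < profile.p_threshold]
    _record(log, f"pvalue<{profile.p_threshold:g}", table, out)
    return stats.replace_table(out)


def ld_clump(stats: SummaryStats, panel: ReferencePanel, profile: ThresholdProfile,
             log: list[FilterRecord] | None = None) -> SummaryStats:
    """Greedy LD clumping against the reference panel.

    Repeatedly take the remaining variant with the smallest p-value as index
    (ties broken by chromosome then position) and discard all remaining
    variants on the same chromosome within +/-clump_window_kb whose panel
    genotype r^2 with the index exceeds clump_r2. Variants absent from the
    panel are dropped with a warning before clumping.
    """
    table = stats.table
    in_panel = table["variant_id"].apply(lambda v: v in panel)
    if not in_panel.all():
        missing = list(table.loc[~in_panel, "variant_id"])
        warnings.warn(f"{len(missing)} variant(s) absent from reference panel, dropped: {missing[:5]}")
    work = table[in_panel].copy()

    chrom_order = pd.to_numeric(work["chrom"], errors="coerce").fillna(np.inf)
    order = work.assign(_c=chrom_order).sort_values(
        ["pval", "_c", "chrom", "pos"], kind="mergesort").index
    window_bp = profile.clump_window_kb * 1_000

    alive = set(order)
    kept: list = []
    for idx in order:
        if idx not in alive:
            continue
        kept.append(idx)
        alive.discard(idx)
        row = work.loc[idx]
        for other in list(alive):
            orow = work.loc[other]
            if orow["chrom"] != row["chrom"]:
                continue
            if abs(int(orow["pos"]) - int(row["pos"])) > window_bp:
                continue
            if panel.r2(row["variant_id"], orow["variant_id"]) > profile.clump_r2:
                alive.discard(other)

    out = work.loc[sorted(kept)]  # original row order
    _record(log, f"ld_clump(r2<{profile.clump_r2:g},{profile.clump_window_kb}kb)", table, out)
    return stats.replace_table(out)


def add_strength_metrics(stats: SummaryStats) -> tuple[pd.Series, pd.Series]:
    """Per-variant F statistic and variance explained, indexed by variant_id."""
    t = stats.table
    f_stats = pd.Series((t["beta"] ** 2 / t["se"] ** 2).to_numpy(),
                        index=t["variant_id"], name="F")
    r2 = pd.Series((2.0 * t["eaf"] * (1.0 - t["eaf"]) * t["beta"] ** 2).to_numpy(),
                   index=t["variant_id"], name="r2_explained")
    return f_stats, r2


def filter_weak_instruments(stats: SummaryStats, min_f: float = 10.0,
                            log: list[FilterRecord] | None = None) -> SummaryStats:
    """Keep variants with F >= min_f (boundary inclusive)."""
    table = stats.table
    f = table["beta"] ** 2 / table["se"] ** 2
    out = table[f >= min_f]
    _record(log, f"F>={min_f:g}", table, out)
    return stats.replace_table(out)


def screen_confounders(stats: SummaryStats, catalog: AnnotationCatalog,
                       p_assoc: float = 5e-8,
                       confounder_terms: Sequence[str] = DEFAULT_CONFOUNDER_TERMS,
                       log: list[FilterRecord] | None = None) -> SummaryStats:
    """Remove variants with a past confounder-trait association below p_assoc.

    A variant is removed when the catalog holds any trait association with
    pval < p_assoc whose trait name contains a confounder term
    (case-insensitive substring). Variants absent from the catalog pass.
    """
    table = stats.table
    terms = [t.lower() for t in confounder_terms]

    def confounded(variant_id: str) -> bool:
        assoc = catalog.trait_associations(variant_id)
        if assoc.empty:
            return False
        hits = assoc[assoc["P"] < p_assoc]
        return any(any(term in str(trait).lower() for term in terms) for trait in hits["TRAIT"])

    out = table[~table["variant_id"].map(confounded)]
    _record(log, f"confounder_screen(p<{p_assoc:g})", table, out)
    return stats.replace_table(out)


def supplement_eaf(stats: SummaryStats, catalog: AnnotationCatalog,
                   log: list[FilterRecord] | None = None) -> SummaryStats:
    """Fill missing effect-allele frequencies from the catalog.

    The catalog frequency is matched on variant_id and, when the catalog
    names the allele it refers to, oriented to the summary-stat effect
    allele (complemented if it refers to the other allele; left missing if
    it matches neither). Rows still missing eaf afterwards are flagged in
    the log but retained.
    """
    table = stats.table.copy()
    still_missing: list[str] = []
    for i in table.index[table["eaf"].isna()]:
        vid = table.at[i, "variant_id"]
        ref = catalog.eaf_reference(vid)
        if ref is None:
            still_missing.append(vid)
            continue
        eaf_ref, allele = ref
        if allele is None or allele == table.at[i, "effect_allele"]:
            table.at[i, "eaf"] = eaf_ref
        elif allele == table.at[i, "other_allele"]:
            table.at[i, "eaf"] = 1.0 - eaf_ref
        else:
            still_missing.append(vid)
    if log is not None:
        log.append(FilterRecord(
            "supplement_eaf(still_missing)", len(table), len(table), tuple(still_missing)))
    return stats.replace_table(table)


def filter_pqtl_instruments(stats: SummaryStats, catalog: AnnotationCatalog,
                            log: list[FilterRecord] | None = None) -> SummaryStats:
    """Keep only annotated, non-eQTL variants (cis-pQTL screen).

    A protein instrument must carry a regulatory annotation in the catalog
    and must not be an eQTL; unannotated variants are removed.
    """
    table = stats.table

    def keep(variant_id: str) -> bool:
        return catalog.regulome_annotated(variant_id) and not catalog.is_eqtl(variant_id)

    out = table[table["variant_id"].map(keep)]
    _record(log, "pqtl_annotation_filter", table, out)
    return stats.replace_table(out)


def select_instruments(
    stats: SummaryStats,
    profile: ThresholdProfile,
    panel: ReferencePanel | None = None,
    catalog: AnnotationCatalog | None = None,
    min_f: float = 10.0,
    p_assoc: float = 5e-8,
    confounder_terms: Sequence[str] = DEFAULT_CONFOUNDER_TERMS,
    pqtl_filter: bool | None = None,
) -> InstrumentSet:
    """Run the full selection cascade and return an InstrumentSet.

    Order: frequency supplementation (before clumping), p-value screen,
    LD clumping (if a panel is given), confounder screen, pQTL annotation
    filter (by default only for protein exposures, and only when a catalog
    is given), weak-instrument filter. Each step appends to the provenance
    log; empty intermediate results are allowed and flagged downstream by
    the minimum-IV rule.
    """
    log: list[FilterRecord] = []
    cur = stats
    if catalog is not None:
        cur = supplement_eaf(cur, catalog, log)
    cur = filter_by_pvalue(cur, profile, log)
    if panel is not None and len(cur):
        cur = ld_clump(cur, panel, profile, log)
    if catalog is not None and len(cur):
        cur = screen_confounders(cur, catalog, p_assoc, confounder_terms, log)
    if pqtl_filter is None:
        pqtl_filter = stats.trait_type == "protein"
    if pqtl_filter and catalog is not None and len(cur):
        cur = filter_pqtl_instruments(cur, catalog, log)
    if len(cur):
        cur = filter_weak_instruments(cur, min_f, log)
    f_stats, r2 = add_strength_metrics(cur) if len(cur) else (pd.Series(dtype=float), pd.Series(dtype=float))
    return InstrumentSet(stats.trait_id, profile, cur, f_stats, r2, log)
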