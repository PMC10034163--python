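"""Orchestration of the bidirectional MR analysis plus FDR and power.

For every exposure/outcome combination, under each configured threshold
profile and direction, the pipeline runs instrument selection,
harmonization, the intermediate-allele-frequency exclusion, radial/RSS
outlier removal, all five estimators and the diagnostic battery; pairs
falling below the minimum instrument count at any stage are excluded with
the reason recorded. IVW p-values are then Benjamini-Hochberg adjusted —
by default within each pair across the five methods — and a pair is labeled
significant when its primary IVW adjusted p-value is below ``fdr_alpha``.
The primary IVW variant follows the protocol's switching rule (random
effects when J > 4 or no heterogeneity at Q-p >= 0.10, otherwise fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .estimators import MRResult, estimate_all, ivw
from .harmonize import HarmonizedSet, drop_intermediate_palindromes, harmonize
from .iv_selection import InstrumentSet, ThresholdProfile, select_instruments
from .sensitivity import cochran_q, leave_one_out, mr_presso, remove_outliers
from .sumstats_io import AnnotationCatalog, ReferencePanel, SummaryStats

__all__ = ["AnalysisConfig", "PowerInput", "PairOutcome", "run_pair",
           "run_bidirectional", "fdr_adjust", "mr_power",
           "minimum_detectable_effect"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by every pair in one bidirectional run."""

    direction: str = "both"                  # forward | reverse | both
    profiles: tuple[ThresholdProfile, ...] = (ThresholdProfile.loose(),)
    fdr_alpha: float = 0.05
    fdr_family: str = "per_pair_methods"     # or per_outcome_exposures
    min_iv: int = 3
    min_f: float = 10.0
    maf_limit: float = 0.42
    ivw_mode: str = "auto"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0,1)")
        if self.min_iv < 3:
            raise ValueError("min_iv must be >= 3")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.fdr_family not in ("per_pair_methods", "per_outcome_exposures"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")


@dataclass(frozen=True)
class PowerInput:
    """Inputs of the analytic power calculation for a continuous outcome."""

    n: int                 # outcome sample size
    r2: float              # variance in exposure explained by the instruments
    beta: float            # hypothesized causal effect (sd units)
    alpha: float = 0.05

    def validate(self) -> None:
        if not (0 < self.r2 < 1):
            raise ValueError("r2 must be in (0,1)")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")


@dataclass
class PairOutcome:
    """Everything one exposure/outcome/profile/direction analysis produced."""

    exposure_id: str
    outcome_id: str
    direction: str
    profile: ThresholdProfile
    excluded: bool = False
    exclusion_reason: str = ""
    instruments: InstrumentSet | None = None
    hset: HarmonizedSet | None = None
    results: list[MRResult] = field(default_factory=list)
    primary_method: str = ""
    outliers_removed: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)


def mr_power(inp: PowerInput) -> float:
    """Analytic power of the two-sided Wald test of the IVW estimate.

    power = Phi( sqrt(n r2) |beta| - z_{1-alpha/2} ): the noncentrality of
    the causal-effect z statistic is sqrt(n r2) beta for a variance-1
    exposure and outcome.
    """
    inp.validate()
    z_crit = sps.norm.ppf(1.0 - inp.alpha / 2.0)
    return float(sps.norm.cdf(np.sqrt(inp.n * inp.r2) * abs(inp.beta) - z_crit))


def minimum_detectable_effect(n: int, r2: float, target_power: float = 0.8,
                              alpha: float = 0.05) -> float:
    """Causal effect detectable with the requested power (inverts mr_power)."""
    PowerInput(n, r2, 1.0, alpha).validate()
    if not (alpha < target_power < 1):
        raise ValueError("target_power must be in (alpha, 1)")
    z_pow = sps.norm.ppf(target_power)
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    return float((z_pow + z_crit) / np.sqrt(n * r2))


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("pvals must be in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _choose_primary(results: list[MRResult], hset: HarmonizedSet, mode: str) -> str:
    """Label of the primary IVW row per the switching rule (or an override)."""
    if mode in ("fixed", "random"):
        return "ivw_fe" if mode == "fixed" else "ivw_re"
    fe = next(r for r in results if r.method == "ivw_fe")
    J = len(hset)
    return "ivw_re" if (J > 4 or fe.extra["Q_pval"] >= 0.10) else "ivw_fe"


def run_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    profile: ThresholdProfile,
    config: AnalysisConfig,
    panel: ReferencePanel | None = None,
    catalog: AnnotationCatalog | None = None,
    direction: str = "forward",
) -> PairOutcome:
    """Run one exposure -> outcome analysis under one threshold profile.

    Stages: select instruments (p-value, clumping, confounder/pQTL screens,
    F >= min_f) -> harmonize -> intermediate-palindrome exclusion -> outlier
    removal -> five estimators -> Q / Egger-intercept / RSS-global /
    leave-one-out diagnostics. A pair whose instrument count drops below
    ``config.min_iv`` at any stage is excluded with the reason recorded, not
    raised.
    """
    config.validate()
    po = PairOutcome(exposure.trait_id, outcome.trait_id, direction, profile)

    iv_set = select_instruments(exposure, profile, panel=panel, catalog=catalog,
                                min_f=config.min_f)
    po.instruments = iv_set
    if len(iv_set) < config.min_iv:
        po.excluded, po.exclusion_reason = True, f"IVs < {config.min_iv} after selection"
        return po

    hset = harmonize(iv_set.stats, outcome, direction)
    hset = drop_intermediate_palindromes(hset, maf_limit=config.maf_limit)
    if len(hset) < config.min_iv:
        po.excluded, po.exclusion_reason = True, f"IVs < {config.min_iv} after harmonization"
        po.hset = hset
        return po

    hset, removed = remove_outliers(hset, n_sim=config.presso_n_sim, seed=config.seed)
    po.outliers_removed = removed
    if len(hset) < config.min_iv:
        po.excluded, po.exclusion_reason = True, f"IVs < {config.min_iv} after outlier removal"
        po.hset = hset
        return po
    po.hset = hset

    po.results = estimate_all(hset, n_boot=config.n_boot, seed=config.seed)
    po.primary_method = _choose_primary(po.results, hset, config.ivw_mode)

    q = cochran_q(hset)
    egger = next(r for r in po.results if r.method == "egger")
    diag = {
        "Q": q.Q, "Q_df": q.df, "Q_pval": q.pval,
        "egger_intercept": egger.extra["intercept"],
        "egger_intercept_pval": egger.extra["intercept_pval"],
        "loo_robust": leave_one_out(hset, config.ivw_mode).robust,
    }
    if len(hset) >= 4:
        presso = mr_presso(hset, n_sim=config.presso_n_sim, seed=config.seed)
        diag["presso_global_pval"] = presso.global_pval
        diag["presso_distortion_pval"] = presso.distortion_pval
    po.diagnostics = diag
    return po


def _result_rows(po: PairOutcome) -> list[dict]:
    rows = []
    for r in po.results:
        rows.append({
            "exposure": po.exposure_id, "outcome": po.outcome_id,
            "direction": po.direction, "profile": po.profile.name,
            "method": r.method, "primary": r.method == po.primary_method,
            "n_snp": r.n_snp, "n_outliers_removed": len(po.outliers_removed),
            "beta": r.beta, "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "pval": r.pval,
            "q_pval": po.diagnostics.get("Q_pval", np.nan),
            "egger_intercept_pval": po.diagnostics.get("egger_intercept_pval", np.nan),
            "presso_global_pval": po.diagnostics.get("presso_global_pval", np.nan),
            "loo_robust": po.diagnostics.get("loo_robust", np.nan),
        })
    return rows


def run_bidirectional(
    exposures: Sequence[SummaryStats],
    outcomes: Sequence[SummaryStats],
    config: AnalysisConfig,
    panel: ReferencePanel | None = None,
    catalog: AnnotationCatalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every combination in the configured directions and profiles.

    Returns (results, exclusions). ``results`` has one row per estimator per
    analysed combination with BH-adjusted IVW significance; ``exclusions``
    one row per combination that fell below the minimum-IV rule, so every
    (exposure, outcome, profile, direction) combination appears in exactly
    one of the two tables.
    """
    config.validate()
    if not exposures or not outcomes:
        raise ValueError("need at least one exposure and one outcome")
    directions = {"forward": ["forward"], "reverse": ["reverse"],
                  "both": ["forward", "reverse"]}[config.direction]

    rows: list[dict] = []
    excl: list[dict] = []
    for profile in config.profiles:
        for direction in directions:
            pairs = [(e, o) for e in exposures for o in outcomes]
            if direction == "reverse":
                pairs = [(o, e) for e in exposures for o in outcomes]
            for exp, out in pairs:
                po = run_pair(exp, out, profile, config, panel=panel,
                              catalog=catalog, direction=direction)
                if po.excluded:
                    excl.append({"exposure": po.exposure_id, "outcome": po.outcome_id,
                                 "direction": direction, "profile": profile.name,
                                 "reason": po.exclusion_reason})
                else:
                    rows.extend(_result_rows(po))

    results = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["exposure", "outcome", "direction",
                                             "profile", "reason"])
    if results.empty:
        return results, exclusions

    results["p_fdr"] = np.nan
    if config.fdr_family == "per_pair_methods":
        keys = ["exposure", "outcome", "direction", "profile"]
        for _, idx in results.groupby(keys).groups.items():
            results.loc[idx, "p_fdr"] = fdr_adjust(results.loc[idx, "pval"])
    else:  # per_outcome_exposures: adjust primary-IVW p-values across exposures
        keys = ["outcome", "direction", "profile", "method"]
        for _, idx in results.groupby(keys).groups.items():
            results.loc[idx, "p_fdr"] = fdr_adjust(results.loc[idx, "pval"])

    primary = results["primary"]
    results["significant"] = primary & (results["p_fdr"] < config.fdr_alpha)
    return results, exclusions
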