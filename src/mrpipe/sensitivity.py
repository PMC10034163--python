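"""Heterogeneity, outlier and robustness diagnostics for an instrument set.

Cochran's Q with per-variant contributions, the radial reformulation for
per-variant outlier flags (Bonferroni alpha = 0.05/J by default), a
simulation-based residual-sum-of-squares test for horizontal pleiotropy with
global / per-variant outlier / distortion components, and leave-one-out
re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .estimators import MRResult, ivw, ratio_estimates
from .harmonize import HarmonizedSet

__all__ = ["QResult", "RadialResult", "PressoResult", "LeaveOneOutResult",
           "cochran_q", "radial_scan", "mr_presso", "leave_one_out",
           "remove_outliers"]


@dataclass(frozen=True)
class QResult:
    """Cochran's Q with its chi-square p-value and per-variant contributions."""

    Q: float
    df: int
    pval: float
    per_variant_q: np.ndarray
    variant_ids: np.ndarray

    @property
    def heterogeneous(self) -> bool:
        """Significant heterogeneity at the conventional p < 0.10 level."""
        return self.pval < 0.10


@dataclass(frozen=True)
class RadialResult:
    """Radial-MR scan: slope, Q decomposition and Bonferroni outlier flags."""

    slope: float
    q: QResult
    outlier_ids: tuple[str, ...]
    alpha_used: float


@dataclass(frozen=True)
class PressoResult:
    """Global, per-variant-outlier and distortion components of the RSS test."""

    global_rss_obs: float
    global_pval: float
    per_variant_pvals: np.ndarray
    variant_ids: np.ndarray
    outlier_ids: tuple[str, ...]
    beta_raw: float
    beta_corrected: float
    distortion_pval: float
    n_sim: int
    seed: int | None


@dataclass(frozen=True)
class LeaveOneOutResult:
    """J re-estimates, each omitting one variant, plus a robustness flag.

    ``robust`` is true when every leave-one-out estimate keeps the sign of
    the full estimate and every leave-one-out CI overlaps the full CI.
    """

    full: MRResult
    results: list[MRResult] = field(default_factory=list)
    omitted_ids: tuple[str, ...] = ()
    robust: bool = True


def _ivw_point(b: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * b) / np.sum(w))


def cochran_q(hset: HarmonizedSet) -> QResult:
    """Cochran's Q about the fixed-effects IVW estimate, chi-square on J-1 df."""
    if len(hset) < 2:
        raise ValueError("cochran_q needs at least 2 instruments")
    b, w, _ = ratio_estimates(hset)
    beta = _ivw_point(b, w)
    qj = w * (b - beta) ** 2
    Q = float(qj.sum())
    df = len(b) - 1
    return QResult(Q, df, float(sps.chi2.sf(Q, df)), qj, hset.variant_ids)


def radial_scan(hset: HarmonizedSet, alpha_per_snp: str = "bonferroni",
                alpha: float = 0.05) -> RadialResult:
    """Radial-MR outlier scan.

    Regressing b_j*sqrt(w_j) on sqrt(w_j) through the origin gives a slope
    identical to the fixed-effects IVW estimate under first-order weights;
    each variant's heterogeneity contribution Q_j = w_j (b_j - slope)^2 is
    referred to chi-square(1) and flagged when its upper tail falls below
    alpha/J (``bonferroni``) or below alpha unadjusted (``fixed``).
    """
    if len(hset) < 3:
        raise ValueError("radial_scan needs at least 3 instruments")
    b, w, _ = ratio_estimates(hset)
    J = len(b)
    slope = _ivw_point(b, w)  # radial through-origin slope == IVW (first-order)
    qj = w * (b - slope) ** 2
    pj = sps.chi2.sf(qj, 1)
    cut = alpha / J if alpha_per_snp == "bonferroni" else alpha
    out = tuple(hset.variant_ids[pj < cut])
    q = QResult(float(qj.sum()), J - 1, float(sps.chi2.sf(qj.sum(), J - 1)),
                qj, hset.variant_ids)
    return RadialResult(slope, q, out, cut)


def _loo_betas(b: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW point estimates leaving each variant out, vectorized."""
    sw, swb = np.sum(w), np.sum(w * b)
    return (swb - w * b) / (sw - w)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = 0,
              outlier_alpha: float | None = None) -> PressoResult:
    """Simulation-based pleiotropy residual-sum-of-squares and outlier test.

    Global test: the observed RSS sums w_j (b_j - beta_{-j})^2 over
    leave-one-out IVW estimates beta_{-j}; its null distribution is built by
    redrawing Gamma*_j ~ Normal(gamma_j beta_{-j}, se_Gamma_j^2) and
    gamma*_j ~ Normal(gamma_j, se_gamma_j^2) and recomputing the RSS n_sim
    times. Outlier test: each variant's observed residual term against its
    simulated counterparts, Bonferroni-thresholded at 0.05/J unless
    ``outlier_alpha`` overrides. Distortion test: the shift from the raw to
    the outlier-corrected IVW estimate against the displacement distribution
    obtained by removing equally many randomly chosen variants. Empirical
    p-values carry a +1/(n+1) continuity correction, so they are never 0.
    """
    J = len(hset)
    if J < 4:
        raise ValueError("mr_presso needs at least 4 instruments")
    rng = np.random.default_rng(seed)
    gamma, se_g = hset.gamma, hset.se_gamma
    b, w, _ = ratio_estimates(hset)
    se_G = hset.se_Gamma
    if outlier_alpha is None:
        outlier_alpha = 0.05 / J

    beta_loo = _loo_betas(b, w)
    res_obs = w * (b - beta_loo) ** 2
    rss_obs = float(res_obs.sum())

    # parametric null: regenerate both sides' effects under the no-pleiotropy
    # model centred on the leave-one-out estimates
    G_star = rng.normal(gamma * beta_loo, se_G, size=(n_sim, J))
    g_star = rng.normal(gamma, se_g, size=(n_sim, J))
    b_star = G_star / g_star
    w_star = g_star ** 2 / se_G ** 2
    sw = w_star.sum(axis=1, keepdims=True)
    swb = (w_star * b_star).sum(axis=1, keepdims=True)
    beta_loo_star = (swb - w_star * b_star) / (sw - w_star)
    res_star = w_star * (b_star - beta_loo_star) ** 2
    rss_star = res_star.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_variant = (1 + np.sum(res_star >= res_obs[None, :], axis=0)) / (n_sim + 1)
    outliers = tuple(hset.variant_ids[per_variant < outlier_alpha])

    beta_raw = _ivw_point(b, w)
    if outliers and J - len(outliers) >= 2:
        keep = ~np.isin(hset.variant_ids, outliers)
        beta_corrected = _ivw_point(b[keep], w[keep])
        n_out = len(outliers)
        # displacement null: remove n_out random variants and re-estimate
        disp = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(J, size=n_out, replace=False)
            m = np.ones(J, dtype=bool)
            m[drop] = False
            disp[s] = _ivw_point(b[m], w[m]) - beta_raw
        observed = abs(beta_corrected - beta_raw)
        distortion_pval = float((1 + np.sum(np.abs(disp) >= observed)) / (n_sim + 1))
    else:
        beta_corrected = beta_raw if not outliers else float("nan")
        distortion_pval = float("nan")

    return PressoResult(rss_obs, global_pval, per_variant, hset.variant_ids,
                        outliers, beta_raw, float(beta_corrected),
                        distortion_pval, n_sim, seed)


def leave_one_out(hset: HarmonizedSet, ivw_mode: str = "auto") -> LeaveOneOutResult:
    """Re-estimate IVW omitting each variant in turn.

    Flags the analysis robust when all J estimates keep the full estimate's
    sign and their 95% CIs all overlap the full CI.
    """
    J = len(hset)
    if J < 3:
        raise ValueError("leave_one_out needs at least 3 instruments")
    full = ivw(hset, ivw_mode)
    results: list[MRResult] = []
    ids = hset.variant_ids
    for j in range(J):
        mask = np.ones(J, dtype=bool)
        mask[j] = False
        r = ivw(hset.subset(mask), ivw_mode)
        r = MRResult(r.method, r.beta, r.se, r.ci_low, r.ci_high, r.pval,
                     r.n_snp, {**r.extra, "omitted": ids[j]})
        results.append(r)
    same_sign = all(np.sign(r.beta) == np.sign(full.beta) or full.beta == 0
                    for r in results)
    overlap = all(r.ci_low <= full.ci_high and full.ci_low <= r.ci_high
                  for r in results)
    return LeaveOneOutResult(full, results, tuple(ids), bool(same_sign and overlap))


def remove_outliers(hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = 0
                    ) -> tuple[HarmonizedSet, tuple[str, ...]]:
    """Drop the union of radial and RSS-test outliers from the set.

    Returns the reduced set (removals logged with reason ``outlier``) and the
    removed ids. Sets too small for either scan are returned unchanged.
    """
    flagged: set[str] = set()
    if len(hset) >= 3:
        flagged |= set(radial_scan(hset).outlier_ids)
    if len(hset) >= 4:
        flagged |= set(mr_presso(hset, n_sim=n_sim, seed=seed).outlier_ids)
    if not flagged:
        return hset, ()
    return hset.drop(sorted(flagged), "outlier"), tuple(sorted(flagged))
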