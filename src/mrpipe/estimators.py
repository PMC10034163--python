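"""Causal-effect estimators for two-sample MR on a harmonized instrument set.

Five estimators over per-variant Wald ratios b_j = Gamma_j / gamma_j with
first-order inverse-variance weights w_j = gamma_j^2 / se_Gamma_j^2 (the
exposure-side error is ignored in the weights, the convention of standard
two-sample MR software):

* fixed-effects IVW — beta = sum(w b) / sum(w), se = (sum w)^{-1/2};
* multiplicative random-effects IVW — the fixed-effects se scaled by
  sqrt(max(1, Q/(J-1))) where Q is Cochran's heterogeneity statistic;
* MR-Egger — weighted regression of Gamma on gamma with a free intercept
  after orienting every gamma_j positive; a nonzero intercept indicates
  directional pleiotropy (InSIDE assumption), inference on t with J-2 df;
* weighted median — the 50% point of the weighted empirical distribution of
  ratio estimates, consistent while valid instruments carry >50% of weight;
* weighted mode — the argmax of a weighted Gaussian kernel density over the
  ratio estimates, consistent if the largest cluster of instruments is valid.

Standard errors for median and mode come from a parametric bootstrap
(resampling each b_j from Normal(b_j, se_bj)). All confidence intervals are
normal-theory beta +/- z_{0.975} * se, matching the reporting style of the
rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedSet

__all__ = ["MRResult", "wald_ratio", "ivw", "mr_egger", "weighted_median",
           "weighted_mode", "estimate_all"]

Z95 = float(sps.norm.ppf(0.975))


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal-effect estimate with normal-theory CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)


def _result(method: str, beta: float, se: float, pval: float, n_snp: int,
            extra: dict | None = None) -> MRResult:
    return MRResult(method, float(beta), float(se), float(beta - Z95 * se),
                    float(beta + Z95 * se), float(min(max(pval, 1e-300), 1.0)),
                    int(n_snp), extra or {})


def ratio_estimates(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant Wald ratios, first-order weights, and ratio SEs."""
    gamma, Gamma, se_G = hset.gamma, hset.Gamma, hset.se_Gamma
    if np.any(gamma == 0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    b = Gamma / gamma
    w = gamma ** 2 / se_G ** 2
    se_b = se_G / np.abs(gamma)
    return b, w, se_b


def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float) -> MRResult:
    """Single-variant causal estimate Gamma/gamma, first-order delta-method se."""
    if gamma == 0:
        raise ValueError("gamma = 0: Wald ratio undefined")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    pval = 2.0 * sps.norm.sf(abs(beta / se)) if se > 0 else 1.0
    return _result("wald", beta, se, pval, 1)


def cochran_q_value(b: np.ndarray, w: np.ndarray) -> float:
    beta = float(np.sum(w * b) / np.sum(w))
    return float(np.sum(w * (b - beta) ** 2))


def ivw(hset: HarmonizedSet, mode: str = "auto") -> MRResult:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``mode`` is ``fixed``, ``random`` (multiplicative random effects with the
    scale floored at 1), or ``auto``. The auto rule follows the source
    protocol as written: random effects when J > 4 or when Cochran's Q shows
    no heterogeneity at p >= 0.10, otherwise fixed effects.
    """
    if len(hset) < 2:
        raise ValueError("ivw needs at least 2 instruments")
    b, w, _ = ratio_estimates(hset)
    J = len(b)
    sw = float(np.sum(w))
    beta = float(np.sum(w * b) / sw)
    se_fixed = sw ** -0.5
    Q = float(np.sum(w * (b - beta) ** 2))
    q_pval = float(sps.chi2.sf(Q, J - 1))
    phi = max(1.0, Q / (J - 1))

    if mode == "auto":
        mode = "random" if (J > 4 or q_pval >= 0.10) else "fixed"
    if mode == "fixed":
        se, label = se_fixed, "ivw_fe"
    elif mode == "random":
        se, label = se_fixed * phi ** 0.5, "ivw_re"
    else:
        raise ValueError(f"unknown ivw mode {mode!r}")
    pval = 2.0 * sps.norm.sf(abs(beta / se))
    return _result(label, beta, se, pval, J,
                   {"Q": Q, "Q_df": J - 1, "Q_pval": q_pval, "phi": phi})


def mr_egger(hset: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of Gamma on gamma with intercept.

    Each pair is first oriented so gamma_j > 0 (both signs flipped where
    needed); weights are 1/se_Gamma^2. The slope is the causal estimate and
    the intercept its pleiotropy diagnostic, both tested on t with J-2 df.
    Solved by the closed-form 2x2 weighted normal equations.
    """
    J = len(hset)
    if J < 3:
        raise ValueError("mr_egger needs at least 3 instruments")
    sign = np.where(hset.gamma < 0, -1.0, 1.0)
    x = hset.gamma * sign
    y = hset.Gamma * sign
    w = 1.0 / hset.se_Gamma ** 2

    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det

    resid = y - intercept - slope * x
    # WLS dispersion on J-2 residual df; with well-calibrated weights this is
    # ~1 and the t tests below are exact under the no-pleiotropy null
    sigma2 = float(np.sum(w * resid ** 2) / (J - 2))
    se_slope = float(np.sqrt(sigma2 * sw / det))
    se_int = float(np.sqrt(sigma2 * swxx / det))

    def _t_pval(est: float, se: float) -> float:
        if se == 0:
            return 0.0 if est != 0 else 1.0
        return float(2.0 * sps.t.sf(abs(est / se), J - 2))

    p_slope = _t_pval(slope, se_slope)
    p_int = _t_pval(intercept, se_int)
    return _result("egger", slope, se_slope, p_slope, J,
                   {"intercept": float(intercept), "intercept_se": se_int,
                    "intercept_pval": float(p_int), "sigma2": sigma2})


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical distribution.

    With sorted ratios b_(1)<=...<=b_(J) and normalized weights w', the
    cumulative midpoint of rank j is s_j = sum_{k<=j} w'_k - w'_j/2; the
    estimate interpolates b over s at 0.5.
    """
    order = np.argsort(b, kind="stable")
    bs, ws = b[order], w[order] / np.sum(w)
    s = np.cumsum(ws) - ws / 2.0
    return float(np.interp(0.5, s, bs))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = 0) -> MRResult:
    """Weighted-median estimator, bootstrap se.

    Robust to up to 50% of weight on invalid instruments. The se is the
    standard deviation of the estimate over ``n_boot`` parametric resamples
    b_j* ~ Normal(b_j, se_bj); with n_boot=0 the se is NaN and only the
    point estimate is meaningful.
    """
    if len(hset) < 3:
        raise ValueError("weighted_median needs at least 3 instruments")
    b, w, se_b = ratio_estimates(hset)
    beta = _weighted_median_point(b, w)
    se = _bootstrap_se(_weighted_median_point, b, w, se_b, n_boot, seed)
    pval = 2.0 * sps.norm.sf(abs(beta / se)) if np.isfinite(se) and se > 0 else np.nan
    return _result("weighted_median", beta, se, np.nan_to_num(pval, nan=1.0), len(b))


def _weighted_mode_point(b: np.ndarray, w: np.ndarray,
                         bandwidth_factor: float = 1.0) -> float:
    """Argmax of the weighted Gaussian KDE over the ratio estimates.

    Bandwidth is the Silverman-style rule 0.9 min(sd, iqr/1.34) J^{-1/5}
    computed on the unweighted b_j, scaled by ``bandwidth_factor``; the
    density is evaluated on a 512-point grid spanning [min-3h, max+3h].
    Degenerate spread (all b identical) returns the common value.
    """
    J = len(b)
    sd = float(np.std(b, ddof=1)) if J > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(b, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * scale * J ** (-0.2)
    if h <= 0:
        return float(b[0])
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 512)
    wn = w / np.sum(w)
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ wn
    return float(grid[np.argmax(dens)])


def _bootstrap_se(point_fn, b, w, se_b, n_boot: int, seed, **kwargs) -> float:
    if n_boot <= 0:
        return float("nan")
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se_b, size=(n_boot, len(b)))
    est = np.array([point_fn(row, w, **kwargs) for row in draws])
    return float(np.std(est, ddof=1))


def weighted_mode(hset: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int | None = 0) -> MRResult:
    """Weighted-mode estimator (majority-cluster consistency), bootstrap se."""
    if len(hset) < 3:
        raise ValueError("weighted_mode needs at least 3 instruments")
    b, w, se_b = ratio_estimates(hset)
    beta = _weighted_mode_point(b, w, bandwidth_factor)
    se = _bootstrap_se(_weighted_mode_point, b, w, se_b, n_boot, seed,
                       bandwidth_factor=bandwidth_factor)
    pval = 2.0 * sps.norm.sf(abs(beta / se)) if np.isfinite(se) and se > 0 else np.nan
    return _result("weighted_mode", beta, se, np.nan_to_num(pval, nan=1.0), len(b))


def estimate_all(hset: HarmonizedSet, n_boot: int = 1000,
                 seed: int | None = 0) -> list[MRResult]:
    """All five estimators: both IVW variants, Egger, median, mode."""
    return [
        ivw(hset, "fixed"),
        ivw(hset, "random"),
        mr_egger(hset),
        weighted_median(hset, n_boot=n_boot, seed=seed),
        weighted_mode(hset, n_boot=n_boot, seed=seed),
    ]
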