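"""Synthetic paired exposure/outcome GWAS summary statistics with known truth.

The generative model is the standard two-sample MR summary-statistic model:
each instrument j has a true effect gamma_j on the exposure and a true effect
on the outcome

    Gamma_j = causal_beta * gamma_j + alpha_j,

where alpha_j is a horizontal-pleiotropy term carried only by designated
invalid instruments. Estimated effects are the true effects perturbed by
Gaussian noise whose standard deviation follows the usual
allele-frequency/sample-size approximation for a variance-1 trait,

    se_j ~= 1 / sqrt(2 f_j (1 - f_j) n),

and p-values are the two-sided normal tail of beta/se. Null (background)
variants have gamma_j = 0 and are never pleiotropic.

A companion reference panel with block LD structure supports clumping tests:
within a block every variant copies a latent haplotype allele with a copy
probability calibrated so that pairwise genotype r^2 approximates the block's
target; across blocks genotypes are independent.

All randomness derives from a single integer seed through named child
streams, in this fixed order: (1) variant layout (frequencies, true effects,
pleiotropy, invalid flags), (2) exposure noise, (3) outcome noise,
(4) reference panel. Identical configs therefore give byte-identical outputs,
and the panel does not perturb the summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats_io import ReferencePanel, SummaryStats

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_pair", "simulate_panel"]

#: spacing that keeps distinct LD regions farther apart than any clump window
_REGION_SPACING_BP = 50_000_000
_MIN_GAMMA = 0.01  # truncation keeping Wald-ratio denominators away from 0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one paired exposure/outcome simulation.

    ``n_variants`` counts instrument candidates (true exposure effects drawn
    from N(0, gamma_sd^2), truncated away from zero); ``n_null_variants``
    adds background variants with no exposure effect. Sample sizes default to
    study scale for a microbiome-GWAS exposure (n=18,340) and a
    protein-level outcome (n=3,301). ``invalid_fraction`` of the instruments
    receive pleiotropic outcome effects: balanced alpha ~ N(0, pleiotropy_sd^2)
    or directional alpha ~ N(pleiotropy_sd, pleiotropy_sd^2).
    ``noiseless`` is the large-sample limit switch: estimated effects equal
    true effects while reported standard errors keep their finite-n values.
    """

    n_variants: int = 50
    n_null_variants: int = 0
    n_exposure: int = 18_340
    n_outcome: int = 3_301
    causal_beta: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.15
    ld_blocks: Sequence[dict] = field(default_factory=tuple)
    n_panel: int = 500
    noiseless: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 3:
            raise ValueError("n_variants must be >= 3 (sets below the minimum-IV rule are untestable)")
        if self.n_null_variants < 0:
            raise ValueError("n_null_variants must be >= 0")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("n_exposure and n_outcome must be > 0")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"eaf_range {self.eaf_range} must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"pleiotropy_mode {self.pleiotropy_mode!r} not in none/balanced/directional")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must be in [0,1]")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be > 0")
        if self.n_panel < 2:
            raise ValueError("n_panel must be >= 2")
        total = self.n_variants + self.n_null_variants
        if sum(int(b["size"]) for b in self.ld_blocks) > total:
            raise ValueError("ld_blocks sizes exceed the total variant count")
        for b in self.ld_blocks:
            if not (0 <= float(b["r2"]) <= 1):
                raise ValueError(f"ld block r2 {b['r2']} must be in [0,1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated pair, for recovery checks."""

    causal_beta: float
    variant_ids: np.ndarray
    gamma: np.ndarray          # true exposure effects (0 for null variants)
    alpha: np.ndarray          # pleiotropic outcome effects
    invalid_flags: np.ndarray  # True iff alpha != 0
    eaf: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        if not (len(self.gamma) == len(self.alpha) == len(self.invalid_flags) == len(self.eaf) == n):
            raise ValueError("truth arrays have inconsistent lengths")


def _streams(seed: int) -> list[np.random.Generator]:
    """Child generators in documented order: layout, exposure, outcome, panel."""
    seqs = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(s) for s in seqs]


def _layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Variant frame: ids, positions, block assignment, eaf, true effects.

    Blocks occupy the leading variants in order; each block (and each
    remaining singleton) sits in its own well-separated region so that only
    intra-block pairs can fall inside one clump window. Variants within a
    block share the block's allele frequency, which keeps the haplotype-copy
    LD construction exact.
    """
    total = config.n_variants + config.n_null_variants
    block_id = np.full(total, -1)
    block_r2 = np.zeros(total)
    i = 0
    for k, b in enumerate(config.ld_blocks):
        size = int(b["size"])
        block_id[i:i + size] = k
        block_r2[i:i + size] = float(b["r2"])
        i += size

    region = np.zeros(total, dtype=int)
    pos = np.zeros(total, dtype=np.int64)
    chrom = np.empty(total, dtype=object)
    r = 0
    j = 0
    while j < total:
        size = int((block_id == block_id[j]).sum()) if block_id[j] >= 0 else 1
        for k in range(size):
            region[j + k] = r
            chrom[j + k] = str(r % 22 + 1)
            pos[j + k] = 1_000_000 + (r // 22) * _REGION_SPACING_BP + k * 1_000
        r += 1
        j += size

    lo, hi = config.eaf_range
    eaf = rng.uniform(lo, hi, size=total)
    for k in range(len(config.ld_blocks)):
        members = block_id == k
        eaf[members] = eaf[members][0]  # shared frequency within a block

    gamma = rng.normal(0.0, config.gamma_sd, size=total)
    small = np.abs(gamma) < _MIN_GAMMA
    gamma[small] = np.where(gamma[small] < 0, -_MIN_GAMMA, _MIN_GAMMA)
    gamma[config.n_variants:] = 0.0  # background variants

    n_invalid = int(round(config.invalid_fraction * config.n_variants))
    invalid = np.zeros(total, dtype=bool)
    if n_invalid and config.pleiotropy_mode != "none":
        chosen = rng.choice(config.n_variants, size=n_invalid, replace=False)
        invalid[chosen] = True
    alpha = np.zeros(total)
    if invalid.any():
        if config.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, config.pleiotropy_sd, size=invalid.sum())
        else:
            # directional with respect to the exposure-increasing allele:
            # aligning the pleiotropic shift with sign(gamma) keeps it
            # directional after Wald-ratio / Egger orientation, which is what
            # makes it bias IVW and shift the Egger intercept in expectation
            draw = rng.normal(config.pleiotropy_sd, config.pleiotropy_sd, size=invalid.sum())
            alpha[invalid] = draw * np.where(gamma[invalid] < 0, -1.0, 1.0)
    invalid = alpha != 0.0

    alleles = np.array(list("ACGT"))
    ea_idx = rng.integers(0, 4, size=total)
    oa_idx = (ea_idx + rng.integers(1, 4, size=total)) % 4

    return pd.DataFrame({
        "variant_id": [f"rs{100000 + i}" for i in range(total)],
        "chrom": chrom,
        "pos": pos,
        "effect_allele": alleles[ea_idx],
        "other_allele": alleles[oa_idx],
        "eaf": eaf,
        "gamma": gamma,
        "alpha": alpha,
        "invalid": invalid,
        "block_id": block_id,
        "block_r2": block_r2,
        "region": region,
    })


def _observed(true_beta: np.ndarray, se: np.ndarray, rng: np.random.Generator,
              noiseless: bool) -> tuple[np.ndarray, np.ndarray]:
    beta = true_beta if noiseless else true_beta + rng.normal(0.0, se)
    z = np.abs(beta / se)
    pval = np.maximum(2.0 * sps.norm.sf(z), 1e-300)  # keep within (0,1]
    return beta, pval


def _as_sumstats(frame: pd.DataFrame, beta: np.ndarray, se: np.ndarray,
                 pval: np.ndarray, n: int, trait_id: str, trait_type: str) -> SummaryStats:
    table = frame[["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["pval"] = pval
    table["n"] = float(n)
    return SummaryStats(trait_id, trait_type, table.reset_index(drop=True))


def simulate_pair(config: SimulationConfig) -> tuple[SummaryStats, SummaryStats, SimulationTruth]:
    """Generate one exposure/outcome summary-statistic pair plus its truth."""
    config.validate()
    layout_rng, exp_rng, out_rng, _ = _streams(config.seed)
    frame = _layout(config, layout_rng)

    f = frame["eaf"].to_numpy()
    se_exp = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * config.n_exposure)
    se_out = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * config.n_outcome)

    gamma = frame["gamma"].to_numpy()
    Gamma = config.causal_beta * gamma + frame["alpha"].to_numpy()

    beta_exp, p_exp = _observed(gamma, se_exp, exp_rng, config.noiseless)
    beta_out, p_out = _observed(Gamma, se_out, out_rng, config.noiseless)

    exposure = _as_sumstats(frame, beta_exp, se_exp, p_exp, config.n_exposure,
                            "sim_exposure", "microbe_taxon")
    outcome = _as_sumstats(frame, beta_out, se_out, p_out, config.n_outcome,
                           "sim_outcome", "protein")
    truth = SimulationTruth(
        causal_beta=config.causal_beta,
        variant_ids=frame["variant_id"].to_numpy(),
        gamma=gamma,
        alpha=frame["alpha"].to_numpy(),
        invalid_flags=frame["invalid"].to_numpy(),
        eaf=f,
    )
    return exposure, outcome, truth


def simulate_panel(config: SimulationConfig) -> ReferencePanel:
    """Generate a diploid 0/1/2 reference panel matching the pair's variants.

    Within a block with target r2, each variant's haplotype allele copies the
    block's latent haplotype with probability r2**0.25 and is otherwise an
    independent Bernoulli(f) draw; genotype correlation between two such
    variants is the square of the copy probability, so pairwise genotype
    r^2 approximates the target. Variants outside blocks are independent.
    """
    config.validate()
    layout_rng, _, _, panel_rng = _streams(config.seed)
    frame = _layout(config, layout_rng)

    total = len(frame)
    n_hap = 2 * config.n_panel
    f = frame["eaf"].to_numpy()
    haplos = np.empty((total, n_hap), dtype=np.int8)

    for k in range(-1, len(config.ld_blocks)):
        if k < 0:
            idx = np.flatnonzero(frame["block_id"].to_numpy() == -1)
            for i in idx:
                haplos[i] = panel_rng.random(n_hap) < f[i]
        else:
            idx = np.flatnonzero(frame["block_id"].to_numpy() == k)
            if idx.size == 0:
                continue
            fb = f[idx[0]]
            copy_p = float(frame["block_r2"].to_numpy()[idx[0]]) ** 0.25
            latent = (panel_rng.random(n_hap) < fb).astype(np.int8)
            for i in idx:
                copy = panel_rng.random(n_hap) < copy_p
                indep = (panel_rng.random(n_hap) < fb).astype(np.int8)
                haplos[i] = np.where(copy, latent, indep)

    geno = haplos[:, :config.n_panel] + haplos[:, config.n_panel:]
    mono = geno.std(axis=1) == 0
    variants = frame[["variant_id", "chrom", "pos"]].reset_index(drop=True)
    return ReferencePanel(variants, geno.astype(np.int8), mono)
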