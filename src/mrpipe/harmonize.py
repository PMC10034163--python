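"""Align exposure and outcome effects to a shared effect allele.

Two-sample MR needs the per-variant exposure effect (gamma) and outcome
effect (Gamma) signed for the same allele. Outcome records whose allele pair
matches the exposure's directly are kept as-is; swapped pairs have the
outcome beta negated and frequency complemented; strand flips (A<->T, C<->G
applied to both alleles) are resolved the same way. Palindromic pairs (A/T or
C/G), where strand cannot be inferred from the alleles, are oriented by
comparing allele frequencies, and those with intermediate frequencies —
minor-allele frequency above 0.42 — are discarded because their orientation
is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import SummaryStats

__all__ = ["HarmonizedSet", "harmonize", "drop_intermediate_palindromes"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of the retained-pair table
PAIR_COLUMNS = ["variant_id", "chrom", "pos", "gamma", "se_gamma", "Gamma", "se_Gamma",
                "eaf", "palindromic", "action"]


@dataclass
class HarmonizedSet:
    """Instrument-level paired effects on a common effect-allele orientation.

    ``pairs`` holds retained instruments (gamma/se_gamma from the exposure,
    Gamma/se_Gamma from the outcome, eaf in exposure orientation);
    ``removed`` logs dropped instruments with a reason code. All estimators
    operate on this container.
    """

    exposure_id: str
    outcome_id: str
    pairs: pd.DataFrame
    removed: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"]))
    direction: str = "forward"

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def gamma(self) -> np.ndarray:
        return self.pairs["gamma"].to_numpy(float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.pairs["se_gamma"].to_numpy(float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.pairs["Gamma"].to_numpy(float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.pairs["se_Gamma"].to_numpy(float)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.pairs["variant_id"].to_numpy()

    def drop(self, variant_ids, reason: str) -> "HarmonizedSet":
        """New set without the given variants, logging them under ``reason``."""
        ids = set(variant_ids)
        mask = self.pairs["variant_id"].isin(ids)
        dropped = pd.DataFrame({"variant_id": self.pairs.loc[mask, "variant_id"],
                                "reason": reason})
        removed = pd.concat([self.removed, dropped], ignore_index=True)
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.pairs[~mask].reset_index(drop=True), removed,
                             self.direction)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        """New set restricted to the boolean mask (removal log not extended)."""
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.pairs[mask].reset_index(drop=True),
                             self.removed, self.direction)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(instruments: SummaryStats, outcome: SummaryStats,
              direction: str = "forward") -> HarmonizedSet:
    """Pair each instrument with its outcome record on a common effect allele.

    Resolution order per instrument: exact allele match -> aligned; swapped
    alleles -> outcome beta negated; strand-complemented match or swap ->
    likewise. Palindromic pairs are oriented by allele frequency (both
    frequencies on the same side of 0.5 means aligned). Instruments missing
    from the outcome or with incompatible allele pairs are dropped and
    logged; nothing is fatal.
    """
    out_by_id = outcome.table.set_index("variant_id")
    rows: list[dict] = []
    removed: list[dict] = []

    for v in instruments.table.itertuples(index=False):
        if v.variant_id not in out_by_id.index:
            removed.append({"variant_id": v.variant_id, "reason": "dropped_missing"})
            continue
        o = out_by_id.loc[v.variant_id]
        e1, o1 = v.effect_allele, v.other_allele
        e2, o2 = str(o["effect_allele"]), str(o["other_allele"])
        palindromic = _is_palindromic(e1, o1)

        if palindromic:
            if _COMPLEMENT[e2] != o2 or {e2, o2} != {e1, o1}:
                removed.append({"variant_id": v.variant_id, "reason": "dropped_incompatible"})
                continue
            # allele labels cannot resolve strand; orient by frequency when possible
            eaf_exp, eaf_out = float(v.eaf), float(o["eaf"])
            raw_match = e2 == e1
            if np.isnan(eaf_exp) or np.isnan(eaf_out):
                flip = not raw_match  # fall back to the allele labels as printed
            else:
                same_side = (eaf_exp - 0.5) * ((eaf_out if raw_match else 1 - eaf_out) - 0.5) >= 0
                flip = (not raw_match) if same_side else raw_match
            action = "flipped" if flip else "aligned"
        else:
            c2, co2 = _COMPLEMENT[e2], _COMPLEMENT[o2]
            if (e2, o2) == (e1, o1) or (c2, co2) == (e1, o1):
                flip, action = False, "aligned"
            elif (e2, o2) == (o1, e1) or (c2, co2) == (o1, e1):
                flip, action = True, "flipped"
            else:
                removed.append({"variant_id": v.variant_id, "reason": "dropped_incompatible"})
                continue

        rows.append({
            "variant_id": v.variant_id,
            "chrom": v.chrom,
            "pos": int(v.pos),
            "gamma": float(v.beta),
            "se_gamma": float(v.se),
            "Gamma": -float(o["beta"]) if flip else float(o["beta"]),
            "se_Gamma": float(o["se"]),
            "eaf": float(v.eaf),
            "palindromic": palindromic,
            "action": action,
        })

    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    removed_df = pd.DataFrame(removed, columns=["variant_id", "reason"])
    return HarmonizedSet(instruments.trait_id, outcome.trait_id, pairs, removed_df, direction)


def drop_intermediate_palindromes(hset: HarmonizedSet, maf_limit: float = 0.42,
                                  palindromic_only: bool = True) -> HarmonizedSet:
    """Drop pairs with intermediate allele frequency (MAF > maf_limit).

    By default only palindromic pairs are tested — they are the ones whose
    strand orientation frequency inference cannot settle near MAF 0.5 —
    with ``palindromic_only=False`` extending the rule to every pair.
    Palindromic pairs with missing frequency are dropped under a distinct
    reason code since the rule cannot be verified for them.
    """
    pairs = hset.pairs
    maf = np.minimum(pairs["eaf"], 1.0 - pairs["eaf"])
    scope = pairs["palindromic"] if palindromic_only else pd.Series(True, index=pairs.index)

    unverifiable = scope & pairs["eaf"].isna()
    intermediate = scope & (maf > maf_limit)

    out = hset
    if unverifiable.any():
        out = out.drop(pairs.loc[unverifiable, "variant_id"], "dropped_palindromic_missing_eaf")
    if intermediate.any():
        out = out.drop(pairs.loc[intermediate, "variant_id"], "dropped_palindromic")
    return out
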