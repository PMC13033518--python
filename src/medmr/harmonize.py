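"""Align exposure and outcome effects to a shared effect allele, resolve
palindromic SNPs, and apply Steiger directionality filtering.

For each variant present in both traits the outcome alleles are compared to
the exposure alleles: identical alleles are used as-is, swapped alleles flip
the sign of the outcome beta, and strand-complement (or complement-swap)
alleles are complemented first — cross-consortium panels can differ in
strand convention.  A/T and C/G (palindromic) variants cannot be resolved
from allele labels alone; they are dropped outright or, under the
``infer_by_eaf`` policy, oriented by allele-frequency concordance when both
frequencies are far enough from 0.5.

Steiger filtering retains variants that explain more variance in the
exposure than in the outcome, guarding against reverse causation; variance
explained is the t-statistic form r2 = t^2 / (t^2 + n - 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import InstrumentSet
from .sumstats import SummaryStats, SumstatsError

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele frequencies within 0.5 +/- this band are ambiguous for palindromes
DEFAULT_EAF_TOLERANCE = 0.08

ROW_COLUMNS = (
    "variant_id",
    "beta_x",
    "se_x",
    "beta_y",
    "se_y",
    "eaf_x",
    "n_x",
    "n_y",
    "palindromic",
    "flipped",
)


def _complement(allele: str) -> str:
    return "".join(COMPLEMENT[b] for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2


@dataclass
class HarmonizedPair:
    """Allele-aligned exposure/outcome effect pairs on shared variants.

    ``report`` counts every variant of the pre-harmonization intersection
    exactly once among {aligned, flipped, palindromic_dropped,
    incompatible_dropped}; ``steiger_dropped`` additionally counts rows
    removed (from the aligned/flipped set) by Steiger filtering.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.df) and not ((self.df["se_x"] > 0).all() and (self.df["se_y"] > 0).all()):
            raise SumstatsError("harmonized rows require positive standard errors")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def skip(self) -> bool:
        return len(self.df) == 0

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def arrays(self):
        d = self.df
        return (
            d["beta_x"].to_numpy(float),
            d["se_x"].to_numpy(float),
            d["beta_y"].to_numpy(float),
            d["se_y"].to_numpy(float),
        )

    def drop_rows(self, mask) -> "HarmonizedPair":
        return HarmonizedPair(
            self.exposure_id, self.outcome_id,
            self.df[~np.asarray(mask)].copy(), dict(self.report),
        )


def empty_report() -> dict:
    return {
        "aligned": 0,
        "flipped": 0,
        "palindromic_dropped": 0,
        "incompatible_dropped": 0,
        "steiger_dropped": 0,
    }


def harmonize_pair(
    exposure: InstrumentSet | SummaryStats,
    outcome: SummaryStats,
    palindromic_policy: str = "infer_by_eaf",
    eaf_tolerance: float = DEFAULT_EAF_TOLERANCE,
) -> HarmonizedPair:
    """Intersect on variant_id and align outcome effects to the exposure's
    effect allele.  An empty intersection yields an empty pair with a skip
    flag rather than an exception."""
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")

    if isinstance(exposure, InstrumentSet):
        exp_records = exposure.variants
        exposure_id = exposure.trait_id
    else:
        exp_records = exposure.records()
        exposure_id = exposure.trait_id

    out_df = outcome.df.set_index("variant_id")
    report = empty_report()
    rows = []
    for ex in exp_records:  # exposure (instrument) order is preserved
        if ex.variant_id not in out_df.index:
            continue
        oc = out_df.loc[ex.variant_id]
        ea, oa = str(oc["effect_allele"]), str(oc["other_allele"])
        beta_y = float(oc["beta"])
        eaf_y = None if pd.isna(oc["eaf"]) else float(oc["eaf"])
        palindromic = _is_palindromic(ex.effect_allele, ex.other_allele)

        if palindromic:
            # labels can only match or swap (complement == swap here)
            if (ea, oa) == (ex.effect_allele, ex.other_allele):
                label_flip = False
            elif (ea, oa) == (ex.other_allele, ex.effect_allele):
                label_flip = True
            else:
                report["incompatible_dropped"] += 1
                continue
            if palindromic_policy == "drop":
                report["palindromic_dropped"] += 1
                continue
            if ex.eaf is None or eaf_y is None:
                report["palindromic_dropped"] += 1
                continue
            lo, hi = 0.5 - eaf_tolerance, 0.5 + eaf_tolerance
            if lo <= ex.eaf <= hi or lo <= eaf_y <= hi:
                report["palindromic_dropped"] += 1
                continue
            eaf_y_aligned = (1.0 - eaf_y) if label_flip else eaf_y
            freq_discordant = (ex.eaf - 0.5) * (eaf_y_aligned - 0.5) < 0
            flipped = label_flip != freq_discordant
        else:
            ce, co = _complement(ea), _complement(oa)
            if (ea, oa) == (ex.effect_allele, ex.other_allele):
                flipped = False
            elif (ea, oa) == (ex.other_allele, ex.effect_allele):
                flipped = True
            elif (ce, co) == (ex.effect_allele, ex.other_allele):
                flipped = False
            elif (ce, co) == (ex.other_allele, ex.effect_allele):
                flipped = True
            else:
                report["incompatible_dropped"] += 1
                continue

        report["flipped" if flipped else "aligned"] += 1
        rows.append(
            (
                ex.variant_id,
                ex.beta,
                ex.se,
                -beta_y if flipped else beta_y,
                float(oc["se"]),
                np.nan if ex.eaf is None else ex.eaf,
                ex.n,
                int(oc["n"]),
                palindromic,
                flipped,
            )
        )

    df = pd.DataFrame(rows, columns=list(ROW_COLUMNS))
    pair = HarmonizedPair(exposure_id, outcome.trait_id, df, report)
    if pair.skip:
        logger.info("%s vs %s: empty harmonized intersection; pair skipped",
                    exposure_id, outcome.trait_id)
    return pair


def variance_explained(beta: float, se: float, n: int) -> float:
    """Variance in a trait explained by one variant: t^2 / (t^2 + n - 2)."""
    if n <= 2:
        raise SumstatsError("variance_explained requires n > 2")
    if not (se > 0):
        raise SumstatsError("variance_explained requires se > 0")
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2)


def steiger_filter(pair: HarmonizedPair) -> HarmonizedPair:
    """Keep rows whose exposure variance explained strictly exceeds the
    outcome's.  Idempotent; an all-dropped result carries the skip flag."""
    if pair.skip:
        return pair
    d = pair.df
    r2_x = np.array([
        variance_explained(b, s, n) for b, s, n in zip(d["beta_x"], d["se_x"], d["n_x"])
    ])
    r2_y = np.array([
        variance_explained(b, s, n) for b, s, n in zip(d["beta_y"], d["se_y"], d["n_y"])
    ])
    keep = r2_x > r2_y
    out = pair.drop_rows(~keep)
    out.report["steiger_dropped"] = pair.report.get("steiger_dropped", 0) + int(
        (~keep).sum()
    )
    return out
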