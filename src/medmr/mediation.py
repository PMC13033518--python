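"""Two-step MR mediation: product-of-coefficients indirect effects with
delta-method uncertainty, Z-test, mediated proportion, and triplet
screening.

For a taxon -> protein -> disease triplet the three inputs are the primary
MR estimates of the total effect (taxon on disease, beta_total), step one
(taxon on protein, beta1) and step two (protein on disease, beta2).  The
indirect effect is beta12 = beta1 * beta2 with first-order (Sobel) SE
sqrt(beta1^2 se2^2 + beta2^2 se1^2); the mediated proportion is
beta12 / beta_total.  On a log-odds outcome the proportion is a ranking
heuristic rather than an exact decomposition, so it is reported raw with
flags instead of being truncated to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .estimators import MrResult

P_FLOOR = np.nextafter(0.0, 1.0)


class MediationError(ValueError):
    """Undefined mediation quantity or mis-wired triplet inputs."""


@dataclass
class MediationTriplet:
    """One taxon -> protein -> disease decomposition."""

    taxon_id: str
    protein_id: str
    beta_total: float
    se_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta12: float
    se12: float
    z: float
    p_beta12: float
    proportion: float
    flags: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "taxon_id": self.taxon_id,
            "protein_id": self.protein_id,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "beta12": self.beta12,
            "se12": self.se12,
            "z": self.z,
            "p_beta12": self.p_beta12,
            "beta_total": self.beta_total,
            "se_total": self.se_total,
            "proportion": self.proportion,
            "flags": ";".join(sorted(self.flags)),
        }


def indirect_effect(
    beta1: float, se1: float, beta2: float, se2: float, exact: bool = False
) -> tuple[float, float]:
    """Product-of-coefficients indirect effect and its delta-method SE.

    The default first-order (Sobel) variance omits the se1^2 * se2^2 cross
    term; pass ``exact=True`` for the exact-product variance.
    """
    if se1 < 0 or se2 < 0:
        raise MediationError("standard errors must be non-negative")
    beta12 = beta1 * beta2
    var = beta1**2 * se2**2 + beta2**2 * se1**2
    if exact:
        var += se1**2 * se2**2
    return beta12, math.sqrt(var)


def mediation_z_test(beta12: float, se12: float) -> tuple[float, float]:
    """Z = beta12/se12 with a two-sided normal p-value.

    Degenerate se12 = 0: a zero effect gives (0, 1); a nonzero effect gives
    an infinite Z with the p-value clamped to the smallest positive double
    (callers flag this).
    """
    if se12 == 0:
        if beta12 == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, beta12), float(P_FLOOR)
    z = beta12 / se12
    p = float(np.clip(2.0 * sps.norm.sf(abs(z)), P_FLOOR, 1.0))
    return z, p


def proportion_mediated(beta12: float, beta_total: float) -> float:
    """beta12 / beta_total; undefined for a zero total effect."""
    if beta_total == 0:
        raise MediationError("proportion undefined: beta_total = 0")
    return beta12 / beta_total


def _proportion_flags(beta12: float, beta_total: float, proportion: float) -> set:
    flags = set()
    if beta12 != 0 and (beta12 > 0) != (beta_total > 0):
        flags.add("sign_discordant")
    if not (0.0 <= proportion <= 1.0):
        flags.add("proportion_out_of_range")
    return flags


def build_triplet(
    taxon_mr: MrResult, protein_mr: MrResult, step1_mr: MrResult, exact_se: bool = False
) -> MediationTriplet:
    """Assemble a triplet from three primary MR fits.

    ``taxon_mr`` is taxon -> disease (total effect), ``step1_mr`` is taxon ->
    protein, ``protein_mr`` is protein -> disease.  Identifier mismatches
    across the three fits raise a wiring error naming the mismatch.
    """
    if taxon_mr.exposure_id != step1_mr.exposure_id:
        raise MediationError(
            "wiring: taxon of total effect "
            f"({taxon_mr.exposure_id!r}) != taxon of step 1 ({step1_mr.exposure_id!r})"
        )
    if step1_mr.outcome_id != protein_mr.exposure_id:
        raise MediationError(
            "wiring: mediator of step 1 "
            f"({step1_mr.outcome_id!r}) != exposure of step 2 ({protein_mr.exposure_id!r})"
        )
    if taxon_mr.outcome_id != protein_mr.outcome_id:
        raise MediationError(
            "wiring: outcome mismatch "
            f"({taxon_mr.outcome_id!r} vs {protein_mr.outcome_id!r})"
        )
    beta12, se12 = indirect_effect(
        step1_mr.beta, step1_mr.se, protein_mr.beta, protein_mr.se, exact=exact_se
    )
    z, p = mediation_z_test(beta12, se12)
    proportion = proportion_mediated(beta12, taxon_mr.beta)
    flags = _proportion_flags(beta12, taxon_mr.beta, proportion)
    if se12 == 0 and beta12 != 0:
        flags.add("degenerate_se")
    return MediationTriplet(
        taxon_id=taxon_mr.exposure_id,
        protein_id=protein_mr.exposure_id,
        beta_total=taxon_mr.beta,
        se_total=taxon_mr.se,
        beta1=step1_mr.beta,
        se1=step1_mr.se,
        beta2=protein_mr.beta,
        se2=protein_mr.se,
        beta12=beta12,
        se12=se12,
        z=z,
        p_beta12=p,
        proportion=proportion,
        flags=flags,
    )


@dataclass
class ScreenedTriplets:
    """Ranked mediation triplets plus the sign-discordant set-aside list."""

    retained: list[MediationTriplet]
    sign_discordant: list[MediationTriplet]


def screen_triplets(
    triplets: list[MediationTriplet],
    min_proportion: float = 0.10,
    require_beta1_significant: bool = False,
    require_z_significant: bool = False,
    alpha: float = 0.05,
) -> ScreenedTriplets:
    """Retain triplets with proportion strictly above ``min_proportion``,
    sorted by descending proportion.

    Sign-discordant (inconsistent-mediation) triplets are excluded from the
    ranked list and returned separately.  Optional nominal-significance
    filters on beta1 and on the mediation Z-test are off by default.
    """
    if not (0 <= min_proportion < 1):
        raise MediationError("min_proportion must be in [0, 1)")
    discordant = [t for t in triplets if "sign_discordant" in t.flags]
    candidates = [t for t in triplets if "sign_discordant" not in t.flags]
    if require_beta1_significant:
        candidates = [
            t for t in candidates
            if t.se1 > 0 and 2.0 * sps.norm.sf(abs(t.beta1 / t.se1)) < alpha
        ]
    if require_z_significant:
        candidates = [t for t in candidates if t.p_beta12 < alpha]
    retained = sorted(
        (t for t in candidates if t.proportion > min_proportion),
        key=lambda t: (-t.proportion, t.taxon_id, t.protein_id),
    )
    return ScreenedTriplets(retained=retained, sign_discordant=discordant)
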