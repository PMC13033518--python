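"""Genetic instrument selection: p-value thresholding, greedy LD clumping
within a distance window, and per-SNP F-statistics for weak-instrument
screening.

Clumping is the standard greedy index-variant procedure: candidates are
ranked by p-value, the best remaining variant is taken as an index, and all
remaining variants on the same chromosome within the window whose r-squared
with the index reaches the threshold are removed.  Because the LD table is
an explicit input (absent pairs count as unlinked), the procedure is fully
deterministic and needs no external reference panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sumstats import LdMatrix, SummaryStats, SumstatsError, VariantAssociation

logger = logging.getLogger(__name__)

# defaults mirroring the study design: genome-wide significance for pQTLs,
# suggestive significance for microbial taxa, r2 < 0.1 within 10 Mb, F > 10
PROTEIN_P_THRESHOLD = 5e-8
TAXON_P_THRESHOLD = 5e-6
R2_MAX = 0.1
WINDOW_BP = 10_000_000
F_MIN = 10.0


@dataclass
class InstrumentSet:
    """Retained instruments for one trait plus selection bookkeeping."""

    trait_id: str
    variants: list[VariantAssociation]
    p_threshold: float
    r2_max: float
    window_bp: int
    f_stats: dict[str, float] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return len(self.variants) == 0

    @property
    def skip(self) -> bool:
        """True when the trait has no usable instruments and downstream MR
        should be recorded as skipped."""
        return self.is_empty

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


def f_statistic(assoc: VariantAssociation | None = None, *, beta: float | None = None,
                se: float | None = None) -> float:
    """Per-SNP instrument-strength F, the squared Wald z: (beta/se)^2."""
    if assoc is not None:
        beta, se = assoc.beta, assoc.se
    if se is None or beta is None or not (se > 0):
        raise SumstatsError("f_statistic requires se > 0")
    return (beta / se) ** 2


def _p_rank_key(v: VariantAssociation):
    # ties broken by chromosome, position, id for reproducibility
    return (v.pvalue, v.chromosome, v.position, v.variant_id)


def _genomic_key(v: VariantAssociation):
    return (v.chromosome, v.position, v.variant_id)


def ld_clump(
    variants: list[VariantAssociation],
    ld: LdMatrix,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
) -> list[VariantAssociation]:
    """Greedy LD clumping; returns the retained variants in genomic order.

    Variants on different chromosomes never clump each other regardless of
    any LD entries.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    remaining = sorted(variants, key=_p_rank_key)
    retained: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        remaining = [
            v
            for v in remaining
            if not (
                v.chromosome == index.chromosome
                and abs(v.position - index.position) <= window_bp
                and ld.r2(v.variant_id, index.variant_id) >= r2_max
            )
        ]
    return sorted(retained, key=_genomic_key)


def select_instruments(
    stats: SummaryStats,
    ld: LdMatrix,
    p_threshold: float | None = None,
    r2_max: float = R2_MAX,
    window_bp: int = WINDOW_BP,
    f_min: float = F_MIN,
) -> InstrumentSet:
    """p-filter, clump, and F-screen one trait's summary statistics.

    When ``p_threshold`` is omitted it follows the trait class (5e-8 for
    proteins, 5e-6 for taxa).  Variants with F below ``f_min`` are dropped
    when ``f_min`` > 0 (pass ``f_min=0`` to keep weak instruments and merely
    record their F).  An empty result is returned with a skip flag rather
    than raising, so genome-wide scans can record and move on.
    """
    if p_threshold is None:
        p_threshold = (
            TAXON_P_THRESHOLD if stats.trait_class == "taxon" else PROTEIN_P_THRESHOLD
        )
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")

    candidates = [r for r in stats.records() if r.pvalue < p_threshold]
    clumped = ld_clump(candidates, ld, r2_max=r2_max, window_bp=window_bp)
    f_all = {v.variant_id: f_statistic(v) for v in clumped}
    if f_min > 0:
        kept = [v for v in clumped if f_all[v.variant_id] >= f_min]
    else:
        kept = list(clumped)
    report = {
        "n_input": len(stats),
        "n_significant": len(candidates),
        "n_clumped": len(clumped),
        "n_weak_dropped": len(clumped) - len(kept),
        "n_final": len(kept),
    }
    if not kept:
        logger.warning("%s: no instruments survive selection; trait will be skipped",
                       stats.trait_id)
    return InstrumentSet(
        trait_id=stats.trait_id,
        variants=kept,
        p_threshold=p_threshold,
        r2_max=r2_max,
        window_bp=window_bp,
        f_stats={v.variant_id: f_all[v.variant_id] for v in kept},
        report=report,
    )
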