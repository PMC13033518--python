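"""Shared fixtures and builders for the test suite.

All fixture data is generated programmatically; nothing is read from disk
except files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from medmr.harmonize import HarmonizedPair, ROW_COLUMNS, empty_report
from medmr.sumstats import SummaryStats, VariantAssociation, stats_from_records


def make_pair(
    beta_x,
    beta_y,
    se_y,
    se_x=None,
    n_x=50_000,
    n_y=50_000,
    exposure_id="x",
    outcome_id="y",
) -> HarmonizedPair:
    """Build a HarmonizedPair directly from effect arrays."""
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.broadcast_to(np.asarray(se_y, float), beta_x.shape)
    se_x = (
        np.broadcast_to(np.asarray(se_x, float), beta_x.shape)
        if se_x is not None
        else np.full_like(beta_x, 0.02)
    )
    J = beta_x.size
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1:04d}" for i in range(J)],
            "beta_x": beta_x,
            "se_x": se_x,
            "beta_y": beta_y,
            "se_y": se_y,
            "eaf_x": np.full(J, 0.3),
            "n_x": np.full(J, n_x, dtype=int),
            "n_y": np.full(J, n_y, dtype=int),
            "palindromic": np.zeros(J, dtype=bool),
            "flipped": np.zeros(J, dtype=bool),
        },
        columns=list(ROW_COLUMNS),
    )
    report = empty_report()
    report["aligned"] = J
    return HarmonizedPair(exposure_id, outcome_id, df, report)


def make_variant(
    variant_id="rs1",
    chromosome="1",
    position=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-8,
    n=10_000,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id,
        chromosome=chromosome,
        position=position,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_stats(records, trait_id="trait", trait_class="taxon") -> SummaryStats:
    return stats_from_records(trait_id, trait_class, records)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def proportional_pair():
    """Five variants with beta_y exactly 0.3 * beta_x (zero heterogeneity)."""
    bx = np.array([0.05, 0.10, 0.15, 0.20, 0.25])
    return make_pair(bx, 0.3 * bx, se_y=0.01)
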