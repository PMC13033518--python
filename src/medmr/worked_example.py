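"""Worked example: a published two-step MR mediation screen of 18
microbe -> protein -> ulcerative-colitis triplets.

Each row carries the printed step-one estimate (path a, taxon on protein,
``beta1``), the step-two estimate (path b, protein on disease log-odds,
``beta2``), the printed indirect effect ``beta12`` and the printed mediated
proportion (percent).  The table is used to exercise the product-of-
coefficients arithmetic: recomputing beta1 * beta2 from the printed inputs
and rounding to three decimals reproduces the printed beta12 on the rows
where the printed values are self-consistent; on the remainder the inputs
were themselves rounded before printing and the product differs by at most
0.0015.

``CONSISTENT_ROWS`` freezes the self-consistent subset (determined once by
direct recomputation) so tests and reports do not re-derive it circularly.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # taxon, protein, beta1 (path a), beta2 (path b), printed beta12, printed % mediated
    ("CAG-495", "MAPK11", 0.032, -1.737, -0.056, 51.7),
    ("Eremiobacterota", "MAPK11", 0.357, -1.737, -0.621, 47.3),
    ("UBA1066 sp900317515", "MAPK11", 0.271, -1.737, -0.471, 41.6),
    ("CAG-495", "KLF4", 0.024, -1.297, -0.032, 29.2),
    ("UBA11963", "KLF4", 0.131, -1.297, -0.170, 26.0),
    ("UBA1066 sp900317515", "PTEN", 0.273, -0.932, -0.255, 22.5),
    ("Borreliaceae", "MAPK11", -0.099, -1.737, 0.173, 20.9),
    ("Prevotella sp000436915", "PTEN", 0.048, -0.932, -0.044, 19.4),
    ("Prevotella sp000436915", "KLF4", 0.033, -1.297, -0.043, 19.0),
    ("UBA1066 sp900317515", "KLF4", 0.144, -1.297, -0.186, 16.5),
    ("Faecalicatena sp002161355", "PTEN", 0.107, -0.932, -0.099, 16.4),
    ("Leuconostoc", "MAPK11", -0.068, -1.737, 0.118, 15.4),
    ("Desulfovibrio piger", "PTEN", 0.035, -0.932, -0.033, 15.1),
    ("Desulfovibrio piger", "MAPK11", 0.018, -1.737, -0.032, 14.7),
    ("Megasphaera sp900066485", "PTEN", 0.076, -0.932, -0.071, 14.5),
    ("Provencibacterium", "KLF4", -0.059, -1.297, 0.077, 14.2),
    ("Provencibacterium massiliense", "KLF4", -0.049, -1.297, 0.063, 12.4),
    ("UBA11963", "PTEN", 0.082, -0.932, -0.076, 11.7),
]

#: (taxon, protein) rows where round(beta1 * beta2, 3) equals the printed beta12
CONSISTENT_ROWS = frozenset(
    [
        ("CAG-495", "MAPK11"),
        ("UBA1066 sp900317515", "MAPK11"),
        ("UBA11963", "KLF4"),
        ("Prevotella sp000436915", "KLF4"),
        ("Leuconostoc", "MAPK11"),
        ("Desulfovibrio piger", "PTEN"),
        ("Megasphaera sp900066485", "PTEN"),
        ("Provencibacterium", "KLF4"),
        ("UBA11963", "PTEN"),
    ]
)


def mediation_rows() -> pd.DataFrame:
    """The published screen as a DataFrame with an implied total effect.

    ``beta_total_implied`` is beta12 / (proportion/100); the published
    table prints the proportion but not beta_total itself.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["taxon", "protein", "beta1", "beta2", "beta12_printed",
                 "proportion_pct"],
    )
    df["beta12_product"] = (df["beta1"] * df["beta2"]).round(3)
    df["beta_total_implied"] = df["beta12_printed"] / (df["proportion_pct"] / 100.0)
    df["product_consistent"] = [
        (t, p) in CONSISTENT_ROWS for t, p in zip(df["taxon"], df["protein"])
    ]
    return df
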