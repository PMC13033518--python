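"""Data model and I/O for GWAS summary statistics and pairwise LD tables.

Summary statistics are one row per variant: identifier, chromosome, 1-based
position (GRCh37 convention), effect/other allele, effect-allele frequency,
per-allele effect (log-odds for binary traits), standard error, p-value and
sample size.  Pairwise LD is a sparse symmetric r-squared table; pairs that
are not listed are taken to be unlinked (r-squared 0).

Variant matching across traits is by identifier only, mirroring how
cross-consortium panels are merged on shared SNP IDs; an optional strict
mode additionally cross-checks chromosome and position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column order for sumstats files written by this package
CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

#: smallest positive double; p-values of exactly 0 are clamped here
P_CLAMP = np.nextafter(0.0, 1.0)


class SumstatsError(ValueError):
    """Malformed or inconsistent summary-statistics input."""


class ConfigurationError(SumstatsError):
    """A required column or setting is missing."""


class LdValidationError(ValueError):
    """An LD table entry violates the r-squared range."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise SumstatsError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if not (self.se > 0):
            raise SumstatsError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pvalue <= 1):
            raise SumstatsError(f"{self.variant_id}: pvalue must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsError(f"{self.variant_id}: eaf outside [0, 1]")


@dataclass
class LoadReport:
    """Bookkeeping from a sumstats load: every input row is either retained
    or dropped for exactly one reason, so counts always reconcile."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped_se: int = 0
    n_dropped_beta: int = 0
    n_dropped_alleles: int = 0
    n_dropped_pvalue: int = 0
    n_dropped_n: int = 0
    n_dropped_duplicate: int = 0
    n_clamped_pvalue: int = 0
    n_missing_eaf: int = 0
    dropped_ids: list = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.n_dropped_se
            + self.n_dropped_beta
            + self.n_dropped_alleles
            + self.n_dropped_pvalue
            + self.n_dropped_n
            + self.n_dropped_duplicate
        )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped": self.n_dropped,
            "dropped_se": self.n_dropped_se,
            "dropped_beta": self.n_dropped_beta,
            "dropped_alleles": self.n_dropped_alleles,
            "dropped_pvalue": self.n_dropped_pvalue,
            "dropped_n": self.n_dropped_n,
            "dropped_duplicate": self.n_dropped_duplicate,
            "clamped_pvalue": self.n_clamped_pvalue,
            "missing_eaf": self.n_missing_eaf,
            "dropped_ids": list(self.dropped_ids),
        }


@dataclass
class SummaryStats:
    """A trait's GWAS summary statistics, unique by variant_id.

    ``trait_class`` is one of {"protein", "taxon", "disease"}; disease
    traits are on the log-odds scale by convention.
    """

    trait_id: str
    trait_class: str
    df: pd.DataFrame
    trait_scale: str = ""
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if self.trait_class not in ("protein", "taxon", "disease"):
            raise SumstatsError(f"unknown trait_class {self.trait_class!r}")
        if not self.trait_scale:
            self.trait_scale = (
                "log_odds" if self.trait_class == "disease" else "continuous"
            )
        if self.trait_class == "disease" and self.trait_scale != "log_odds":
            raise SumstatsError("disease traits must be on the log_odds scale")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dups = self.df["variant_id"][self.df["variant_id"].duplicated()]
            raise SumstatsError(f"duplicate variant_id(s): {sorted(set(dups))[:5]}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.df.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            out.append(
                VariantAssociation(
                    variant_id=row.variant_id,
                    chromosome=str(row.chromosome),
                    position=int(row.position),
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    eaf=eaf,
                    beta=float(row.beta),
                    se=float(row.se),
                    pvalue=float(row.pvalue),
                    n=int(row.n),
                )
            )
        return out

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        keep = set(variant_ids)
        sub = self.df[self.df["variant_id"].isin(keep)].copy()
        return SummaryStats(self.trait_id, self.trait_class, sub, self.trait_scale)


def stats_from_records(
    trait_id: str,
    trait_class: str,
    records: Iterable[VariantAssociation],
    trait_scale: str = "",
) -> SummaryStats:
    """Build a SummaryStats from validated records."""
    rows = [
        (
            r.variant_id,
            r.chromosome,
            r.position,
            r.effect_allele,
            r.other_allele,
            np.nan if r.eaf is None else r.eaf,
            r.beta,
            r.se,
            r.pvalue,
            r.n,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    if df.empty:
        df = pd.DataFrame(
            {
                "variant_id": pd.Series(dtype=str),
                "chromosome": pd.Series(dtype=str),
                "position": pd.Series(dtype=int),
                "effect_allele": pd.Series(dtype=str),
                "other_allele": pd.Series(dtype=str),
                "eaf": pd.Series(dtype=float),
                "beta": pd.Series(dtype=float),
                "se": pd.Series(dtype=float),
                "pvalue": pd.Series(dtype=float),
                "n": pd.Series(dtype=int),
            }
        )
    df["chromosome"] = df["chromosome"].astype(str)
    return SummaryStats(trait_id, trait_class, df, trait_scale)


class LdMatrix:
    """Sparse symmetric pairwise r-squared lookup.

    Unlisted pairs are unlinked (r2 = 0); the diagonal is implicitly 1.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], float] | None = None,
        positions: Mapping[str, tuple[str, int]] | None = None,
    ):
        self._entries: dict[tuple[str, str], float] = {}
        self.positions: dict[str, tuple[str, int]] = dict(positions or {})
        for (a, b), r2 in (entries or {}).items():
            self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise LdValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            if r2 != 1.0:
                logger.warning("diagonal LD entry r2(%s,%s)=%s replaced by 1.0", a, b, r2)
            return
        self._entries[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._entries.get(self._key(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


def _coerce_float(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def read_sumstats(
    path: str | Path,
    trait_id: str,
    trait_class: str,
    column_map: Mapping[str, str] | None = None,
    trait_scale: str = "",
    delimiter: str | None = None,
) -> SummaryStats:
    """Read delimited summary statistics into a validated SummaryStats.

    ``column_map`` maps standard field names (see CANONICAL_COLUMNS) to the
    source file's column names; omit it when the file already uses canonical
    names.  Rows with non-positive se, missing beta, malformed alleles,
    out-of-range p-values, or missing n are dropped and counted in the load
    report; p = 0 is clamped to the smallest positive double and flagged.
    """
    path = Path(path)
    sep = delimiter if delimiter is not None else r"\s+"
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", "NaN", ""])
    except pd.errors.EmptyDataError:
        raise SumstatsError(f"{path}: empty input file") from None
    if raw.empty:
        raise SumstatsError(f"{path}: no data rows")

    cmap = dict(column_map or {})
    for std in CANONICAL_COLUMNS:
        cmap.setdefault(std, std)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: mapped column(s) not found in header: {missing}"
        )
    df = raw[[cmap[std] for std in CANONICAL_COLUMNS]].copy()
    df.columns = list(CANONICAL_COLUMNS)

    report = LoadReport(n_input=len(df))

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper().str.strip()
    df["other_allele"] = df["other_allele"].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pvalue", "n", "position"):
        df[col] = df[col].map(_coerce_float)

    def allele_ok(a: str) -> bool:
        return len(a) > 0 and set(a) <= VALID_BASES

    bad_alleles = ~(
        df["effect_allele"].map(allele_ok)
        & df["other_allele"].map(allele_ok)
        & (df["effect_allele"] != df["other_allele"])
    )
    bad_se = ~(df["se"] > 0)
    bad_beta = df["beta"].isna()
    bad_p = df["pvalue"].isna() | (df["pvalue"] < 0) | (df["pvalue"] > 1)
    bad_n = df["n"].isna() | (df["n"] <= 0)

    # each row dropped once, for the first applicable reason
    reason_masks = [
        ("se", bad_se),
        ("beta", bad_beta),
        ("alleles", bad_alleles),
        ("pvalue", bad_p),
        ("n", bad_n),
    ]
    dropped = pd.Series(False, index=df.index)
    for name, mask in reason_masks:
        newly = mask & ~dropped
        count = int(newly.sum())
        setattr(report, f"n_dropped_{name}", count)
        report.dropped_ids.extend(df.loc[newly, "variant_id"].tolist())
        dropped |= mask
    df = df[~dropped].copy()

    dup = df["variant_id"].duplicated(keep="first")
    report.n_dropped_duplicate = int(dup.sum())
    report.dropped_ids.extend(df.loc[dup, "variant_id"].tolist())
    df = df[~dup].copy()

    clamp = df["pvalue"] == 0.0
    report.n_clamped_pvalue = int(clamp.sum())
    df.loc[clamp, "pvalue"] = P_CLAMP

    oob_eaf = df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))
    df.loc[oob_eaf, "eaf"] = np.nan
    report.n_missing_eaf = int(df["eaf"].isna().sum())

    df["position"] = df["position"].astype(int)
    df["n"] = df["n"].astype(float).round().astype(int)
    df["chromosome"] = df["chromosome"].astype(str)
    report.n_retained = len(df)
    logger.info(
        "%s: read %d rows, retained %d, dropped %d",
        path,
        report.n_input,
        report.n_retained,
        report.n_dropped,
    )
    stats = SummaryStats(trait_id, trait_class, df.reset_index(drop=True), trait_scale)
    stats.load_report = report
    return stats


def write_sumstats(stats: SummaryStats, path: str | Path) -> Path:
    """Write canonical tab-delimited sumstats; missing eaf becomes "NA".

    Floats use the shortest round-trip representation, so a write/read
    round trip reproduces every retained field bit-for-bit.
    """
    if len(stats) == 0:
        raise SumstatsError("refusing to write empty SummaryStats")
    path = Path(path)
    out = stats.df[list(CANONICAL_COLUMNS)].copy()
    for col in ("eaf", "beta", "se", "pvalue"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)
    logger.info("%s: wrote %d records", path, len(out))
    return path


def read_ld(path: str | Path) -> LdMatrix:
    """Read a three-column (id_a, id_b, r2) LD table with symmetric closure."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        return LdMatrix()
    if df.shape[1] < 3:
        raise LdValidationError(f"{path}: expected three columns (id_a, id_b, r2)")
    ld = LdMatrix()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        a, b, r2 = str(row[0]), str(row[1]), float(row[2])
        if not (0.0 <= r2 <= 1.0):
            raise LdValidationError(f"{path}:{i}: r2 = {r2} outside [0, 1]")
        ld.set(a, b, r2)
    return ld


def write_ld(ld: LdMatrix, path: str | Path) -> Path:
    """Write an LD table as three-column tab-delimited text."""
    path = Path(path)
    rows = sorted(ld.items())
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tr2\n")
        for (a, b), r2 in rows:
            fh.write(f"{a}\t{b}\t{r2:.12g}\n")
    return path
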