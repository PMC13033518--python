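"""End-to-end orchestration of the four-step MR design.

1. Screen every candidate protein against the disease (instrument
   selection, harmonization, Steiger filtering, MR); keep IVW p < alpha.
2. Screen every microbial taxon against the disease the same way.
3. Pairwise taxon -> protein MR across every (passed taxon, passed
   protein) pair, all results retained regardless of significance.
4. Two-step mediation for every pair, ranking triplets by mediated
   proportion above a minimum.

No multiple-testing correction is applied anywhere — the screens are an
exploratory discovery device — but a Benjamini-Hochberg column is emitted
for reference.  Taxon instruments selected for the disease screen are
re-harmonized against each protein panel (not re-clumped per outcome).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import MrResult, run_mr
from .harmonize import harmonize_pair, steiger_filter
from .instruments import (
    F_MIN,
    InstrumentSet,
    PROTEIN_P_THRESHOLD,
    R2_MAX,
    TAXON_P_THRESHOLD,
    WINDOW_BP,
    select_instruments,
)
from .mediation import MediationTriplet, build_triplet, screen_triplets
from .sumstats import LdMatrix, SummaryStats, read_ld, read_sumstats

logger = logging.getLogger(__name__)

TABLE_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """All thresholds and inputs of a full run."""

    protein_p_threshold: float = PROTEIN_P_THRESHOLD
    taxon_p_threshold: float = TAXON_P_THRESHOLD
    r2_max: float = R2_MAX
    window_bp: int = WINDOW_BP
    f_min: float = F_MIN
    screen_alpha: float = 0.05
    min_proportion: float = 0.10
    palindromic_policy: str = "infer_by_eaf"
    eaf_tolerance: float = 0.08
    steiger: bool = True
    effects_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    # file-based inputs (optional for in-memory use)
    taxa_paths: dict = field(default_factory=dict)      # trait_id -> path
    protein_paths: dict = field(default_factory=dict)   # trait_id -> path
    disease_path: str = ""
    ld_path: str = ""
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("protein_p_threshold", "taxon_p_threshold", "r2_max",
                     "window_bp", "min_proportion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.screen_alpha < 1):
            raise ValueError("screen_alpha must be in (0, 1)")

    def p_threshold_for(self, trait_class: str) -> float:
        return (
            self.taxon_p_threshold if trait_class == "taxon"
            else self.protein_p_threshold
        )


@dataclass
class ScreenResult:
    """One exposure's disease screen: primary estimate plus diagnostics."""

    trait_id: str
    passed: bool
    skipped: bool
    reason: str = ""
    primary: MrResult | None = None
    results: list[MrResult] = field(default_factory=list)
    instruments: InstrumentSet | None = None
    counts: dict = field(default_factory=dict)


def _mr_for_exposure(
    instruments: InstrumentSet,
    outcome: SummaryStats,
    config: PipelineConfig,
) -> tuple[list[MrResult], dict, str]:
    """Harmonize instruments against an outcome and run the estimator
    suite; returns (results, stage counts, skip reason)."""
    pair = harmonize_pair(
        instruments, outcome,
        palindromic_policy=config.palindromic_policy,
        eaf_tolerance=config.eaf_tolerance,
    )
    counts = {"harmonized": pair.n_snp, **pair.report}
    if pair.skip:
        return [], counts, "empty_harmonized_intersection"
    if config.steiger:
        pair = steiger_filter(pair)
        counts["steiger_dropped"] = pair.report["steiger_dropped"]
        counts["after_steiger"] = pair.n_snp
    if pair.skip:
        return [], counts, "all_dropped_by_steiger"
    results = run_mr(
        pair,
        effects_model=config.effects_model,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    return results, counts, ""


def screen_exposures_on_outcome(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: LdMatrix,
    config: PipelineConfig,
) -> list[ScreenResult]:
    """Screen each exposure against the outcome; per-trait failures are
    recorded as skips and never abort the scan."""
    if not exposures:
        raise ValueError("empty exposure collection")
    out = []
    for stats in exposures:
        inst = select_instruments(
            stats, ld,
            p_threshold=config.p_threshold_for(stats.trait_class),
            r2_max=config.r2_max,
            window_bp=config.window_bp,
            f_min=config.f_min,
        )
        counts = dict(inst.report)
        if inst.skip:
            out.append(ScreenResult(stats.trait_id, passed=False, skipped=True,
                                    reason="no_instruments", instruments=inst,
                                    counts=counts))
            continue
        results, mr_counts, reason = _mr_for_exposure(inst, outcome, config)
        counts.update(mr_counts)
        if not results:
            out.append(ScreenResult(stats.trait_id, passed=False, skipped=True,
                                    reason=reason, instruments=inst, counts=counts))
            continue
        primary = next(r for r in results if r.role == "primary")
        out.append(
            ScreenResult(
                trait_id=stats.trait_id,
                passed=primary.pvalue < config.screen_alpha,
                skipped=False,
                primary=primary,
                results=results,
                instruments=inst,
                counts=counts,
            )
        )
    return out


@dataclass
class CrossMrScan:
    """Bookkeeping for the pairwise taxon -> protein scan."""

    attempts: int
    results: list[MrResult]
    primaries: dict  # (taxon_id, protein_id) -> MrResult
    skipped: list  # (taxon_id, protein_id, reason)


def cross_mr(
    taxa_instruments: list[InstrumentSet],
    proteins: list[SummaryStats],
    config: PipelineConfig,
) -> CrossMrScan:
    """One taxon -> protein MR per ordered pair; every pair counts as an
    attempt whether or not it yields shared instruments, and no
    significance filter is applied."""
    if not taxa_instruments or not proteins:
        raise ValueError("cross_mr requires non-empty taxa and protein collections")
    results: list[MrResult] = []
    primaries: dict = {}
    skipped: list = []
    attempts = 0
    for inst in taxa_instruments:
        for prot in proteins:
            attempts += 1
            if inst.skip:
                skipped.append((inst.trait_id, prot.trait_id, "no_instruments"))
                continue
            fits, _, reason = _mr_for_exposure(inst, prot, config)
            if not fits:
                skipped.append((inst.trait_id, prot.trait_id, reason))
                continue
            results.extend(fits)
            primaries[(inst.trait_id, prot.trait_id)] = next(
                r for r in fits if r.role == "primary"
            )
    return CrossMrScan(attempts=attempts, results=results, primaries=primaries,
                       skipped=skipped)


def _bh(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (reference column only)."""
    p = pvalues.to_numpy(float)
    m = p.size
    if m == 0:
        return pd.Series(dtype=float)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return pd.Series(np.minimum(adj, 1.0), index=pvalues.index)


def screen_table(screens: list[ScreenResult]) -> pd.DataFrame:
    rows = []
    for s in screens:
        base = {
            "trait_id": s.trait_id,
            "passed": s.passed,
            "skipped": s.skipped,
            "reason": s.reason,
            "n_instruments": len(s.instruments) if s.instruments else 0,
        }
        if s.primary is None:
            rows.append({**base, "method": "", "n_snp": 0})
        else:
            for r in s.results:
                rows.append({**base, **r.as_dict()})
    df = pd.DataFrame(rows)
    if len(df) and "pvalue" in df:
        primary = df["role"] == "primary"
        df["pvalue_bh"] = np.nan
        df.loc[primary, "pvalue_bh"] = _bh(df.loc[primary, "pvalue"])
    return df


def mr_table(results: list[MrResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def mediation_table(triplets: list[MediationTriplet]) -> pd.DataFrame:
    return pd.DataFrame([t.as_dict() for t in triplets])


@dataclass
class PipelineResult:
    protein_screen: pd.DataFrame
    taxon_screen: pd.DataFrame
    cross_mr: pd.DataFrame
    mediation: pd.DataFrame
    manifest: dict


def run_pipeline(
    taxa: list[SummaryStats],
    proteins: list[SummaryStats],
    disease: SummaryStats,
    ld: LdMatrix,
    config: PipelineConfig,
) -> PipelineResult:
    """The four-step design on in-memory inputs."""
    protein_screens = screen_exposures_on_outcome(proteins, disease, ld, config)
    taxon_screens = screen_exposures_on_outcome(taxa, disease, ld, config)
    passed_proteins = [s for s in protein_screens if s.passed]
    passed_taxa = [s for s in taxon_screens if s.passed]

    protein_by_id = {p.trait_id: p for p in proteins}
    scan = None
    triplets: list[MediationTriplet] = []
    if passed_taxa and passed_proteins:
        scan = cross_mr(
            [s.instruments for s in passed_taxa],
            [protein_by_id[s.trait_id] for s in passed_proteins],
            config,
        )
        for ts in passed_taxa:
            for ps in passed_proteins:
                step1 = scan.primaries.get((ts.trait_id, ps.trait_id))
                if step1 is None:
                    continue
                triplets.append(build_triplet(ts.primary, ps.primary, step1))
    screened = screen_triplets(triplets, min_proportion=config.min_proportion)

    med_df = mediation_table(screened.retained)
    if len(med_df):
        med_df["retained"] = True
    disc_df = mediation_table(screened.sign_discordant)
    if len(disc_df):
        disc_df["retained"] = False
    med_all = pd.concat([med_df, disc_df], ignore_index=True)

    manifest = {
        "config": {
            k: v for k, v in asdict(config).items()
            if k not in ("taxa_paths", "protein_paths")
        },
        "counts": {
            "proteins_in": len(proteins),
            "taxa_in": len(taxa),
            "proteins_passed": len(passed_proteins),
            "taxa_passed": len(passed_taxa),
            "proteins_skipped": sum(s.skipped for s in protein_screens),
            "taxa_skipped": sum(s.skipped for s in taxon_screens),
            "cross_mr_attempts": scan.attempts if scan else 0,
            "cross_mr_skipped": len(scan.skipped) if scan else 0,
            "triplets_built": len(triplets),
            "triplets_retained": len(screened.retained),
            "triplets_sign_discordant": len(screened.sign_discordant),
        },
        "skip_lists": {
            "proteins": [
                {"trait_id": s.trait_id, "reason": s.reason}
                for s in protein_screens if s.skipped
            ],
            "taxa": [
                {"trait_id": s.trait_id, "reason": s.reason}
                for s in taxon_screens if s.skipped
            ],
            "cross_mr": [
                {"taxon_id": t, "protein_id": p, "reason": r}
                for (t, p, r) in (scan.skipped if scan else [])
            ],
        },
    }
    return PipelineResult(
        protein_screen=screen_table(protein_screens),
        taxon_screen=screen_table(taxon_screens),
        cross_mr=mr_table(scan.results) if scan else pd.DataFrame(),
        mediation=med_all,
        manifest=manifest,
    )


def write_result(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write the four tables plus the JSON run manifest, byte-stable for a
    fixed (inputs, config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "protein_screen.tsv": result.protein_screen,
        "taxon_screen.tsv": result.taxon_screen,
        "cross_mr.tsv": result.cross_mr,
        "mediation.tsv": result.mediation,
    }
    for name, df in tables.items():
        df.to_csv(out / name, sep="\t", index=False,
                  float_format=TABLE_FLOAT_FORMAT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load every input named in the config, run
    the four steps, and write the tables under ``config.out_dir``."""
    try:
        disease = read_sumstats(config.disease_path, "disease", "disease")
    except Exception as exc:
        raise RuntimeError(f"[stage: load disease] {exc}") from exc
    ld = read_ld(config.ld_path) if config.ld_path else LdMatrix()
    taxa = [
        read_sumstats(path, tid, "taxon")
        for tid, path in sorted(config.taxa_paths.items())
    ]
    proteins = [
        read_sumstats(path, pid, "protein")
        for pid, path in sorted(config.protein_paths.items())
    ]
    result = run_pipeline(taxa, proteins, disease, ld, config)
    write_result(result, config.out_dir)
    return result
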