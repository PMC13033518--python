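"""Synthetic GWAS summary-statistics universes with known causal structure.

Generation is at the summary level (no individual genotypes): each exposure
trait receives a panel of instrument variants with true per-allele effects,
and observed betas are the true effects plus normal noise with the standard
allele-frequency standard error se = (2 n maf (1 - maf))^(-1/2).  A
taxon -> protein -> disease chain is planted through three parameters:
theta1 (taxon on protein), theta2 (protein on disease, log-odds) and
theta_direct (taxon on disease not via the protein), giving the identity
theta_total = theta_direct + theta1 * theta2.

Each trait gets its own instrument panel ("n_instruments per trait"): the
taxon's variants carry effects gamma_j, and the protein additionally has
pQTL-like variants of its own with direct effects on its level — exactly
the situation the real design exploits, where the protein -> disease path
is instrumented by the protein's own strong pQTLs rather than by taxon
variants it inherits weakly.  Per-variant horizontal pleiotropy enters on
the taxon panel as direct effects a_j on the protein and d_j on the
disease, nonzero for a configurable fraction of variants with a
configurable mean shift (zero-mean: balanced; nonzero: directional).

LD is block-constant: within a block every pair shares the same r-squared,
between blocks r-squared is 0 — the simplest structure that exercises
clumping nontrivially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedPair, ROW_COLUMNS, empty_report
from .sumstats import (
    LdMatrix,
    SummaryStats,
    VariantAssociation,
    stats_from_records,
    write_ld,
    write_sumstats,
)

import pandas as pd

# Cohort sizes of the data sources the generator emulates: a microbiome
# consortium GWAS, a plasma-proteomics cohort, and a biobank disease GWAS.
DEFAULT_N_TAXON = 18_340
DEFAULT_N_PROTEIN = 35_559
DEFAULT_N_DISEASE = 456_348

DEFAULT_MEAN_F = 30.0

#: disease case fraction of the emulated biobank cohort; binary phecodes
#: typically run from ~1% to ~10%, and the disease trait's standard errors
#: reflect the corresponding effective sample size 4 n phi (1 - phi)
DEFAULT_CASE_FRACTION = 0.05


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of one synthetic chain scenario."""

    scenario_id: str
    theta1: float = 0.0
    theta2: float = 0.0
    theta_direct: float = 0.0
    n_instruments: int = 15  # per exposure trait
    n_x: int = DEFAULT_N_TAXON
    n_m: int = DEFAULT_N_PROTEIN
    n_y: int = DEFAULT_N_DISEASE
    pleiotropy_frac: float = 0.0
    pleiotropy_shift: float = 0.0
    pleiotropy_sd: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    mean_f: float = DEFAULT_MEAN_F
    case_fraction: float = DEFAULT_CASE_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if not (0 <= self.ld_r2_within < 1):
            raise ValueError("ld_r2_within must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta1 * self.theta2

    def as_dict(self) -> dict:
        d = asdict(self)
        d["theta_total"] = self.theta_total
        return d


@dataclass
class InstrumentPanel:
    """True per-variant state for one exposure trait's instrument region."""

    variant_ids: list[str]
    chromosome: str
    positions: np.ndarray
    maf: np.ndarray
    gamma: np.ndarray  # true per-allele effects on the exposure
    ld: LdMatrix


def allele_se(n: int, maf: np.ndarray) -> np.ndarray:
    """Standard error of a per-allele effect at sample size n: the
    standardized-genotype form (2 n maf (1 - maf))^(-1/2)."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def effective_n(n: int, case_fraction: float) -> int:
    """Effective sample size of a binary-trait GWAS: 4 n phi (1 - phi).

    Real biobank binary GWAS rows report the total cohort size while their
    log-odds standard errors carry the information of the effective sample
    size; the generator reproduces that convention, applying the allele-
    frequency se formula at the effective n but writing total n in the
    sumstats (so downstream consumers, Steiger included, see what a real
    file would give them).
    """
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must be in (0, 1)")
    return max(4, int(round(4 * n * case_fraction * (1 - case_fraction))))


def simulate_instrument_panel(
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    prefix: str = "rs",
    chromosome: str = "1",
    start_bp: int = 1_000_000,
    spacing_bp: int = 100_000,
) -> InstrumentPanel:
    """Draw an instrument panel: block LD, uniform MAFs, and true exposure
    effects scaled so the mean per-SNP F at n_x matches ``truth.mean_f``.

    Within each ld_block_size-sized block one variant is causal and the
    rest tag it with correlation sqrt(ld_r2_within); blocks are mutually
    unlinked.
    """
    if truth.n_instruments <= 0:
        raise ValueError("n_instruments must be > 0")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    J = truth.n_instruments
    ids = [f"{prefix}{i + 1:05d}" for i in range(J)]
    positions = start_bp + spacing_bp * np.arange(J)
    maf = rng.uniform(*truth.maf_range, size=J)

    se_x = allele_se(truth.n_x, maf)
    # mean F = sd_gamma^2 * mean(1/se^2)  =>  solve for sd_gamma
    sd_gamma = np.sqrt(truth.mean_f / np.mean(1.0 / se_x**2))
    block = np.arange(J) // max(1, truth.ld_block_size)
    r = np.sqrt(truth.ld_r2_within)
    causal = rng.normal(0.0, sd_gamma, size=J)
    gamma = np.empty(J)
    ld = LdMatrix()
    for b in np.unique(block):
        members = np.flatnonzero(block == b)
        lead = members[0]
        gamma[lead] = causal[lead]
        for m in members[1:]:
            gamma[m] = r * causal[lead]  # marginal effect of a tag variant
        if truth.ld_r2_within > 0:
            for i in members:
                for j in members:
                    if i < j:
                        ld.set(ids[i], ids[j], truth.ld_r2_within)
    ld.positions.update({vid: (chromosome, int(p)) for vid, p in zip(ids, positions)})
    return InstrumentPanel(
        variant_ids=ids,
        chromosome=chromosome,
        positions=positions,
        maf=maf,
        gamma=gamma,
        ld=ld,
    )


def _observe(
    true_beta: np.ndarray, se: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    beta = rng.normal(true_beta, se)
    p = np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)
    return beta, p


def _panel_stats(
    trait_id: str,
    trait_class: str,
    panels: list[tuple[InstrumentPanel, np.ndarray]],
    n: int,
    rng: np.random.Generator,
    n_se: int | None = None,
) -> SummaryStats:
    """Observe one trait over several panels with given true effects.

    ``n_se`` is the sample size the noise scale is computed from (the
    effective n for binary traits); the reported n column always carries
    ``n``.
    """
    if n_se is None:
        n_se = n
    records = []
    for panel, true_beta in panels:
        se = allele_se(n_se, panel.maf)
        beta, p = _observe(true_beta, se, rng)
        for k, vid in enumerate(panel.variant_ids):
            records.append(
                VariantAssociation(
                    variant_id=vid,
                    chromosome=panel.chromosome,
                    position=int(panel.positions[k]),
                    effect_allele="A",
                    other_allele="G",
                    eaf=float(panel.maf[k]),
                    beta=float(beta[k]),
                    se=float(se[k]),
                    pvalue=float(p[k]),
                    n=n,
                )
            )
    return stats_from_records(trait_id, trait_class, records)


def simulate_chain_sumstats(
    truth: SimulationTruth,
    rng: np.random.Generator | None = None,
    taxon_id: str = "taxon",
    protein_id: str = "protein",
    disease_id: str = "disease",
) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimulationTruth]:
    """Observed summary statistics for one taxon -> protein -> disease chain.

    Taxon panel (effects gamma_j): protein true effect theta1*gamma_j + a_j,
    disease true effect theta_total*gamma_j + theta2*a_j + d_j, with a_j and
    d_j the pleiotropic terms.  Protein panel (own pQTLs b_j): disease true
    effect theta2*b_j; the taxon is unaffected.  All three traits report all
    variants, so harmonization intersections are complete.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    tax_panel = simulate_instrument_panel(
        truth, rng, prefix="rsT", chromosome="1", start_bp=1_000_000
    )
    # the protein's own panel, scaled to the same mean F at n_m
    prot_truth = SimulationTruth(
        scenario_id=truth.scenario_id,
        n_instruments=truth.n_instruments,
        n_x=truth.n_m,
        maf_range=truth.maf_range,
        ld_block_size=truth.ld_block_size,
        ld_r2_within=truth.ld_r2_within,
        mean_f=truth.mean_f,
        seed=truth.seed,
    )
    prot_panel = simulate_instrument_panel(
        prot_truth, rng, prefix="rsP", chromosome="2", start_bp=1_000_000
    )

    J = truth.n_instruments
    n_pleio = int(round(truth.pleiotropy_frac * J))
    pleio_idx = rng.choice(J, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    a = np.zeros(J)
    d = np.zeros(J)
    if n_pleio:
        a[pleio_idx] = rng.normal(truth.pleiotropy_shift, truth.pleiotropy_sd, n_pleio)
        d[pleio_idx] = rng.normal(truth.pleiotropy_shift, truth.pleiotropy_sd, n_pleio)

    g = tax_panel.gamma
    b = prot_panel.gamma
    zeros_p = np.zeros(J)
    taxon = _panel_stats(
        taxon_id, "taxon",
        [(tax_panel, g), (prot_panel, zeros_p)], truth.n_x, rng,
    )
    protein = _panel_stats(
        protein_id, "protein",
        [(tax_panel, truth.theta1 * g + a), (prot_panel, b)], truth.n_m, rng,
    )
    disease = _panel_stats(
        disease_id, "disease",
        [
            (tax_panel, truth.theta_total * g + truth.theta2 * a + d),
            (prot_panel, truth.theta2 * b),
        ],
        truth.n_y, rng,
        n_se=effective_n(truth.n_y, truth.case_fraction),
    )
    return taxon, protein, disease, truth


def merged_ld(panels: list[InstrumentPanel]) -> LdMatrix:
    out = LdMatrix()
    for p in panels:
        for (x, y), r2 in p.ld.items():
            out.set(x, y, r2)
        out.positions.update(p.ld.positions)
    return out


def chain_ld(truth: SimulationTruth) -> LdMatrix:
    """LD table matching simulate_chain_sumstats' two panels."""
    rng = np.random.default_rng(truth.seed)
    tax = simulate_instrument_panel(truth, rng, prefix="rsT", chromosome="1")
    prot_truth = SimulationTruth(
        scenario_id=truth.scenario_id,
        n_instruments=truth.n_instruments,
        n_x=truth.n_m,
        maf_range=truth.maf_range,
        ld_block_size=truth.ld_block_size,
        ld_r2_within=truth.ld_r2_within,
        mean_f=truth.mean_f,
        seed=truth.seed,
    )
    prot = simulate_instrument_panel(prot_truth, rng, prefix="rsP", chromosome="2")
    return merged_ld([tax, prot])


def chain_path_pairs(
    taxon: SummaryStats,
    protein: SummaryStats,
    disease: SummaryStats,
    steiger: bool = False,
) -> dict[str, HarmonizedPair]:
    """The three causal-path pairs of a simulated chain, instrumented by
    each exposure's own panel (taxon variants carry the ``rsT`` prefix,
    protein pQTLs the ``rsP`` prefix).

    Panel membership — not an observed p-value threshold — defines the
    instrument sets here, so estimator-recovery studies measure estimator
    behaviour free of winner's-curse selection.  Steiger filtering is off
    by default for the same reason: it is a directionality guard, and on
    the exactly-specified chain it can only select on noise.
    """
    from .harmonize import harmonize_pair, steiger_filter

    tax_own = taxon.subset([v for v in taxon.variant_ids if v.startswith("rsT")])
    prot_own = protein.subset([v for v in protein.variant_ids if v.startswith("rsP")])
    pairs = {
        "step1": harmonize_pair(tax_own, protein),
        "step2": harmonize_pair(prot_own, disease),
        "total": harmonize_pair(tax_own, disease),
    }
    if steiger:
        pairs = {k: steiger_filter(p) for k, p in pairs.items()}
    return pairs


def simulate_harmonized_pair(
    theta: float,
    n_snp: int,
    rng: np.random.Generator,
    se_y_scale: float = 0.05,
    se_x_scale: float = 0.02,
    mean_f: float = DEFAULT_MEAN_F,
    invalid_frac: float = 0.0,
    pleiotropy_delta: float = 0.0,
    balanced_pleiotropy_sd: float = 0.0,
    exposure_id: str = "x",
    outcome_id: str = "y",
    noiseless_x: bool = False,
    positive_x: bool = False,
) -> HarmonizedPair:
    """Directly simulate a harmonized exposure/outcome pair.

    A fast path for estimator calibration studies: true exposure effects
    are drawn with mean per-SNP F ``mean_f`` at noise scale ``se_x_scale``;
    outcome betas are theta * beta_x plus noise, the first ``invalid_frac``
    fraction of variants receive a directional pleiotropic offset
    ``pleiotropy_delta`` on the outcome, and ``balanced_pleiotropy_sd``
    adds a zero-mean pleiotropic term to every variant (heterogeneity
    without directionality).  ``noiseless_x`` reports the true exposure
    effects as observed (exactly calibrated nulls); ``positive_x`` orients
    all true exposure effects positive (the exposure-increasing-allele
    convention used in pleiotropy scenarios).
    """
    gx = rng.normal(0.0, se_x_scale * np.sqrt(mean_f), size=n_snp)
    if positive_x:
        gx = np.abs(gx)
    se_x = np.full(n_snp, se_x_scale)
    bx = gx if noiseless_x else rng.normal(gx, se_x)
    se_y = np.full(n_snp, se_y_scale)
    shift = np.zeros(n_snp)
    n_invalid = int(round(invalid_frac * n_snp))
    shift[:n_invalid] = pleiotropy_delta
    if balanced_pleiotropy_sd > 0:
        shift = shift + rng.normal(0.0, balanced_pleiotropy_sd, size=n_snp)
    by = rng.normal(theta * gx + shift, se_y)
    df = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1:05d}" for i in range(n_snp)],
            "beta_x": bx,
            "se_x": se_x,
            "beta_y": by,
            "se_y": se_y,
            "eaf_x": np.full(n_snp, 0.3),
            "n_x": np.full(n_snp, 50_000, dtype=int),
            "n_y": np.full(n_snp, 50_000, dtype=int),
            "palindromic": np.zeros(n_snp, dtype=bool),
            "flipped": np.zeros(n_snp, dtype=bool),
        },
        columns=list(ROW_COLUMNS),
    )
    report = empty_report()
    report["aligned"] = n_snp
    return HarmonizedPair(exposure_id, outcome_id, df, report)


@dataclass
class Universe:
    """An in-memory pipeline input: per-trait sumstats, LD, and the truth."""

    taxa: dict[str, SummaryStats]
    proteins: dict[str, SummaryStats]
    disease: SummaryStats
    ld: LdMatrix
    manifest: dict = field(default_factory=dict)


def simulate_universe(
    n_taxa: int,
    n_proteins: int,
    planted: list[SimulationTruth],
    seed: int,
    n_instruments: int = 15,
    n_x: int = DEFAULT_N_TAXON,
    n_m: int = DEFAULT_N_PROTEIN,
    n_y: int = DEFAULT_N_DISEASE,
    mean_f: float = DEFAULT_MEAN_F,
    case_fraction: float = DEFAULT_CASE_FRACTION,
    out_dir: str | Path | None = None,
) -> Universe:
    """A universe of taxa and proteins, null except for planted chains.

    Each planted SimulationTruth's scenario_id must be "<t>:<m>" with t in
    [0, n_taxa) and m in [0, n_proteins) naming the (taxon, protein) slot
    it occupies; duplicate slots are rejected.  When ``out_dir`` is given
    the universe is also written as canonical sumstats files, an LD table
    and a truth-manifest JSON.
    """
    slots: dict[tuple[int, int], SimulationTruth] = {}
    for tr in planted:
        try:
            t_str, m_str = tr.scenario_id.split(":")
            slot = (int(t_str), int(m_str))
        except ValueError:
            raise ValueError(
                f"planted scenario_id {tr.scenario_id!r} is not '<taxon>:<protein>'"
            ) from None
        if not (0 <= slot[0] < n_taxa and 0 <= slot[1] < n_proteins):
            raise ValueError(f"planted slot {slot} outside universe")
        if slot in slots:
            raise ValueError(f"duplicate planted slot {slot}")
        slots[slot] = tr

    rng = np.random.default_rng(seed)
    base = SimulationTruth(
        scenario_id="universe",
        n_instruments=n_instruments,
        n_x=n_x,
        n_m=n_m,
        n_y=n_y,
        mean_f=mean_f,
        seed=seed,
    )
    # one panel per exposure trait, each on its own chromosome region
    taxa_panels = []
    for t in range(n_taxa):
        taxa_panels.append(
            simulate_instrument_panel(
                base, rng, prefix=f"rsT{t}_", chromosome=str(t % 22 + 1),
                start_bp=1_000_000 + 30_000_000 * (t // 22),
            )
        )
    prot_base = SimulationTruth(
        scenario_id="universe", n_instruments=n_instruments, n_x=n_m,
        mean_f=mean_f, seed=seed,
    )
    prot_panels = []
    for m in range(n_proteins):
        prot_panels.append(
            simulate_instrument_panel(
                prot_base, rng, prefix=f"rsM{m}_", chromosome=str(m % 22 + 1),
                start_bp=200_000_000 + 30_000_000 * (m // 22),
            )
        )

    def chain_for(t: int, m: int) -> SimulationTruth | None:
        return slots.get((t, m))

    taxa_stats: dict[str, SummaryStats] = {}
    for t, panel in enumerate(taxa_panels):
        tid = f"taxon_{t:02d}"
        panels = [(panel, panel.gamma)]
        for other_t, op in enumerate(taxa_panels):
            if other_t != t:
                panels.append((op, np.zeros(n_instruments)))
        for op in prot_panels:
            panels.append((op, np.zeros(n_instruments)))
        taxa_stats[tid] = _panel_stats(tid, "taxon", panels, n_x, rng)

    prot_stats: dict[str, SummaryStats] = {}
    for m, panel in enumerate(prot_panels):
        pid = f"protein_{m:02d}"
        panels = [(panel, panel.gamma)]
        for other_m, op in enumerate(prot_panels):
            if other_m != m:
                panels.append((op, np.zeros(n_instruments)))
        for t, op in enumerate(taxa_panels):
            tr = chain_for(t, m)
            effect = tr.theta1 * op.gamma if tr else np.zeros(n_instruments)
            panels.append((op, effect))
        prot_stats[pid] = _panel_stats(pid, "protein", panels, n_m, rng)

    disease_panels = []
    for t, op in enumerate(taxa_panels):
        effect = np.zeros(n_instruments)
        for m in range(n_proteins):
            tr = chain_for(t, m)
            if tr:
                effect = effect + tr.theta_total * op.gamma
        disease_panels.append((op, effect))
    for m, op in enumerate(prot_panels):
        effect = np.zeros(n_instruments)
        for t in range(n_taxa):
            tr = chain_for(t, m)
            if tr:
                effect = effect + tr.theta2 * op.gamma
        disease_panels.append((op, effect))
    disease = _panel_stats("disease", "disease", disease_panels, n_y, rng,
                           n_se=effective_n(n_y, case_fraction))

    ld = merged_ld(taxa_panels + prot_panels)
    manifest = {
        "seed": seed,
        "n_taxa": n_taxa,
        "n_proteins": n_proteins,
        "n_instruments": n_instruments,
        "sample_sizes": {"taxon": n_x, "protein": n_m, "disease": n_y},
        "case_fraction": case_fraction,
        "mean_f": mean_f,
        "planted": [
            {"taxon": f"taxon_{t:02d}", "protein": f"protein_{m:02d}", **tr.as_dict()}
            for (t, m), tr in sorted(slots.items())
        ],
    }
    uni = Universe(taxa=taxa_stats, proteins=prot_stats, disease=disease, ld=ld,
                   manifest=manifest)
    if out_dir is not None:
        write_universe(uni, out_dir)
    return uni


def write_universe(uni: Universe, out_dir: str | Path) -> Path:
    """Write a universe as a ready-to-run pipeline input directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tid, stats in uni.taxa.items():
        write_sumstats(stats, out / f"{tid}.tsv")
    for pid, stats in uni.proteins.items():
        write_sumstats(stats, out / f"{pid}.tsv")
    write_sumstats(uni.disease, out / "disease.tsv")
    write_ld(uni.ld, out / "ld.tsv")
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(uni.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
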