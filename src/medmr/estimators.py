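"""Two-sample MR estimators and diagnostics.

Implemented from their closed forms on harmonized per-variant effect pairs
(beta_Xj, beta_Yj) with outcome standard errors se_Yj:

* Wald ratio — single-instrument estimate beta_Y / beta_X with first-order
  SE |se_Y / beta_X|.
* IVW — weighted regression of beta_Y on beta_X through the origin with
  weights 1/se_Y^2; the primary estimator.  The default multiplicative
  random-effects model inflates the fixed-effect SE by
  max(1, sqrt(Q / (n - 1))), so it never reports less uncertainty than the
  fixed model.
* Cochran's Q — heterogeneity of per-variant ratio estimates about the IVW
  estimate, chi-square with n - 1 df under homogeneity.
* MR-Egger — weighted regression with a free intercept after orienting all
  exposure effects non-negative; a nonzero intercept indicates directional
  pleiotropy.  Inference uses the t distribution with n - 2 df and the same
  lower-bounded over-dispersion scaling.
* Weighted median — consistent when under half the instrument weight comes
  from invalid instruments; SE by seeded parametric bootstrap.
* Leave-one-out — one IVW fit per excluded variant.

``run_mr`` dispatches on instrument count (1: Wald ratio; 2: IVW; >= 3:
IVW + MR-Egger + weighted median) and tags the IVW/Wald fit as primary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedPair

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000
DEFAULT_SEED = 20260316


class EstimatorError(ValueError):
    """Degenerate or insufficient instruments for the requested estimator."""


@dataclass(frozen=True)
class MrResult:
    """One estimator's causal estimate plus diagnostics."""

    exposure_id: str
    outcome_id: str
    method: str  # wald_ratio | ivw | egger | weighted_median
    n_snp: int
    beta: float
    se: float
    pvalue: float
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    role: str = ""  # primary | sensitivity

    def as_dict(self) -> dict:
        return {
            "exposure_id": self.exposure_id,
            "outcome_id": self.outcome_id,
            "method": self.method,
            "role": self.role,
            "n_snp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pvalue": self.egger_intercept_pvalue,
        }


def _norm_p(z: float) -> float:
    return float(np.clip(2.0 * sps.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))


def wald_ratio(pair_or_row, exposure_id: str = "", outcome_id: str = "") -> MrResult:
    """Single-instrument causal estimate beta_Y/beta_X.

    Accepts a one-row HarmonizedPair or any object with beta_x/se_x/beta_y/
    se_y attributes.  The first-order SE ignores exposure-side uncertainty.
    """
    if isinstance(pair_or_row, HarmonizedPair):
        if pair_or_row.n_snp != 1:
            raise EstimatorError("wald_ratio requires exactly one instrument")
        row = pair_or_row.df.iloc[0]
        beta_x, beta_y, se_y = float(row["beta_x"]), float(row["beta_y"]), float(row["se_y"])
        exposure_id = exposure_id or pair_or_row.exposure_id
        outcome_id = outcome_id or pair_or_row.outcome_id
    else:
        beta_x, beta_y, se_y = pair_or_row.beta_x, pair_or_row.beta_y, pair_or_row.se_y
    if beta_x == 0:
        raise EstimatorError("wald_ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return MrResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        method="wald_ratio",
        n_snp=1,
        beta=beta,
        se=se,
        pvalue=_norm_p(beta / se),
    )


def cochran_q(pair: HarmonizedPair, beta_ivw: float) -> tuple[float, int, float]:
    """Heterogeneity Q of per-variant ratios about ``beta_ivw``.

    Variants with beta_x = 0 are excluded with a warning (their ratio is
    undefined); df counts the included variants minus one.
    """
    bx, _, by, sy = pair.arrays()
    ok = bx != 0
    if not ok.all():
        logger.warning("cochran_q: excluding %d variant(s) with beta_x = 0",
                       int((~ok).sum()))
    bx, by, sy = bx[ok], by[ok], sy[ok]
    if bx.size < 2:
        raise EstimatorError("cochran_q requires >= 2 usable instruments")
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - beta_ivw) ** 2))
    df = int(bx.size - 1)
    return q, df, float(np.clip(sps.chi2.sf(q, df), np.nextafter(0, 1), 1.0))


def ivw(pair: HarmonizedPair, effects_model: str = "multiplicative_random") -> MrResult:
    """Inverse-variance-weighted estimate (regression through the origin).

    A single-instrument pair delegates to the Wald ratio.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    if pair.n_snp == 0:
        raise EstimatorError("ivw on empty pair")
    if pair.n_snp == 1:
        return wald_ratio(pair)
    bx, _, by, sy = pair.arrays()
    if np.all(bx == 0):
        raise EstimatorError("ivw degenerate: all exposure betas are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se_fixed = denom**-0.5
    q, q_df, q_p = cochran_q(pair, beta)
    se = se_fixed
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (pair.n_snp - 1)))
    return MrResult(
        exposure_id=pair.exposure_id,
        outcome_id=pair.outcome_id,
        method="ivw",
        n_snp=pair.n_snp,
        beta=beta,
        se=float(se),
        pvalue=_norm_p(beta / se),
        q_stat=q,
        q_df=q_df,
        q_pvalue=q_p,
    )


def mr_egger(pair: HarmonizedPair) -> MrResult:
    """MR-Egger regression: slope is the causal estimate, the intercept
    tests directional pleiotropy.  Rows are oriented so beta_x >= 0 (both
    betas of a row are negated together, leaving ratios unchanged)."""
    if pair.n_snp < 3:
        raise EstimatorError("mr_egger requires >= 3 instruments")
    bx, _, by, sy = pair.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise EstimatorError("mr_egger degenerate: no variance in oriented beta_x")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    n, df = bx.size, bx.size - 2
    rss_w = float(np.sum(w * resid**2))
    sigma = np.sqrt(rss_w / df)
    base_se = np.sqrt(np.diag(np.linalg.inv(xtwx)))
    scale = max(1.0, sigma)
    se_int, se_slope = base_se * scale
    intercept, slope = coef

    def t_p(est, se):
        return float(np.clip(2.0 * sps.t.sf(abs(est / se), df), np.nextafter(0, 1), 1.0))

    return MrResult(
        exposure_id=pair.exposure_id,
        outcome_id=pair.outcome_id,
        method="egger",
        n_snp=n,
        beta=float(slope),
        se=float(se_slope),
        pvalue=t_p(slope, se_slope),
        q_stat=rss_w,
        q_df=df,
        q_pvalue=float(np.clip(sps.chi2.sf(rss_w, df), np.nextafter(0, 1), 1.0)),
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_pvalue=t_p(intercept, se_int),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    b, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, cum, b))


def weighted_median(
    pair: HarmonizedPair,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> MrResult:
    """Weighted-median estimate over per-variant ratios, inverse-variance
    weighted; SE from a seeded parametric bootstrap that resamples each
    variant's (beta_x, beta_y) from normal(estimate, se)."""
    if pair.n_snp < 3:
        raise EstimatorError("weighted_median requires >= 3 instruments")
    bx, sx, by, sy = pair.arrays()
    if np.any(bx == 0):
        raise EstimatorError("weighted_median undefined with beta_x = 0 rows")
    w = bx**2 / sy**2
    beta = _weighted_median(by / bx, w)

    rng = np.random.default_rng(seed)
    J = bx.size
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    bx_b[bx_b == 0] = np.finfo(float).tiny  # keep bootstrap ratios finite
    est = np.empty(n_boot)
    for i in range(n_boot):
        est[i] = _weighted_median(by_b[i] / bx_b[i], bx_b[i] ** 2 / sy**2)
    se = float(np.std(est, ddof=1))
    return MrResult(
        exposure_id=pair.exposure_id,
        outcome_id=pair.outcome_id,
        method="weighted_median",
        n_snp=pair.n_snp,
        beta=beta,
        se=se,
        pvalue=_norm_p(beta / se) if se > 0 else 1.0,
    )


def leave_one_out(
    pair: HarmonizedPair, effects_model: str = "multiplicative_random"
) -> list[tuple[str, MrResult]]:
    """IVW refit excluding each variant in turn, in input order."""
    if pair.n_snp < 3:
        raise EstimatorError("leave_one_out requires >= 3 instruments")
    out = []
    for i, vid in enumerate(pair.df["variant_id"]):
        mask = np.zeros(pair.n_snp, dtype=bool)
        mask[i] = True
        out.append((str(vid), ivw(pair.drop_rows(mask), effects_model)))
    return out


def run_mr(
    pair: HarmonizedPair,
    effects_model: str = "multiplicative_random",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
) -> list[MrResult]:
    """Estimator suite dispatched on instrument count.

    1 instrument: Wald ratio only; 2: IVW only; >= 3: IVW plus MR-Egger and
    weighted-median sensitivity fits.  The IVW (or Wald) result is tagged
    ``primary``.  An empty pair returns an empty list (callers record the
    skip).
    """
    if pair.skip:
        return []
    if pair.n_snp == 1:
        return [replace(wald_ratio(pair), role="primary")]
    results = [replace(ivw(pair, effects_model), role="primary")]
    if pair.n_snp >= 3:
        results.append(replace(mr_egger(pair), role="sensitivity"))
        results.append(
            replace(weighted_median(pair, n_boot=n_boot, seed=seed), role="sensitivity")
        )
    return results
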