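"""Univariable two-sample MR estimators and sensitivity statistics.

All estimators consume a :class:`~mrmediation.sumstats.HarmonizedPanel`
with the exposure as one column and the outcome as another. Per-SNP Wald
ratios use the first-order approximation ``se = se_outcome / |beta_exposure|``
(exposure uncertainty neglected, the standard two-sample convention when
instruments are strong).

Estimators
----------
ivw
    Inverse-variance weighted meta-analysis of Wald ratios; identical to
    weighted least squares of outcome betas on exposure betas through the
    origin with weights 1/se_outcome². Fixed-effect or multiplicative
    random-effects standard errors.
egger
    Weighted regression with an unconstrained intercept; the intercept
    estimates average directional pleiotropy, the slope is a
    pleiotropy-robust causal estimate under the InSIDE assumption.
weighted_median
    Consistent when at least half the instrument weight is valid; SE by
    seeded parametric bootstrap.
cochran_q
    Heterogeneity of the per-SNP ratios around the IVW estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .errors import InsufficientInstrumentsError
from .sumstats import HarmonizedPanel

Z95 = 1.96  # normal-approximation 95% CI multiplier


@dataclass
class MREstimate:
    """One estimator's causal-effect result.

    ``beta`` is the effect on the outcome scale (log-odds for a binary
    outcome) per SD of the exposure; ``or_scale`` holds the
    exp-transformed (OR, low, high) triple iff the outcome was declared
    binary.
    """

    method: str
    beta: float
    se: float
    ci95: tuple[float, float]
    pval: float
    n_snps: int
    or_scale: tuple[float, float, float] | None = None

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "pval": self.pval,
            "n_snps": self.n_snps,
        }
        if self.or_scale is not None:
            row["or"], row["or_ci_low"], row["or_ci_high"] = self.or_scale
        return row


@dataclass
class SensitivityReport:
    """Cochran's Q heterogeneity and the MR-Egger intercept test."""

    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    def merged(self, other: "SensitivityReport") -> "SensitivityReport":
        def pick(a, b):
            return a if a is not None else b

        return SensitivityReport(
            q_stat=pick(self.q_stat, other.q_stat),
            q_df=pick(self.q_df, other.q_df),
            q_pval=pick(self.q_pval, other.q_pval),
            egger_intercept=pick(self.egger_intercept, other.egger_intercept),
            egger_intercept_se=pick(
                self.egger_intercept_se, other.egger_intercept_se
            ),
            egger_intercept_pval=pick(
                self.egger_intercept_pval, other.egger_intercept_pval
            ),
        )


def _estimate(method, beta, se, n_snps, binary_outcome) -> MREstimate:
    ci = (beta - Z95 * se, beta + Z95 * se)
    pval = float(np.clip(2.0 * norm.sf(abs(beta) / se), 5e-324, 1.0))
    or_scale = None
    if binary_outcome:
        or_scale = (float(np.exp(beta)), float(np.exp(ci[0])), float(np.exp(ci[1])))
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci95=(float(ci[0]), float(ci[1])),
        pval=pval,
        n_snps=int(n_snps),
        or_scale=or_scale,
    )


def _columns(panel: HarmonizedPanel, exposure, outcome):
    exposure = panel.traits[0] if exposure is None else exposure
    outcome = panel.traits[-1] if outcome is None else outcome
    bx = panel.beta_matrix[exposure].to_numpy(dtype=float)
    sx = panel.se_matrix[exposure].to_numpy(dtype=float)
    by = panel.beta_matrix[outcome].to_numpy(dtype=float)
    sy = panel.se_matrix[outcome].to_numpy(dtype=float)
    return bx, sx, by, sy


def wald_ratios(
    panel: HarmonizedPanel,
    exposure: str | None = None,
    outcome: str | None = None,
) -> pd.DataFrame:
    """Per-SNP causal estimates: ratio = betaY/betaX, se = seY/|betaX|.

    SNPs with an exactly zero exposure beta are excluded with a warning
    (their ratio is undefined).
    """
    bx, _, by, sy = _columns(panel, exposure, outcome)
    ok = bx != 0.0
    if not ok.all():
        bad = [s for s, m in zip(panel.snp_ids, ok) if not m]
        warnings.warn(
            f"excluding {len(bad)} SNP(s) with zero exposure beta: {bad[:5]}",
            stacklevel=2,
        )
    idx = pd.Index(np.asarray(panel.snp_ids)[ok], name="snp")
    return pd.DataFrame(
        {"ratio": by[ok] / bx[ok], "se": sy[ok] / np.abs(bx[ok])}, index=idx
    )


def ivw(
    panel: HarmonizedPanel,
    re_model: str = "multiplicative_random",
    exposure: str | None = None,
    outcome: str | None = None,
    binary_outcome: bool = False,
    allow_single: bool = False,
) -> MREstimate:
    """Inverse-variance weighted estimate of the causal effect.

    ``re_model='fixed'`` uses the fixed-effect SE ``(Σ w)^-1/2``;
    ``'multiplicative_random'`` (default) inflates it by
    ``max(1, sqrt(Q/(n-1)))`` so that heterogeneity widens, never
    narrows, the interval.
    """
    if re_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown re_model {re_model!r}")
    ratios = wald_ratios(panel, exposure, outcome)
    n = len(ratios)
    if n < 2 and not allow_single:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments, got {n} (use wald_ratios for one)"
        )
    if n < 1:
        raise InsufficientInstrumentsError("no usable instruments")
    r = ratios["ratio"].to_numpy()
    w = 1.0 / ratios["se"].to_numpy() ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    se = se_fixed
    if re_model == "multiplicative_random" and n > 1:
        q = float(np.sum(w * (r - beta) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (n - 1)))
    return _estimate("IVW", beta, se, n, binary_outcome)


def egger(
    panel: HarmonizedPanel,
    exposure: str | None = None,
    outcome: str | None = None,
    binary_outcome: bool = False,
) -> tuple[MREstimate, SensitivityReport]:
    """MR-Egger regression: slope (causal estimate) plus intercept test.

    SNPs are oriented so every exposure beta is positive before fitting
    (Egger is not orientation-invariant; this is the standard convention).
    SEs use multiplicative overdispersion scaling ``max(1, sqrt(RSS/(n-2)))``.
    """
    bx, _, by, sy = _columns(panel, exposure, outcome)
    ok = bx != 0.0
    bx, by, sy = bx[ok], by[ok], sy[ok]
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(f"Egger needs >= 3 instruments, got {n}")
    flip = np.sign(bx)
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (n - 2)))
    cov = np.linalg.inv(xtwx) * scale**2
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))

    est = _estimate("Egger", slope, se_slope, n, binary_outcome)
    p_inter = float(np.clip(2.0 * norm.sf(abs(inter) / se_inter), 5e-324, 1.0))
    report = SensitivityReport(
        egger_intercept=float(inter),
        egger_intercept_se=float(se_inter),
        egger_intercept_pval=p_inter,
    )
    return est, report


def _weighted_median_core(r: np.ndarray, w: np.ndarray) -> float:
    """Lower weighted median with tie-averaging at an exact 0.5 crossing.

    Order ratios ascending; the estimate is the first ratio at which the
    running sum of normalized weights reaches 0.5. When the running sum
    hits 0.5 exactly, the two bracketing ratios are averaged (so two
    equally weighted SNPs yield their midpoint, like a plain median).
    A SNP carrying more than half the total weight is therefore the
    estimate outright.
    """
    order = np.argsort(r, kind="mergesort")
    r = r[order]
    w = w[order] / np.sum(w)
    c = np.cumsum(w)
    j = int(np.searchsorted(c, 0.5))
    if j < len(r) - 1 and np.isclose(c[j], 0.5, rtol=0, atol=1e-12):
        return 0.5 * (r[j] + r[j + 1])
    return float(r[j])


def weighted_median(
    panel: HarmonizedPanel,
    n_boot: int = 1000,
    seed: int | None = None,
    exposure: str | None = None,
    outcome: str | None = None,
    binary_outcome: bool = False,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Weights are normalized inverse variances of the Wald ratios. The SE
    is the SD of the estimate over ``n_boot`` resamples of the per-SNP
    exposure and outcome betas from their sampling distributions.
    """
    exposure = panel.traits[0] if exposure is None else exposure
    outcome_t = panel.traits[-1] if outcome is None else outcome
    bx, sx, by, sy = _columns(panel, exposure, outcome_t)
    ok = bx != 0.0
    bx, sx, by, sy = bx[ok], sx[ok], by[ok], sy[ok]
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 instruments, got {n}"
        )
    r = by / bx
    sr = sy / np.abs(bx)
    beta = _weighted_median_core(r, 1.0 / sr**2)

    rng = np.random.default_rng(seed)
    bxb = bx + rng.standard_normal((n_boot, n)) * sx
    byb = by + rng.standard_normal((n_boot, n)) * sy
    bxb = np.where(bxb == 0.0, np.finfo(float).tiny, bxb)
    rb = byb / bxb
    wb = (np.abs(bxb) / sy) ** 2  # 1/ratio_se², recomputed per resample

    order = np.argsort(rb, axis=1, kind="mergesort")
    rb = np.take_along_axis(rb, order, axis=1)
    wb = np.take_along_axis(wb, order, axis=1)
    cb = np.cumsum(wb, axis=1)
    cb /= cb[:, -1][:, None]
    j = np.apply_along_axis(lambda c: np.searchsorted(c, 0.5), 1, cb)
    boots = rb[np.arange(n_boot), j]
    se = float(np.std(boots, ddof=1))
    return _estimate("WeightedMedian", beta, se, n, binary_outcome)


def cochran_q(
    panel: HarmonizedPanel,
    exposure: str | None = None,
    outcome: str | None = None,
) -> SensitivityReport:
    """Cochran's Q heterogeneity of Wald ratios around the IVW estimate."""
    ratios = wald_ratios(panel, exposure, outcome)
    n = len(ratios)
    if n < 2:
        raise InsufficientInstrumentsError(f"Q needs >= 2 instruments, got {n}")
    r = ratios["ratio"].to_numpy()
    w = 1.0 / ratios["se"].to_numpy() ** 2
    beta = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - beta) ** 2))
    return SensitivityReport(
        q_stat=q, q_df=n - 1, q_pval=float(chi2.sf(q, n - 1))
    )


def sensitivity_report(
    panel: HarmonizedPanel,
    exposure: str | None = None,
    outcome: str | None = None,
) -> SensitivityReport:
    """Combined Q heterogeneity + Egger-intercept pleiotropy report."""
    qrep = cochran_q(panel, exposure, outcome)
    _, erep = egger(panel, exposure, outcome)
    return qrep.merged(erep)


def outlier_report(
    panel: HarmonizedPanel,
    exposure: str | None = None,
    outcome: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Standardized-residual outlier flagging (report only, no removal).

    Residuals of the Wald ratios around the IVW estimate, standardized by
    their ratio SEs; a SNP is flagged when |z| exceeds the two-sided
    Bonferroni threshold at level ``alpha``. Flagged SNPs are candidates
    for pleiotropy, left to the analyst's judgement.
    """
    ratios = wald_ratios(panel, exposure, outcome)
    r = ratios["ratio"].to_numpy()
    w = 1.0 / ratios["se"].to_numpy() ** 2
    beta = np.sum(w * r) / np.sum(w)
    z = (r - beta) * np.sqrt(w)
    thresh = norm.isf(alpha / (2 * len(r)))
    return pd.DataFrame(
        {"residual_z": z, "flagged": np.abs(z) > thresh}, index=ratios.index
    )
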