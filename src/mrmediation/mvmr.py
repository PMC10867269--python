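"""Multivariable MR: joint direct effects of several traits on an outcome.

Weighted multiple linear regression (no intercept) of outcome betas on
the matrix of exposure/mediator betas, weights 1/se_outcome². With the
exposure included as a column, each mediator's coefficient is its direct
effect on the outcome conditional on the exposure — the β2 of two-step
mediation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import CollinearityError, InsufficientInstrumentsError
from .sumstats import HarmonizedPanel
from .uvmr import Z95


@dataclass
class MVMRResult:
    """Direct-effect estimates for each included trait.

    ``estimates`` has one row per trait with columns beta, se, ci_low,
    ci_high, pval (plus or/or_ci_low/or_ci_high for a binary outcome).
    ``conditional_f`` holds per-trait conditional instrument-strength
    diagnostics (not used for filtering).
    """

    estimates: pd.DataFrame
    n_snps: int
    conditioned_on: list[str]
    outcome: str
    conditional_f: dict[str, float] = field(default_factory=dict)

    def row(self, trait: str) -> pd.Series:
        return self.estimates.loc[trait]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise when two (non-null) columns are linearly dependent."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the most collinear pair for the error message
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            f"instrument-effect matrix is rank deficient; most collinear "
            f"pair: {names[i]!r} and {names[j]!r} (|r|={abs(corr[i, j]):.3f})"
        )


def mvmr_ivw(
    panel: HarmonizedPanel,
    outcome: str | None = None,
    exposures: list[str] | None = None,
    binary_outcome: bool = False,
) -> MVMRResult:
    """Multivariable IVW: weighted regression of outcome on trait betas.

    Coefficient SEs come from the weighted regression with multiplicative
    overdispersion scaling ``max(1, sqrt(Q/(n-k)))``, matching the
    univariable IVW convention.
    """
    outcome = panel.traits[-1] if outcome is None else outcome
    if exposures is None:
        exposures = [t for t in panel.traits if t != outcome]
    if len(exposures) < 2:
        raise InsufficientInstrumentsError(
            "multivariable MR needs >= 2 non-outcome traits; "
            "use univariable ivw() otherwise"
        )
    X_full = panel.beta_matrix[exposures].to_numpy(dtype=float)
    y = panel.beta_matrix[outcome].to_numpy(dtype=float)
    sy = panel.se_matrix[outcome].to_numpy(dtype=float)
    n, k = X_full.shape
    if n <= k:
        raise InsufficientInstrumentsError(
            f"need more SNPs ({n}) than included traits ({k})"
        )
    # a trait with all-zero instrument effects carries no signal: its
    # direct effect is identically 0 and it is excluded from the fit, so
    # the remaining coefficients reduce to the nested model
    nonzero = [i for i in range(k) if np.any(X_full[:, i] != 0.0)]
    X = X_full[:, nonzero]
    active = [exposures[i] for i in nonzero]
    _check_rank(X, active)

    w = 1.0 / sy**2
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef_a = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef_a
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (n - len(nonzero)))
    cov = np.linalg.inv(xtwx) * phi
    se_a = np.sqrt(np.diag(cov))
    coef = np.zeros(k)
    se = np.full(k, np.inf)
    coef[nonzero] = coef_a
    se[nonzero] = se_a

    rows = {}
    for i, t in enumerate(exposures):
        b, s = float(coef[i]), float(se[i])
        row = {
            "beta": b,
            "se": s,
            "ci_low": b - Z95 * s,
            "ci_high": b + Z95 * s,
            "pval": float(np.clip(2.0 * norm.sf(abs(b) / s), 5e-324, 1.0)),
        }
        if binary_outcome:
            row["or"] = float(np.exp(b))
            row["or_ci_low"] = float(np.exp(row["ci_low"]))
            row["or_ci_high"] = float(np.exp(row["ci_high"]))
        rows[t] = row
    est = pd.DataFrame.from_dict(rows, orient="index").loc[exposures]
    est.index.name = "trait"

    return MVMRResult(
        estimates=est,
        n_snps=n,
        conditioned_on=list(exposures),
        outcome=outcome,
        conditional_f=conditional_f(panel, exposures),
    )


def conditional_f(
    panel: HarmonizedPanel, exposures: list[str]
) -> dict[str, float]:
    """Conditional instrument-strength diagnostic per included trait.

    For trait t, its betas are regressed on the other included traits'
    betas (weights 1/se_t²) and the mean squared standardized residual is
    reported — a heuristic analogue of the conditional F statistic.
    Values near 1 indicate no instrument signal left after conditioning;
    diagnostics only, never a filter.
    """
    out: dict[str, float] = {}
    B = panel.beta_matrix[exposures].to_numpy(dtype=float)
    S = panel.se_matrix[exposures].to_numpy(dtype=float)
    k = len(exposures)
    for i, t in enumerate(exposures):
        y = B[:, i]
        s = S[:, i]
        if k == 1:
            resid = y
        else:
            X = np.delete(B, i, axis=1)
            w = 1.0 / s**2
            coef, *_ = np.linalg.lstsq(
                np.sqrt(w)[:, None] * X, np.sqrt(w) * y, rcond=None
            )
            resid = y - X @ coef
        out[t] = float(np.mean((resid / s) ** 2))
    return out
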