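"""Two-step MR mediation: coefficient products, proportions, delta-method SEs.

The indirect effect of the exposure on the outcome through mediator k is
the coefficient product β1_k·β2_k, where β1_k is the exposure→mediator
effect (univariable MR) and β2_k the mediator→outcome direct effect
(multivariable MR adjusting for the exposure). The proportion mediated is
indirect/total. Uncertainty uses first-order delta-method approximations
with zero covariance across the independent GWAS samples; all arithmetic
is on the log-odds scale for a binary outcome — odds ratios only at
presentation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import UnitError
from .uvmr import Z95, MREstimate


@dataclass
class MediationResult:
    """Decomposition of one mediator's pathway.

    Invariants: ``indirect == beta1 * beta2`` and
    ``proportion == indirect / total`` exactly;
    ``ci95 = proportion ± 1.96 * se_prop``.
    """

    mediator_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    se_indirect: float
    total: float
    se_total: float
    proportion: float
    se_prop: float
    ci95: tuple[float, float]

    def to_row(self) -> dict:
        return {
            "mediator": self.mediator_id,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "indirect": self.indirect,
            "se_indirect": self.se_indirect,
            "total": self.total,
            "se_total": self.se_total,
            "proportion": self.proportion,
            "se_prop": self.se_prop,
            "prop_ci_low": self.ci95[0],
            "prop_ci_high": self.ci95[1],
        }


def indirect_effect(
    beta1: float, se1: float, beta2: float, se2: float
) -> tuple[float, float]:
    """Coefficient product β1·β2 with first-order delta-method SE.

    ``se = sqrt(beta2²·se1² + beta1²·se2²)`` — the covariance term is zero
    because β1 and β2 derive from independent samples.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("se1 and se2 must be positive")
    ind = beta1 * beta2
    se = float(np.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2))
    return float(ind), se


def proportion_mediated(
    indirect: float, se_indirect: float, total: float, se_total: float
) -> tuple[float, float, tuple[float, float]]:
    """Proportion mediated = indirect/total, with delta-method SE and CI.

    ``se_prop = |prop|·sqrt(se_ind²/ind² + se_tot²/tot²)`` for a ratio of
    independent estimates (``se_ind/|tot|`` at an exactly zero indirect
    effect). Proportions outside [0, 1] are reported with a warning,
    never truncated: inconsistent mediation is a finding, not an error.
    """
    if total == 0:
        raise UnitError("proportion mediated is undefined when total == 0")
    prop = indirect / total
    if indirect == 0:
        se = se_indirect / abs(total)
    else:
        se = abs(prop) * float(
            np.sqrt(se_indirect**2 / indirect**2 + se_total**2 / total**2)
        )
    if not 0 <= prop <= 1:
        warnings.warn(
            f"proportion mediated {prop:.3f} lies outside [0, 1] "
            "(inconsistent mediation); reported untruncated",
            stacklevel=2,
        )
    ci = (prop - Z95 * se, prop + Z95 * se)
    return float(prop), float(se), (float(ci[0]), float(ci[1]))


def _as_beta_se(x) -> tuple[float, float]:
    """Accept an MREstimate, an MVMR row (Series/dict), or a (beta, se) pair."""
    if isinstance(x, MREstimate):
        return x.beta, x.se
    if isinstance(x, pd.Series) or isinstance(x, dict):
        return float(x["beta"]), float(x["se"])
    b, s = x
    return float(b), float(s)


def mediation_table(
    total,
    mediators,
    scale: str = "log_odds",
) -> tuple[pd.DataFrame, list[MediationResult]]:
    """Assemble the per-mediator mediation decomposition.

    Parameters
    ----------
    total
        Total-effect estimate (MREstimate or (beta, se)), log-odds scale.
    mediators
        Iterable of ``(mediator_id, beta1_estimate, beta2_estimate)`` where
        each estimate is an MREstimate, an MVMR result row, or (beta, se).
    scale
        Must be ``"log_odds"`` (or ``"linear"`` for a continuous outcome);
        passing ``"or"`` raises :class:`UnitError` — convert odds ratios
        with ``log`` first, products of ORs are not meaningful.

    Returns the table sorted by descending proportion plus the underlying
    :class:`MediationResult` objects (same order). The summed proportion
    across mediators is attached as ``table.attrs['summed_proportion']``
    with a caveat flag: mediators may be correlated, so the sum is not a
    joint decomposition.
    """
    if scale not in ("log_odds", "linear"):
        raise UnitError(
            f"scale {scale!r}: mediation arithmetic requires log-odds (or "
            "linear) effects; convert odds ratios with log() first"
        )
    t_beta, t_se = _as_beta_se(total)
    results = []
    for mid, b1, b2 in mediators:
        beta1, se1 = _as_beta_se(b1)
        beta2, se2 = _as_beta_se(b2)
        ind, se_ind = indirect_effect(beta1, se1, beta2, se2)
        prop, se_prop, ci = proportion_mediated(ind, se_ind, t_beta, t_se)
        results.append(
            MediationResult(
                mediator_id=str(mid),
                beta1=beta1,
                se1=se1,
                beta2=beta2,
                se2=se2,
                indirect=ind,
                se_indirect=se_ind,
                total=t_beta,
                se_total=t_se,
                proportion=prop,
                se_prop=se_prop,
                ci95=ci,
            )
        )
    results.sort(key=lambda r: -r.proportion)
    table = pd.DataFrame([r.to_row() for r in results])
    table.attrs["summed_proportion"] = float(sum(r.proportion for r in results))
    table.attrs["summed_proportion_caveat"] = (
        "mediators may be correlated; the summed proportion is not a joint "
        "decomposition"
    )
    return table, results


def plot_proportions(table: pd.DataFrame, path) -> None:
    """Forest-plot-style figure of proportions mediated with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1.5))
    ypos = np.arange(len(table))[::-1]
    ax.errorbar(
        100 * table["proportion"],
        ypos,
        xerr=np.vstack(
            [
                100 * (table["proportion"] - table["prop_ci_low"]),
                100 * (table["prop_ci_high"] - table["proportion"]),
            ]
        ),
        fmt="o",
        color="black",
        ecolor="gray",
        capsize=3,
    )
    ax.axvline(0, color="lightgray", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["mediator"])
    ax.set_xlabel("proportion mediated (%)")
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
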