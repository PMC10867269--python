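"""Parameter-recovery helpers for simulation studies.

These run the two-step MR mediation machinery on in-memory simulated
summary statistics (using the generator's true instrument flags, i.e. no
re-selection step), so that repeated-replicate studies of estimator bias,
CI coverage and mediation-proportion recovery stay cheap.
"""

from __future__ import annotations

import numpy as np

from .mediation import mediation_table
from .mvmr import mvmr_ivw
from .simulate import SimOutput, SimScenario, simulate_summary_stats
from .uvmr import MREstimate, ivw


def total_effect_from_sim(
    sim: SimOutput, re_model: str = "multiplicative_random"
) -> MREstimate:
    """IVW total effect using the replicate's true exposure instruments."""
    sc = sim.truth
    panel = sim.to_panel(traits=[sc.exposure_id, sc.outcome_id],
                         snps=sim.instruments[sc.exposure_id])
    return ivw(panel, re_model=re_model, binary_outcome=True)


def mediation_from_sim(sim: SimOutput, re_model: str = "multiplicative_random"):
    """Full two-step decomposition of one simulated replicate.

    β1 per mediator by UVMR on the exposure instruments; β2 by
    per-mediator MVMR (exposure + that mediator, union instrument set);
    total by UVMR. Returns the mediation table and results as in
    :func:`mrmediation.mediation.mediation_table`.
    """
    sc = sim.truth
    panel = sim.to_panel()
    exp_instr = sim.instruments[sc.exposure_id]
    exp_panel = panel.subset(exp_instr)

    total = ivw(exp_panel, exposure=sc.exposure_id, outcome=sc.outcome_id,
                re_model=re_model, binary_outcome=True)
    rows = []
    for mid in sc.mediator_ids:
        b1 = ivw(exp_panel, exposure=sc.exposure_id, outcome=mid,
                 re_model=re_model)
        joint = panel.subset(exp_instr + sim.instruments[mid])
        mv = mvmr_ivw(joint, outcome=sc.outcome_id,
                      exposures=[sc.exposure_id, mid], binary_outcome=True)
        rows.append((mid, b1, mv.row(mid)))
    return mediation_table(total, rows, scale="log_odds")


def replicate_seeds(base_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate seeds below 2**31 derived from one seed."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_reps)]


def replicate_scenarios(scenario: SimScenario, base_seed: int,
                        n_reps: int) -> list[SimScenario]:
    """The same scenario re-seeded for each replicate."""
    import dataclasses

    return [
        dataclasses.replace(scenario, seed=s)
        for s in replicate_seeds(base_seed, n_reps)
    ]


def run_total_effect_study(scenario: SimScenario, n_reps: int,
                           base_seed: int) -> dict:
    """IVW recovery over replicates: per-replicate estimates, SEs, CI
    coverage of the true total effect, and the rejection rate of the
    nominal-5% test of no effect."""
    betas, ses, covered, rejected = [], [], [], []
    truth = scenario.theta_total
    for sc in replicate_scenarios(scenario, base_seed, n_reps):
        est = total_effect_from_sim(simulate_summary_stats(sc))
        betas.append(est.beta)
        ses.append(est.se)
        covered.append(est.ci95[0] <= truth <= est.ci95[1])
        rejected.append(est.pval < 0.05)
    betas = np.asarray(betas)
    return {
        "betas": betas,
        "ses": np.asarray(ses),
        "mean_beta": float(np.mean(betas)),
        "mc_se": float(np.std(betas, ddof=1) / np.sqrt(n_reps)),
        "coverage": float(np.mean(covered)),
        "rejection_rate": float(np.mean(rejected)),
    }


def run_mediation_study(scenario: SimScenario, n_reps: int,
                        base_seed: int) -> dict:
    """Two-step mediation recovery over replicates.

    Returns per-mediator proportion estimates (replicates × mediators,
    mediator order as in the scenario), their means and Monte-Carlo SEs.
    """
    props = np.empty((n_reps, scenario.n_mediators))
    for i, sc in enumerate(replicate_scenarios(scenario, base_seed, n_reps)):
        _, results = mediation_from_sim(simulate_summary_stats(sc))
        by_id = {r.mediator_id: r.proportion for r in results}
        props[i] = [by_id[m] for m in scenario.mediator_ids]
    return {
        "proportions": props,
        "mean": props.mean(axis=0),
        "mc_se": props.std(axis=0, ddof=1) / np.sqrt(n_reps),
        "mediator_ids": list(scenario.mediator_ids),
    }
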