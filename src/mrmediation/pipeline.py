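"""End-to-end orchestration of the MR mediation analysis.

From a single :class:`RunConfig` the pipeline runs: instrument selection →
harmonization → total effect (UVMR with sensitivity panel) → per-mediator
β1 (UVMR) → β2 (MVMR adjusting for the exposure) → mediation table →
reverse-direction reruns. Every stage logs SNP counts (read, p-filter,
clump, harmonization drops) so instrument bookkeeping is auditable, and
all outputs are written with fixed formatting so identical config + seed
yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .clump import ClumpSpec, LDReference, select_instruments
from .errors import ConfigError, EmptyPanelError
from .mediation import MediationResult, mediation_table, plot_proportions
from .mvmr import mvmr_ivw
from .sumstats import SummaryStatSet, harmonize, read_summary_stats
from .uvmr import (
    MREstimate,
    SensitivityReport,
    egger,
    ivw,
    outlier_report,
    sensitivity_report,
    weighted_median,
)

log = logging.getLogger("mrmediation")


@dataclass
class TraitFile:
    """One summary-statistics input: path plus read options."""

    file: str
    id: str | None = None
    dialect: str | dict = "loose"
    unit: str = ""
    binary: bool = False

    def read(self) -> SummaryStatSet:
        return read_summary_stats(
            self.file, dialect=self.dialect, trait_id=self.id, unit=self.unit
        )


@dataclass
class RunConfig:
    """Full configuration of one analysis run."""

    exposure: TraitFile
    outcome: TraitFile
    mediators: list[TraitFile] = field(default_factory=list)
    ld_positions: str | None = None
    ld_r2: str | None = None
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    re_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    outdir: str = "mrmediation_results"

    def __post_init__(self) -> None:
        ids = [self.exposure.id, self.outcome.id] + [m.id for m in self.mediators]
        known = [i for i in ids if i is not None]
        if len(set(known)) != len(known):
            raise ConfigError(f"duplicated trait ids in config: {known}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = os.path.dirname(os.path.abspath(str(path)))
        with open(str(path), "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)

        def tf(entry, binary_default=False) -> TraitFile:
            if isinstance(entry, str):
                entry = {"file": entry}
            entry = dict(entry)
            entry.setdefault("binary", binary_default)
            entry["file"] = os.path.join(base, entry["file"])
            return TraitFile(**entry)

        ld = d.get("ld", {}) or {}
        clump_d = d.get("clump", {}) or {}
        est = d.get("estimators", {}) or {}
        return cls(
            exposure=tf(d["exposure"]),
            outcome=tf(d["outcome"], binary_default=True),
            mediators=[tf(m) for m in d.get("mediators", [])],
            ld_positions=os.path.join(base, ld["positions"]) if "positions" in ld else None,
            ld_r2=os.path.join(base, ld["r2"]) if "r2" in ld else None,
            clump=ClumpSpec(**clump_d),
            re_model=est.get("re_model", "multiplicative_random"),
            n_boot=int(est.get("n_boot", 1000)),
            seed=int(est.get("seed", 0)),
            outdir=os.path.join(base, d.get("outdir", "mrmediation_results")),
        )


def _write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(str(path), sep="\t", index=False, float_format="%.10g")


def _load(cfg: RunConfig):
    exposure = cfg.exposure.read()
    outcome = cfg.outcome.read()
    mediators = [m.read() for m in cfg.mediators]
    ld = None
    if cfg.ld_positions is not None:
        ld = LDReference.from_files(cfg.ld_positions, cfg.ld_r2)
    counts = {s.trait_id: len(s) for s in [exposure, outcome, *mediators]}
    log.info("read summary statistics: %s", counts)
    return exposure, outcome, mediators, ld


def _instruments(stats: SummaryStatSet, ld: LDReference | None,
                 spec: ClumpSpec, counts: dict) -> list[str]:
    n_sig = int((stats.df["pval"] < spec.p_threshold).sum())
    counts[f"{stats.trait_id}_p_filter"] = n_sig
    if ld is None:
        sel = stats.df.loc[stats.df["pval"] < spec.p_threshold, "snp"].tolist()
    else:
        sel = select_instruments(stats, ld, spec)
    counts[f"{stats.trait_id}_clumped"] = len(sel)
    log.info(
        "%s: %d read, %d genome-wide significant, %d after clumping",
        stats.trait_id, len(stats), n_sig, len(sel),
    )
    return sel


def _uvmr_panel(exposure_set, outcome_set, instruments, counts):
    exp_sub = SummaryStatSet(
        trait_id=exposure_set.trait_id,
        df=exposure_set.df[exposure_set.df["snp"].isin(instruments)],
        unit=exposure_set.unit,
    )
    panel = harmonize([exp_sub, outcome_set])
    counts[f"{exposure_set.trait_id}_{outcome_set.trait_id}_harmonized"] = panel.n_snps
    counts[f"{exposure_set.trait_id}_{outcome_set.trait_id}_dropped"] = len(panel.dropped)
    return panel


def run_total_effect(cfg: RunConfig) -> tuple[MREstimate, SensitivityReport]:
    """Total exposure→outcome effect: IVW primary plus the full panel
    (weighted median, Egger, Q, Egger intercept, outlier flags)."""
    exposure, outcome, _, ld = _load(cfg)
    counts: dict = {}
    instruments = _instruments(exposure, ld, cfg.clump, counts)
    if not instruments:
        raise EmptyPanelError(
            f"no instruments for {exposure.trait_id!r} after p-filter/clumping"
        )
    panel = _uvmr_panel(exposure, outcome, instruments, counts)
    binary = cfg.outcome.binary

    est_ivw = ivw(panel, re_model=cfg.re_model, binary_outcome=binary)
    est_wm = weighted_median(
        panel, n_boot=cfg.n_boot, seed=cfg.seed, binary_outcome=binary
    )
    est_egger, _ = egger(panel, binary_outcome=binary)
    sens = sensitivity_report(panel)
    outliers = outlier_report(panel)

    os.makedirs(cfg.outdir, exist_ok=True)
    table = pd.DataFrame([e.to_row() for e in (est_ivw, est_wm, est_egger)])
    _write_table(table, os.path.join(cfg.outdir, "total_effect.tsv"))
    _write_table(
        outliers.reset_index(), os.path.join(cfg.outdir, "total_effect_outliers.tsv")
    )
    report = {
        "stage": "total_effect",
        "exposure": exposure.trait_id,
        "outcome": outcome.trait_id,
        "counts": counts,
        "sensitivity": dataclasses.asdict(sens),
        "n_outliers_flagged": int(outliers["flagged"].sum()),
    }
    with open(os.path.join(cfg.outdir, "total_effect_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return est_ivw, sens


def run_mediation(cfg: RunConfig) -> list[MediationResult]:
    """Two-step mediation: β1 by UVMR, β2 by per-mediator MVMR, table."""
    if not cfg.mediators:
        raise ConfigError("run_mediation requires at least one mediator")
    exposure, outcome, mediators, ld = _load(cfg)
    counts: dict = {}
    binary = cfg.outcome.binary

    exp_instr = _instruments(exposure, ld, cfg.clump, counts)
    if not exp_instr:
        raise EmptyPanelError("no exposure instruments after filtering")

    total_panel = _uvmr_panel(exposure, outcome, exp_instr, counts)
    total = ivw(total_panel, re_model=cfg.re_model, binary_outcome=binary)

    rows = []
    for med in mediators:
        b1_panel = _uvmr_panel(exposure, med, exp_instr, counts)
        b1 = ivw(b1_panel, re_model=cfg.re_model)

        med_instr = _instruments(med, ld, cfg.clump, counts)
        union = sorted(set(exp_instr) | set(med_instr))
        joint_sets = [
            SummaryStatSet(
                trait_id=s.trait_id,
                df=s.df[s.df["snp"].isin(union)],
                unit=s.unit,
            )
            for s in (exposure, med, outcome)
        ]
        joint = harmonize(joint_sets)
        counts[f"mvmr_{med.trait_id}_n_snps"] = joint.n_snps
        mv = mvmr_ivw(joint, outcome=outcome.trait_id, binary_outcome=binary)
        rows.append((med.trait_id, b1, mv.row(med.trait_id)))

    table, results = mediation_table(total, rows, scale="log_odds")
    os.makedirs(cfg.outdir, exist_ok=True)
    _write_table(table, os.path.join(cfg.outdir, "mediation.tsv"))
    plot_proportions(table, os.path.join(cfg.outdir, "mediation_forest.png"))
    report = {
        "stage": "mediation",
        "counts": counts,
        "summed_proportion": table.attrs["summed_proportion"],
        "caveat": table.attrs["summed_proportion_caveat"],
        "multiple_testing": "none applied across mediators",
    }
    with open(os.path.join(cfg.outdir, "mediation_report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return results


def run_reverse(cfg: RunConfig) -> dict[str, dict]:
    """Reverse-causation screens: each mediator as exposure, the original
    exposure as outcome. A mediator is flagged when |z| > 1.96 (flag only,
    no exclusion). Mediators lacking instruments are skipped with a
    warning entry in the report."""
    if not cfg.mediators:
        raise ConfigError("run_reverse requires at least one mediator")
    exposure, _, mediators, ld = _load(cfg)
    counts: dict = {}
    out: dict[str, dict] = {}
    for med in mediators:
        med_instr = _instruments(med, ld, cfg.clump, counts)
        if len(med_instr) < 2:
            log.warning("%s: no instruments for reverse test; skipped", med.trait_id)
            out[med.trait_id] = {"skipped": True, "reason": "no instruments"}
            continue
        panel = _uvmr_panel(med, exposure, med_instr, counts)
        est = ivw(panel, re_model=cfg.re_model)
        sens = sensitivity_report(panel) if panel.n_snps >= 3 else SensitivityReport()
        z = est.beta / est.se
        out[med.trait_id] = {
            "estimate": est.to_row(),
            "sensitivity": dataclasses.asdict(sens),
            "z": float(z),
            "flagged": bool(abs(z) > 1.96),
        }
    os.makedirs(cfg.outdir, exist_ok=True)
    rows = []
    for mid, r in out.items():
        if r.get("skipped"):
            rows.append({"mediator": mid, "skipped": True})
        else:
            rows.append(
                {"mediator": mid, "skipped": False, **r["estimate"],
                 "z": r["z"], "flagged": r["flagged"]}
            )
    _write_table(pd.DataFrame(rows), os.path.join(cfg.outdir, "reverse.tsv"))
    with open(os.path.join(cfg.outdir, "reverse_report.json"), "w") as fh:
        json.dump({"stage": "reverse", "counts": counts, "results": out},
                  fh, indent=2, sort_keys=True, default=float)
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run total effect, mediation and reverse screens; write a combined
    run report. The report footer notes that no multiple-testing
    correction is applied across mediators."""
    total, sens = run_total_effect(cfg)
    mediation = run_mediation(cfg) if cfg.mediators else []
    reverse = run_reverse(cfg) if cfg.mediators else {}
    summary = {
        "total_effect": total.to_row(),
        "sensitivity": dataclasses.asdict(sens),
        "mediation": [m.to_row() for m in mediation],
        "reverse": reverse,
        "footer": "no multiple-testing correction applied across mediators",
    }
    with open(os.path.join(cfg.outdir, "run_report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
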