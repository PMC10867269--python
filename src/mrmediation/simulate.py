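"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the statistical structure of consortium GWAS used
in MR mediation studies of a binary outcome: hundreds of independent
SD-scaled instruments at genome-wide significance, SD-scaled continuous
mediators, a log-odds-scale binary outcome, and per-SNP noise determined
by each study's sample size.

Causal diagram (all effects linear, per SD):

    instruments γ_j → exposure → mediator_k (β1_k) → outcome (β2_k)
                       exposure ————————————————————→ outcome (direct)

with total exposure→outcome effect ``theta_total`` and implied direct
effect ``theta_total − Σ_k β1_k·β2_k``. Each mediator additionally has its
own instruments δ_m (needed to identify β2 in multivariable MR).

Per-SNP standard errors follow the standard large-sample forms for an
SD-scaled trait, ``se = 1/sqrt(2·p·(1−p)·n)``, with the binary outcome's n
replaced by the effective case-control size ``n·cf·(1−cf)``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import norm

from .clump import LDReference
from .errors import ConfigError
from .sumstats import (
    HarmonizedPanel,
    SummaryStatSet,
    harmonize,
    write_summary_stats,
)

import pandas as pd

#: headline education→sepsis study conditions (SD-scaled exposure,
#: log-odds outcome): total OR 0.83 per SD (4.2 y) of schooling
EDUCATION_SEPSIS = {
    "n_exposure": 1_131_881,
    "n_outcome": 486_484,
    "case_fraction": 10_154 / (10_154 + 452_764),
    "theta_total": float(np.log(0.83)),
    "n_snps": 371,
}


@dataclass
class SimScenario:
    """Generative parameters for synthetic summary statistics.

    Defaults are the education→sepsis study conditions: 371 exposure
    instruments jointly explaining 10% of exposure variance, the published
    GWAS sample sizes, and a total effect of ln(0.83) log-odds per SD.
    """

    n_snps: int = 371
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_h2: float = 0.1
    theta_total: float = EDUCATION_SEPSIS["theta_total"]
    beta1_true: tuple[float, ...] = ()
    beta2_true: tuple[float, ...] = ()
    mediator_ids: tuple[str, ...] = ()
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_scale: float = 0.0
    n_exposure: int = EDUCATION_SEPSIS["n_exposure"]
    n_mediator: tuple[int, ...] = ()
    n_outcome: int = EDUCATION_SEPSIS["n_outcome"]
    case_fraction: float = EDUCATION_SEPSIS["case_fraction"]
    n_snps_mediator: tuple[int, ...] = ()
    mediator_h2: tuple[float, ...] = ()
    reverse_effects: tuple[float, ...] = ()
    ld_blocks: list[tuple[int, float]] | None = None
    exposure_id: str = "exposure"
    outcome_id: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.beta1_true)
        if len(self.beta2_true) != k:
            raise ConfigError("beta1_true and beta2_true lengths differ")
        if not self.mediator_ids:
            self.mediator_ids = tuple(f"M{i + 1}" for i in range(k))
        if len(self.mediator_ids) != k:
            raise ConfigError("mediator_ids length mismatch")
        if not self.n_mediator:
            self.n_mediator = tuple([100_000] * k)
        if len(self.n_mediator) != k:
            raise ConfigError("n_mediator length mismatch")
        if not self.n_snps_mediator:
            self.n_snps_mediator = tuple([150] * k)
        if len(self.n_snps_mediator) != k:
            raise ConfigError("n_snps_mediator length mismatch")
        if not self.mediator_h2:
            self.mediator_h2 = tuple([0.1] * k)
        if len(self.mediator_h2) != k:
            raise ConfigError("mediator_h2 length mismatch")
        if not self.reverse_effects:
            self.reverse_effects = tuple([0.0] * k)
        if len(self.reverse_effects) != k:
            raise ConfigError("reverse_effects length mismatch")
        if not (0 < self.instrument_h2 < 1):
            raise ConfigError("instrument_h2 must lie in (0, 1)")
        if any(not (0 < h < 1) for h in self.mediator_h2):
            raise ConfigError("mediator_h2 entries must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must lie in (0, 0.5]")
        if not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must lie in (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.ld_blocks is not None:
            if len(self.ld_blocks) > self.n_snps:
                raise ConfigError("more LD blocks than exposure instruments")
            for size, r2 in self.ld_blocks:
                if size < 1 or not (0 <= r2 <= 1):
                    raise ConfigError("ld_blocks entries must be (size>=1, r2 in [0,1])")

    @property
    def n_mediators(self) -> int:
        return len(self.beta1_true)

    @property
    def theta_direct(self) -> float:
        """Direct exposure→outcome effect implied by the causal diagram."""
        return self.theta_total - float(
            np.dot(self.beta1_true, self.beta2_true)
        )

    @property
    def trait_ids(self) -> list[str]:
        return [self.exposure_id, *self.mediator_ids, self.outcome_id]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        for key in (
            "beta1_true",
            "beta2_true",
            "mediator_ids",
            "n_mediator",
            "n_snps_mediator",
            "mediator_h2",
            "reverse_effects",
        ):
            d[key] = list(d[key])
        if self.ld_blocks is not None:
            d["ld_blocks"] = [[int(s), float(r)] for s, r in self.ld_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown scenario fields: {sorted(unknown)}")
        for key in (
            "maf_range",
            "beta1_true",
            "beta2_true",
            "mediator_ids",
            "n_mediator",
            "n_snps_mediator",
            "mediator_h2",
            "reverse_effects",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("ld_blocks") is not None:
            d["ld_blocks"] = [(int(s), float(r)) for s, r in d["ld_blocks"]]
        return cls(**d)


def sepsis_mediation_scenario(seed: int = 0, **overrides) -> SimScenario:
    """Four-mediator education→sepsis scenario at the published estimates.

    β1 (SD per SD of schooling): BMI −0.177, smoking −0.334, omega-3 0.096,
    ApoA-I 0.104; β2 (log-odds per SD): ln 1.51, ln 1.23, ln 0.93, ln 0.89;
    the total effect is calibrated so the BMI pathway mediates 38.8% of it
    (OR ≈ 0.83 per SD). Mediator GWAS sample sizes follow the source
    studies.
    """
    beta1 = (-0.177, -0.334, 0.096, 0.104)
    beta2 = tuple(float(np.log(x)) for x in (1.51, 1.23, 0.93, 0.89))
    params = dict(
        n_snps=371,
        instrument_h2=0.1,
        beta1_true=beta1,
        beta2_true=beta2,
        mediator_ids=("BMI", "smoking", "omega3", "apoa1"),
        n_mediator=(681_275, 249_752, 114_999, 115_078),
        theta_total=beta1[0] * beta2[0] / 0.388,
        exposure_id="education",
        outcome_id="sepsis",
        seed=seed,
    )
    params.update(overrides)
    return SimScenario(**params)


@dataclass
class SimOutput:
    """Simulated per-trait summary statistics plus the generating truth."""

    sets: dict[str, SummaryStatSet]
    truth: SimScenario
    instruments: dict[str, list[str]]  # trait -> its true (lead) instruments
    ld: LDReference
    trait_order: list[str] = field(default_factory=list)

    def to_panel(self, traits: list[str] | None = None,
                 snps: list[str] | None = None) -> HarmonizedPanel:
        """Harmonize the simulated sets into an analysis-ready panel."""
        traits = traits or self.trait_order
        panel = harmonize([self.sets[t] for t in traits])
        return panel if snps is None else panel.subset(snps)


def _draw_effects(rng, n: int, maf: np.ndarray, h2: float) -> np.ndarray:
    """Normal per-SNP effects rescaled so Σ 2p(1−p)γ² equals h2 exactly."""
    g = rng.standard_normal(n) * np.sqrt(h2 / n)
    var = np.sum(2.0 * maf * (1.0 - maf) * g**2)
    return g * np.sqrt(h2 / var)


def simulate_summary_stats(scenario: SimScenario) -> SimOutput:
    """Generate one replicate of two-sample GWAS summary statistics.

    Reproducible given ``scenario.seed``: a master seed spawns one child
    stream for the genetic architecture and one per trait for sampling
    noise, so adding a trait never perturbs the others' draws.
    """
    sc = scenario
    k = sc.n_mediators
    ss = np.random.SeedSequence(sc.seed)
    children = ss.spawn(2 + k + 2)  # structure, pleiotropy, one per trait
    rng_struct = np.random.default_rng(children[0])

    # --- SNP universe -----------------------------------------------------
    n_exp = sc.n_snps
    n_med = list(sc.n_snps_mediator)
    n_sat = 0
    blocks = sc.ld_blocks or []
    sat_of: list[int] = []  # satellite -> lead index (within exposure leads)
    sat_r: list[float] = []
    for bi, (size, r2) in enumerate(blocks):
        for _ in range(size - 1):
            sat_of.append(bi)
            sat_r.append(float(np.sqrt(r2)))
            n_sat += 1
    n_total = n_exp + n_sat + sum(n_med)

    snp_ids = [f"rs{i + 1:06d}" for i in range(n_total)]
    maf = rng_struct.uniform(sc.maf_range[0], sc.maf_range[1], n_total)

    # positions: leads/mediator instruments spaced 20 Mb apart (beyond any
    # clumping window); satellites within 10 kb of their lead
    positions: dict[str, tuple[int, int]] = {}
    r2_map: dict[frozenset, float] = {}
    main_idx = list(range(n_exp)) + list(range(n_exp + n_sat, n_total))
    for j, idx in enumerate(main_idx):
        chrom = (j % 22) + 1
        bp = 10_000_000 + (j // 22) * 20_000_000
        positions[snp_ids[idx]] = (chrom, bp)
    sat_counter: dict[int, int] = {}
    for s in range(n_sat):
        lead = sat_of[s]
        sat_counter[lead] = sat_counter.get(lead, 0) + 1
        c, b = positions[snp_ids[lead]]
        positions[snp_ids[n_exp + s]] = (c, b + 1000 * sat_counter[lead])
    # within-block pairwise r2 entries (lead + satellites, all pairs)
    for bi, (size, r2) in enumerate(blocks):
        members = [snp_ids[bi]] + [
            snp_ids[n_exp + s] for s in range(n_sat) if sat_of[s] == bi
        ]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                r2_map[frozenset((members[a], members[b]))] = r2

    # --- true per-trait effects ------------------------------------------
    gamma = _draw_effects(rng_struct, n_exp, maf[:n_exp], sc.instrument_h2)
    deltas = []
    off = n_exp + n_sat
    for m in range(k):
        deltas.append(
            _draw_effects(
                rng_struct, n_med[m], maf[off : off + n_med[m]], sc.mediator_h2[m]
            )
        )
        off += n_med[m]

    def pleio(rng, n):
        if sc.pleiotropy_mode == "none" or sc.pleiotropy_scale == 0:
            return np.zeros(n)
        if sc.pleiotropy_mode == "balanced":
            return rng.normal(0.0, sc.pleiotropy_scale, n)
        return rng.normal(sc.pleiotropy_scale, sc.pleiotropy_scale, n)

    rng_pleio = np.random.default_rng(children[1])
    # pleiotropy is defined per exposure-increasing allele (sign(gamma)),
    # so "directional" keeps one direction after Egger's orientation step
    orient = np.sign(gamma)
    alpha_out = pleio(rng_pleio, n_exp) * orient
    alpha_med = [pleio(rng_pleio, n_exp) * orient for _ in range(k)]

    true = {t: np.zeros(n_total) for t in sc.trait_ids}
    exp_id, out_id = sc.exposure_id, sc.outcome_id
    true[exp_id][:n_exp] = gamma
    # mediator-side pleiotropy flows on to the outcome through beta2
    true[out_id][:n_exp] = sc.theta_total * gamma + alpha_out + sum(
        sc.beta2_true[m] * alpha_med[m] for m in range(k)
    )
    for m, mid in enumerate(sc.mediator_ids):
        true[mid][:n_exp] = sc.beta1_true[m] * gamma + alpha_med[m]
    off = n_exp + n_sat
    for m, mid in enumerate(sc.mediator_ids):
        sl = slice(off, off + n_med[m])
        true[mid][sl] = deltas[m]
        rev = sc.reverse_effects[m]
        true[exp_id][sl] = rev * deltas[m]
        true[out_id][sl] = (sc.beta2_true[m] + rev * sc.theta_direct) * deltas[m]
        off += n_med[m]
    # satellites tag their lead with correlation r: marginal effect = r·lead
    for s in range(n_sat):
        for t in sc.trait_ids:
            true[t][n_exp + s] = sat_r[s] * true[t][sat_of[s]]

    # --- observed statistics ---------------------------------------------
    het = 2.0 * maf * (1.0 - maf)
    n_eff = {exp_id: float(sc.n_exposure), out_id: sc.n_outcome
             * sc.case_fraction * (1.0 - sc.case_fraction)}
    n_label = {exp_id: sc.n_exposure, out_id: sc.n_outcome}
    for m, mid in enumerate(sc.mediator_ids):
        n_eff[mid] = float(sc.n_mediator[m])
        n_label[mid] = sc.n_mediator[m]

    ea = np.where(rng_struct.random(n_total) < 0.5, "A", "G")
    oa = np.where(ea == "A", "G", "A")  # non-palindromic by construction

    sets: dict[str, SummaryStatSet] = {}
    for i, t in enumerate(sc.trait_ids):
        rng_t = np.random.default_rng(children[2 + i])
        se = 1.0 / np.sqrt(het * n_eff[t])
        beta = true[t] + rng_t.standard_normal(n_total) * se
        pval = np.clip(2.0 * norm.sf(np.abs(beta / se)), 5e-324, 1.0)
        df = pd.DataFrame(
            {
                "snp": snp_ids,
                "ea": ea,
                "oa": oa,
                "eaf": maf,
                "beta": beta,
                "se": se,
                "pval": pval,
                "n": n_label[t],
            }
        )
        unit = "log-odds" if t == out_id else "SD"
        sets[t] = SummaryStatSet(trait_id=t, df=df, unit=unit)

    instruments = {exp_id: snp_ids[:n_exp]}
    off = n_exp + n_sat
    for m, mid in enumerate(sc.mediator_ids):
        instruments[mid] = snp_ids[off : off + n_med[m]]
        off += n_med[m]

    return SimOutput(
        sets=sets,
        truth=sc,
        instruments=instruments,
        ld=LDReference(positions=positions, r2=r2_map),
        trait_order=sc.trait_ids,
    )


def write_fixture(sim: SimOutput, outdir) -> dict[str, str]:
    """Write one summary-stat file per trait plus LD and truth sidecars.

    Produces ``<trait>.tsv`` for each trait, ``positions.tsv`` and
    ``ld.tsv`` for the LD reference, and ``truth.yaml`` from which the
    original :class:`SimScenario` can be recovered field-by-field.
    Deterministic: the same SimOutput yields byte-identical files.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for t in sim.trait_order:
        p = os.path.join(outdir, f"{t}.tsv")
        write_summary_stats(sim.sets[t], p)
        paths[t] = p
    sim.ld.write(
        os.path.join(outdir, "positions.tsv"), os.path.join(outdir, "ld.tsv")
    )
    paths["positions"] = os.path.join(outdir, "positions.tsv")
    paths["ld"] = os.path.join(outdir, "ld.tsv")
    truth_path = os.path.join(outdir, "truth.yaml")
    with open(truth_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"scenario": sim.truth.to_dict(), "instruments": sim.instruments},
            fh,
            sort_keys=True,
        )
    paths["truth"] = truth_path
    return paths


def read_scenario(path) -> SimScenario:
    """Read a SimScenario from a YAML file (plain mapping of field names,
    or a fixture ``truth.yaml`` with a top-level ``scenario`` key)."""
    with open(str(path), "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if isinstance(d, dict) and "scenario" in d:
        d = d["scenario"]
    return SimScenario.from_dict(d)
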