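"""Instrument selection: p-value filtering plus greedy LD clumping.

Mirrors the standard GWAS "clumping" procedure: keep only genome-wide
significant SNPs (default p < 5e-8), then greedily accept the smallest-p
remaining SNP and discard everything correlated with it (r² at or above
the threshold, default 0.001) within a positional window (default
10,000 kb) on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, MissingLDError
from .sumstats import SummaryStatSet


@dataclass
class ClumpSpec:
    """Thresholds for instrument selection."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigError("p_threshold must lie in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ConfigError("r2_threshold must lie in [0, 1]")
        if not self.window_kb > 0:
            raise ConfigError("window_kb must be positive")


@dataclass
class LDReference:
    """SNP positions plus a sparse pairwise r² lookup.

    ``positions`` maps snp_id -> (chromosome, basepair); ``r2`` maps an
    unordered SNP pair to its squared correlation. Absent pairs default
    to r² = 0; r²(j, j) is implicitly 1.
    """

    positions: dict[str, tuple[int, int]]
    r2: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [p for p, v in self.r2.items() if not (0 <= v <= 1)]
        if bad:
            raise ConfigError(f"r2 values outside [0,1] for pairs {bad[:5]}")

    def get_r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.r2.get(frozenset((a, b)), 0.0)

    @classmethod
    def from_files(cls, positions_path, r2_path=None) -> "LDReference":
        """Load from delimited text: positions (snp, chrom, bp; 1-based)
        and optionally pairwise r² (snp_a, snp_b, r2)."""
        pos_df = pd.read_csv(positions_path, sep=None, engine="python")
        pos_df.columns = [c.lower() for c in pos_df.columns]
        positions = {
            str(r.snp): (int(r.chrom), int(r.bp))
            for r in pos_df.itertuples(index=False)
        }
        r2: dict[frozenset, float] = {}
        if r2_path is not None:
            ld_df = pd.read_csv(r2_path, sep=None, engine="python")
            ld_df.columns = [c.lower() for c in ld_df.columns]
            for r in ld_df.itertuples(index=False):
                r2[frozenset((str(r.snp_a), str(r.snp_b)))] = float(r.r2)
        return cls(positions=positions, r2=r2)

    def write(self, positions_path, r2_path) -> None:
        with open(str(positions_path), "w", encoding="utf-8") as fh:
            fh.write("snp\tchrom\tbp\n")
            for snp in sorted(self.positions):
                c, b = self.positions[snp]
                fh.write(f"{snp}\t{c}\t{b}\n")
        with open(str(r2_path), "w", encoding="utf-8") as fh:
            fh.write("snp_a\tsnp_b\tr2\n")
            for pair in sorted(self.r2, key=lambda p: sorted(p)):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{self.r2[pair]:.10g}\n")


def select_instruments(
    stats: SummaryStatSet,
    ld: LDReference,
    spec: ClumpSpec | None = None,
) -> list[str]:
    """Greedy LD clumping of genome-wide significant SNPs.

    Candidates are SNPs with p below ``spec.p_threshold``. Repeatedly the
    smallest-p remaining candidate is accepted (ties broken by snp id) and
    all unaccepted candidates on the same chromosome within
    ``spec.window_kb`` (inclusive) with r² >= ``spec.r2_threshold`` are
    discarded. Returns accepted SNP ids sorted by (chromosome, position).
    """
    if spec is None:
        spec = ClumpSpec()
    df = stats.df
    missing = [s for s in df["snp"] if s not in ld.positions]
    if missing:
        raise MissingLDError(
            f"SNPs missing from the LD reference: {missing[:10]}"
            + ("" if len(missing) <= 10 else f" (+{len(missing) - 10} more)")
        )
    cand = df[df["pval"] < spec.p_threshold][["snp", "pval"]].copy()
    if cand.empty:
        return []
    cand["chrom"] = [ld.positions[s][0] for s in cand["snp"]]
    cand["bp"] = [ld.positions[s][1] for s in cand["snp"]]
    cand = cand.sort_values(["pval", "snp"], kind="mergesort")

    window_bp = spec.window_kb * 1000.0
    alive = dict.fromkeys(cand["snp"], True)
    accepted: list[str] = []
    rows = list(cand.itertuples(index=False))
    by_chrom: dict[int, list] = {}
    for r in rows:
        by_chrom.setdefault(r.chrom, []).append(r)

    for r in rows:
        if not alive[r.snp]:
            continue
        accepted.append(r.snp)
        alive[r.snp] = False
        for other in by_chrom[r.chrom]:
            if not alive[other.snp]:
                continue
            if abs(other.bp - r.bp) <= window_bp and ld.get_r2(
                r.snp, other.snp
            ) >= spec.r2_threshold:
                alive[other.snp] = False

    return sorted(accepted, key=lambda s: ld.positions[s])
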