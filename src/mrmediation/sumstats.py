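"""GWAS summary-statistics I/O and cross-trait allele harmonization.

A :class:`SummaryStatSet` holds per-SNP association records for one trait
(SNP id, effect/other allele, effect-allele frequency, beta, SE, p, n).
Betas are per copy of the effect allele, in SD units for continuous traits
and log-odds for binary traits. :func:`harmonize` aligns several sets onto
the first set's effect alleles, producing a :class:`HarmonizedPanel` whose
beta matrix feeds every MR estimator in the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, FormatError, ValidationError

#: canonical on-disk column order
CANONICAL_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

#: internal (lowercase) frame columns, same order
_FIELDS = ["snp", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Built-in column dialects. "canonical" is this package's own writer format;
# "loose" matches common GWAS export headers case-insensitively. Each maps a
# semantic field to the set of accepted header names (lowercased).
DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "canonical": {
        "snp": ("snp",),
        "ea": ("ea",),
        "oa": ("oa",),
        "eaf": ("eaf",),
        "beta": ("beta",),
        "se": ("se",),
        "pval": ("p",),
        "n": ("n",),
    },
    "loose": {
        "snp": ("snp", "rsid", "markername", "snpid", "variant_id"),
        "ea": ("ea", "effect_allele", "a1", "allele1", "alt"),
        "oa": ("oa", "other_allele", "a2", "allele2", "ref", "non_effect_allele"),
        "eaf": ("eaf", "freq", "af", "effect_allele_frequency", "frq", "maf"),
        "beta": ("beta", "b", "effect", "effect_size", "beta_hat"),
        "se": ("se", "stderr", "standard_error", "sebeta"),
        "pval": ("p", "pval", "p_value", "pvalue", "p_val"),
        "n": ("n", "samplesize", "sample_size", "n_total", "neff"),
    },
}

#: fixed enumeration of harmonization drop reasons
DROP_REASONS = ("missing_in_trait", "palindromic_ambiguous", "allele_mismatch")


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G pairs cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT[ea] == oa


@dataclass
class SummaryStatSet:
    """Validated per-SNP association records for one trait.

    Parameters
    ----------
    trait_id
        Label for the trait (e.g. ``"education"``).
    df
        Frame with columns ``snp, ea, oa, eaf, beta, se, pval, n``.
        ``eaf`` may be NaN (unknown); everything else must validate.
    unit
        Free-text unit of ``beta`` (e.g. ``"SD (4.2 y)"`` or ``"log-odds"``).
    """

    trait_id: str
    df: pd.DataFrame
    unit: str = ""

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        missing = [c for c in _FIELDS if c not in df.columns]
        if missing:
            raise FormatError(
                f"trait {self.trait_id!r}: missing fields {missing}"
            )
        df = df[_FIELDS]
        df["ea"] = df["ea"].astype(str).str.upper()
        df["oa"] = df["oa"].astype(str).str.upper()
        for col in ("eaf", "beta", "se", "pval"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["n"] = pd.to_numeric(df["n"], errors="coerce")
        self.df = df
        self._validate()

    def _validate(self) -> None:
        df = self.df
        problems: list[str] = []

        def bad(mask: pd.Series, why: str) -> None:
            for i in df.index[mask.fillna(False)]:
                problems.append(f"row {i + 1} (snp={df.at[i, 'snp']!r}): {why}")

        bad(~df["ea"].isin(_VALID_ALLELES), "effect allele not in A/C/G/T")
        bad(~df["oa"].isin(_VALID_ALLELES), "other allele not in A/C/G/T")
        bad(df["ea"] == df["oa"], "effect allele equals other allele")
        bad(~(df["se"] > 0) | df["se"].isna(), "se must be > 0")
        bad(df["beta"].isna(), "beta is not numeric")
        bad(
            ~((df["pval"] > 0) & (df["pval"] <= 1)) | df["pval"].isna(),
            "p-value must lie in (0, 1]",
        )
        eaf_bad = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
        bad(eaf_bad, "eaf must lie in (0, 1) when present")
        bad(~(df["n"] > 0) | df["n"].isna(), "n must be a positive count")
        dup = df["snp"].duplicated(keep=False)
        bad(dup, "duplicated snp id")
        if problems:
            head = "; ".join(problems[:20])
            more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
            raise ValidationError(
                f"trait {self.trait_id!r}: {len(problems)} invalid rows: {head}{more}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp"].tolist()


def _resolve_columns(header: list[str], dialect) -> dict[str, str]:
    """Map semantic field -> actual header name for this file."""
    if isinstance(dialect, str):
        try:
            mapping = DIALECTS[dialect]
        except KeyError:
            raise FormatError(f"unknown dialect {dialect!r}") from None
    else:
        # explicit user mapping: semantic field -> header name
        mapping = {k: (v,) for k, v in dialect.items()}
    lower = {h.lower(): h for h in header}
    out: dict[str, str] = {}
    missing = []
    for fieldname, names in mapping.items():
        for name in names:
            if name.lower() in lower:
                out[fieldname] = lower[name.lower()]
                break
        else:
            missing.append(fieldname)
    if missing:
        raise FormatError(
            f"header {header} lacks required columns for fields {missing}; "
            "supply an explicit column mapping"
        )
    return out


def read_summary_stats(
    path,
    dialect="loose",
    trait_id: str | None = None,
    unit: str = "",
) -> SummaryStatSet:
    """Read a delimited summary-statistics file into a validated set.

    ``dialect`` is either the name of a built-in column mapping
    (``"canonical"`` or ``"loose"``) or an explicit dict mapping the
    semantic fields ``snp, ea, oa, eaf, beta, se, pval, n`` to header names.
    The delimiter (tab or comma) is sniffed from the header line.
    """
    path = str(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        sep = "\t" if first.count("\t") >= first.count(",") else ","
        df = pd.read_csv(io.StringIO(first + fh.read()), sep=sep, dtype={0: str})
    colmap = _resolve_columns(list(df.columns), dialect)
    frame = pd.DataFrame({f: df[colmap[f]] for f in _FIELDS})
    frame["snp"] = frame["snp"].astype(str)
    if trait_id is None:
        import os

        trait_id = os.path.splitext(os.path.basename(path))[0]
    return SummaryStatSet(trait_id=trait_id, df=frame, unit=unit)


def write_summary_stats(sset: SummaryStatSet, path, sep: str = "\t") -> None:
    """Write in canonical column order with fixed formatting (diffable).

    Floats are rendered with ``%.10g`` (betas/SEs) and ``%.6g`` (eaf, p),
    which round-trips through :func:`read_summary_stats` bit-exactly at the
    printed precision.
    """
    df = sset.df
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write(sep.join(CANONICAL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            eaf = "NA" if pd.isna(row.eaf) else f"{row.eaf:.6g}"
            fh.write(
                sep.join(
                    [
                        row.snp,
                        row.ea,
                        row.oa,
                        eaf,
                        f"{row.beta:.10g}",
                        f"{row.se:.10g}",
                        f"{row.pval:.6g}",
                        f"{int(row.n)}",
                    ]
                )
                + "\n"
            )


@dataclass
class HarmonizedPanel:
    """SNP-aligned effect matrices across traits, one effect allele per SNP.

    ``beta_matrix`` and ``se_matrix`` are frames indexed by SNP id with one
    column per trait (exposure first, outcome conventionally last).
    ``dropped`` records every input SNP excluded during harmonization with a
    reason from :data:`DROP_REASONS`.
    """

    snp_ids: list[str]
    traits: list[str]
    beta_matrix: pd.DataFrame
    se_matrix: pd.DataFrame
    eaf_matrix: pd.DataFrame | None = None
    alleles: pd.DataFrame | None = None  # columns ea, oa (reference orientation)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    units: dict[str, str] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, snps) -> "HarmonizedPanel":
        """Panel restricted to ``snps`` (order preserved from the panel)."""
        keep = [s for s in self.snp_ids if s in set(snps)]
        return HarmonizedPanel(
            snp_ids=keep,
            traits=list(self.traits),
            beta_matrix=self.beta_matrix.loc[keep],
            se_matrix=self.se_matrix.loc[keep],
            eaf_matrix=None if self.eaf_matrix is None else self.eaf_matrix.loc[keep],
            alleles=None if self.alleles is None else self.alleles.loc[keep],
            dropped=list(self.dropped),
            units=dict(self.units),
        )

    def to_sets(self) -> list[SummaryStatSet]:
        """Re-materialize one SummaryStatSet per trait (reference alleles)."""
        out = []
        for t in self.traits:
            df = pd.DataFrame(
                {
                    "snp": self.snp_ids,
                    "ea": self.alleles["ea"].values,
                    "oa": self.alleles["oa"].values,
                    "eaf": self.eaf_matrix[t].values
                    if self.eaf_matrix is not None
                    else np.nan,
                    "beta": self.beta_matrix[t].values,
                    "se": self.se_matrix[t].values,
                    "pval": 1.0,
                    "n": 1,
                }
            )
            # recompute two-sided p from the z statistic for completeness
            from scipy.stats import norm

            z = np.abs(df["beta"] / df["se"])
            df["pval"] = np.clip(2.0 * norm.sf(z), 5e-324, 1.0)
            out.append(SummaryStatSet(trait_id=t, df=df, unit=self.units.get(t, "")))
        return out


def _orient(ref_ea, ref_oa, ea, oa):
    """Classify allele orientation of (ea, oa) against the reference pair.

    Returns +1 (same orientation), -1 (swapped: flip beta, complement eaf)
    or 0 (mismatch). Strand flips are resolved by complementing first.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return 1
    if (cea, coa) == (ref_oa, ref_ea):
        return -1
    return 0


def harmonize(
    sets: list[SummaryStatSet],
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedPanel:
    """Align ≥2 summary-stat sets onto the first set's effect alleles.

    For each SNP shared by every set, non-reference betas whose effect
    allele is the reference's *other* allele are sign-flipped (and eaf
    complemented); strand flips are resolved by allele complementing.
    Palindromic SNPs (A/T, C/G) are dropped as ambiguous when the reference
    eaf is within ``palindromic_eaf_window`` of 0.5 (or missing); otherwise
    they are oriented so every trait's eaf falls on the same side of 0.5 as
    the reference's.
    """
    if len(sets) < 2:
        raise ValueError("harmonize needs at least two summary-stat sets")
    ids = [s.trait_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicated trait ids: {ids}")

    ref = sets[0]
    frames = {s.trait_id: s.df.set_index("snp") for s in sets}
    ref_df = frames[ref.trait_id]

    universe: list[str] = []
    seen: set[str] = set()
    for s in sets:
        for snp in s.df["snp"]:
            if snp not in seen:
                universe.append(snp)
                seen.add(snp)

    shared_mask = pd.Series(True, index=pd.Index(universe, name="snp"))
    for t in ids:
        shared_mask &= shared_mask.index.isin(frames[t].index)
    shared = shared_mask.index[shared_mask.values]

    dropped: list[tuple[str, str]] = [
        (snp, "missing_in_trait") for snp in universe if snp not in set(shared)
    ]
    if len(shared) == 0:
        raise EmptyPanelError("no SNPs are shared across all traits")

    aligned = {t: frames[t].reindex(shared) for t in ids}
    r = aligned[ref.trait_id]
    ref_ea = r["ea"].to_numpy()
    ref_oa = r["oa"].to_numpy()
    ref_eaf = r["eaf"].to_numpy(dtype=float)
    comp = lambda a: np.vectorize(_COMPLEMENT.get)(a)  # noqa: E731
    palindromic = comp(ref_ea) == ref_oa

    w = palindromic_eaf_window
    # reason codes per shared SNP: "" keep, else drop reason
    reason = np.full(len(shared), "", dtype=object)
    amb = palindromic & (np.isnan(ref_eaf) | (np.abs(ref_eaf - 0.5) <= w))
    reason[amb] = "palindromic_ambiguous"

    beta = np.empty((len(shared), len(ids)))
    se = np.empty_like(beta)
    eaf = np.empty_like(beta)

    for k, t in enumerate(ids):
        a = aligned[t]
        ea = a["ea"].to_numpy()
        oa = a["oa"].to_numpy()
        cea, coa = comp(ea), comp(oa)
        same = ((ea == ref_ea) & (oa == ref_oa)) | ((cea == ref_ea) & (coa == ref_oa))
        swap = ((ea == ref_oa) & (oa == ref_ea)) | ((cea == ref_oa) & (coa == ref_ea))
        sign = np.where(same, 1.0, np.where(swap, -1.0, 0.0))
        mism = (sign == 0.0) & (reason == "")
        reason[mism] = "allele_mismatch"

        b = sign * a["beta"].to_numpy(dtype=float)
        f = np.where(sign >= 0, a["eaf"].to_numpy(dtype=float),
                     1.0 - a["eaf"].to_numpy(dtype=float))
        if t != ref.trait_id:
            # palindromic SNPs: allele labels cannot fix the strand; orient
            # by frequency relative to the reference's side of 0.5
            pal = palindromic & (reason == "")
            no_f = pal & np.isnan(f)
            reason[no_f] = "palindromic_ambiguous"
            flip = pal & ((f - 0.5) * (ref_eaf - 0.5) < 0)
            b = np.where(flip, -b, b)
            f = np.where(flip, 1.0 - f, f)
        beta[:, k] = b
        se[:, k] = a["se"].to_numpy(dtype=float)
        eaf[:, k] = f

    keep = reason == ""
    dropped.extend(
        (snp, why) for snp, why in zip(shared[~keep], reason[~keep])
    )
    kept = list(shared[keep])
    if not kept:
        raise EmptyPanelError(
            "no SNPs shared across all traits survived harmonization"
        )

    idx = pd.Index(kept, name="snp")
    return HarmonizedPanel(
        snp_ids=kept,
        traits=ids,
        beta_matrix=pd.DataFrame(beta[keep], index=idx, columns=ids),
        se_matrix=pd.DataFrame(se[keep], index=idx, columns=ids),
        eaf_matrix=pd.DataFrame(eaf[keep], index=idx, columns=ids),
        alleles=pd.DataFrame({"ea": ref_ea[keep], "oa": ref_oa[keep]}, index=idx),
        dropped=dropped,
        units={s.trait_id: s.unit for s in sets},
    )
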