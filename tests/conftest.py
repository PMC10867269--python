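import numpy as np
import pandas as pd
import pytest

from mrmediation.sumstats import HarmonizedPanel, SummaryStatSet


def make_panel(bx, sx, by, sy, traits=("X", "Y"), snps=None) -> HarmonizedPanel:
    """Build a two-trait harmonized panel directly from effect arrays."""
    bx, sx, by, sy = map(np.asarray, (bx, sx, by, sy))
    n = len(bx)
    if snps is None:
        snps = [f"rs{i + 1}" for i in range(n)]
    idx = pd.Index(snps, name="snp")
    tx, ty = traits
    return HarmonizedPanel(
        snp_ids=list(snps),
        traits=[tx, ty],
        beta_matrix=pd.DataFrame({tx: bx, ty: by}, index=idx),
        se_matrix=pd.DataFrame({tx: sx, ty: sy}, index=idx),
        alleles=pd.DataFrame({"ea": ["A"] * n, "oa": ["G"] * n}, index=idx),
        eaf_matrix=pd.DataFrame({tx: 0.3, ty: 0.3}, index=idx),
    )


def make_multipanel(columns: dict, se: dict) -> HarmonizedPanel:
    """Panel with arbitrary trait columns ({trait: betas}, {trait: ses})."""
    traits = list(columns)
    n = len(next(iter(columns.values())))
    idx = pd.Index([f"rs{i + 1}" for i in range(n)], name="snp")
    return HarmonizedPanel(
        snp_ids=list(idx),
        traits=traits,
        beta_matrix=pd.DataFrame(columns, index=idx)[traits],
        se_matrix=pd.DataFrame(se, index=idx)[traits],
        alleles=pd.DataFrame({"ea": ["A"] * n, "oa": ["G"] * n}, index=idx),
    )


def make_set(records, trait_id="trait", unit="SD") -> SummaryStatSet:
    """SummaryStatSet from (snp, ea, oa, eaf, beta, se, pval, n) tuples."""
    df = pd.DataFrame(
        records, columns=["snp", "ea", "oa", "eaf", "beta", "se", "pval", "n"]
    )
    return SummaryStatSet(trait_id=trait_id, df=df, unit=unit)


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)
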