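"""Summary-statistics I/O and allele-harmonization behaviour."""

import numpy as np
import pandas as pd
import pytest

from mrmediation.errors import EmptyPanelError, FormatError, ValidationError
from mrmediation.sumstats import (
    harmonize,
    read_summary_stats,
    write_summary_stats,
)

from conftest import make_set

WELL_FORMED = (
    "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
    "rs1\tA\tG\t0.3\t0.05\t0.01\t5e-7\t10000\n"
    "rs2\tC\tT\t0.12\t-0.02\t0.015\t0.18\t10000\n"
    "rs3\tG\tA\t0.45\t0.11\t0.02\t3.9e-8\t9000\n"
)


def test_read_well_formed_tsv(tmp_path):
    p = tmp_path / "stats.tsv"
    p.write_text(WELL_FORMED)
    s = read_summary_stats(p, dialect="canonical", trait_id="t")
    assert len(s) == 3
    assert s.snp_ids == ["rs1", "rs2", "rs3"]
    assert s.df.loc[1, "beta"] == -0.02


def test_read_loose_dialect_and_comma(tmp_path):
    p = tmp_path / "stats.csv"
    p.write_text(
        "rsid,effect_allele,other_allele,freq,b,stderr,pvalue,samplesize\n"
        "rs1,A,G,0.3,0.05,0.01,5e-7,10000\n"
    )
    s = read_summary_stats(p, dialect="loose")
    assert len(s) == 1 and s.df.loc[0, "ea"] == "A"


def test_explicit_mapping_required_for_unknown_headers(tmp_path):
    p = tmp_path / "weird.tsv"
    p.write_text("marker\tx1\tx2\tfrq\tslope\terr\tsig\tcount\nrs1\tA\tG\t0.3\t0.1\t0.01\t1e-9\t500\n")
    with pytest.raises(FormatError, match="lacks required columns"):
        read_summary_stats(p, dialect="loose")
    mapping = dict(snp="marker", ea="x1", oa="x2", eaf="frq",
                   beta="slope", se="err", pval="sig", n="count")
    s = read_summary_stats(p, dialect=mapping)
    assert s.df.loc[0, "beta"] == 0.1


@pytest.mark.parametrize(
    "row,match",
    [
        ("rs9\tA\tG\t0.3\t0.05\t0\t0.5\t100\n", "se must be > 0"),
        ("rs9\tA\tN\t0.3\t0.05\t0.01\t0.5\t100\n", "not in A/C/G/T"),
        ("rs9\tA\tA\t0.3\t0.05\t0.01\t0.5\t100\n", "equals other allele"),
        ("rs9\tA\tG\t0.3\t0.05\t0.01\t0\t100\n", r"p-value must lie"),
        ("rs9\tA\tG\t1.3\t0.05\t0.01\t0.5\t100\n", "eaf must lie"),
    ],
)
def test_validation_errors_name_offending_rows(tmp_path, row, match):
    p = tmp_path / "bad.tsv"
    p.write_text("SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n" + row)
    with pytest.raises(ValidationError, match=match) as exc:
        read_summary_stats(p, dialect="canonical")
    assert "rs9" in str(exc.value)


def test_duplicate_snp_id_rejected(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text(
        "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
        "rs1\tA\tG\t0.3\t0.05\t0.01\t0.5\t100\n"
        "rs1\tA\tG\t0.3\t0.06\t0.01\t0.5\t100\n"
    )
    with pytest.raises(ValidationError, match="duplicated snp id"):
        read_summary_stats(p, dialect="canonical")


def test_write_read_write_round_trip_bytes(tmp_path):
    src = tmp_path / "src.tsv"
    src.write_text(WELL_FORMED)
    s = read_summary_stats(src, dialect="canonical", trait_id="t")
    out1 = tmp_path / "out1.tsv"
    write_summary_stats(s, out1)
    s2 = read_summary_stats(out1, dialect="canonical", trait_id="t")
    out2 = tmp_path / "out2.tsv"
    write_summary_stats(s2, out2)
    assert out1.read_bytes() == out2.read_bytes()
    pd.testing.assert_frame_equal(s.df, s2.df)


# --- harmonization ---------------------------------------------------------


def _pair(ea2, oa2, beta2=0.2, eaf2=0.3):
    ref = make_set([("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)], "ref")
    other = make_set([("rs1", ea2, oa2, eaf2, beta2, 0.02, 1e-5, 2000)], "oth")
    return ref, other


def test_identical_orientation_unchanged():
    panel = harmonize(list(_pair("A", "G")))
    assert panel.beta_matrix.loc["rs1", "oth"] == 0.2
    assert panel.eaf_matrix.loc["rs1", "oth"] == 0.3


def test_swapped_alleles_flip_beta_and_eaf():
    panel = harmonize(list(_pair("G", "A", beta2=0.2, eaf2=0.3)))
    assert panel.beta_matrix.loc["rs1", "oth"] == -0.2
    assert panel.eaf_matrix.loc["rs1", "oth"] == pytest.approx(0.7)


def test_strand_flip_resolved_by_complementing():
    # T/C is the reverse-strand reading of A/G: same orientation
    panel = harmonize(list(_pair("T", "C")))
    assert panel.beta_matrix.loc["rs1", "oth"] == 0.2
    # C/T is reverse strand of the swapped pair: flip
    panel = harmonize(list(_pair("C", "T")))
    assert panel.beta_matrix.loc["rs1", "oth"] == -0.2


def test_allele_mismatch_dropped():
    ref = make_set(
        [
            ("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
            ("rs2", "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
        ],
        "ref",
    )
    oth = make_set(
        [
            ("rs1", "A", "C", 0.3, 0.2, 0.02, 1e-5, 2000),
            ("rs2", "A", "G", 0.3, 0.2, 0.02, 1e-5, 2000),
        ],
        "oth",
    )
    panel = harmonize([ref, oth])
    assert ("rs1", "allele_mismatch") in panel.dropped
    assert panel.snp_ids == ["rs2"]


def test_palindromic_ambiguous_dropped_on_ten_snp_fixture():
    """10 SNPs incl. 2 near-0.5 palindromes -> both dropped, rest kept."""
    rows_ref, rows_oth = [], []
    # 8 unambiguous SNPs
    for i in range(8):
        rows_ref.append((f"rs{i}", "A", "G", 0.2 + 0.02 * i, 0.1, 0.01, 1e-9, 1000))
        rows_oth.append((f"rs{i}", "A", "G", 0.2 + 0.02 * i, 0.2, 0.02, 1e-5, 2000))
    # palindromic, ref eaf 0.50 and 0.47 (inside the +/-0.08 window)
    rows_ref += [
        ("rsP1", "A", "T", 0.50, 0.1, 0.01, 1e-9, 1000),
        ("rsP2", "C", "G", 0.47, 0.1, 0.01, 1e-9, 1000),
    ]
    rows_oth += [
        ("rsP1", "A", "T", 0.50, 0.2, 0.02, 1e-5, 2000),
        ("rsP2", "C", "G", 0.47, 0.2, 0.02, 1e-5, 2000),
    ]
    panel = harmonize([make_set(rows_ref, "ref"), make_set(rows_oth, "oth")])
    assert panel.n_snps == 8
    dropped = dict(panel.dropped)
    assert dropped == {"rsP1": "palindromic_ambiguous",
                       "rsP2": "palindromic_ambiguous"}


def test_palindrome_outside_window_oriented_by_frequency():
    ref = make_set([("rs1", "A", "T", 0.2, 0.1, 0.01, 1e-9, 1000)], "ref")
    # other set's eaf on the opposite side of 0.5: must be flipped
    oth = make_set([("rs1", "A", "T", 0.75, 0.2, 0.02, 1e-5, 2000)], "oth")
    panel = harmonize([ref, oth])
    assert panel.beta_matrix.loc["rs1", "oth"] == -0.2
    assert panel.eaf_matrix.loc["rs1", "oth"] == pytest.approx(0.25)


def test_palindrome_missing_eaf_always_dropped():
    ref = make_set([("rs1", "A", "T", 0.2, 0.1, 0.01, 1e-9, 1000)], "ref")
    oth = make_set([("rs1", "A", "T", np.nan, 0.2, 0.02, 1e-5, 2000)], "oth")
    with pytest.raises(EmptyPanelError):
        harmonize([ref, oth])  # the only SNP is dropped -> empty panel


def test_no_shared_snps_raises():
    ref = make_set([("rs1", "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)], "ref")
    oth = make_set([("rs2", "A", "G", 0.3, 0.2, 0.02, 1e-5, 2000)], "oth")
    with pytest.raises(EmptyPanelError):
        harmonize([ref, oth])


def test_every_input_snp_in_panel_or_dropped(rng):
    """Partition property on a randomized three-set input."""
    from mrmediation.simulate import SimScenario, simulate_summary_stats

    sim = simulate_summary_stats(
        SimScenario(n_snps=30, beta1_true=(0.2,), beta2_true=(0.1,),
                    n_mediator=(50_000,), seed=5)
    )
    sets = [sim.sets[t] for t in sim.trait_order]
    # knock some SNPs out of one set to force missing_in_trait drops
    sets[1].df = sets[1].df.iloc[5:].reset_index(drop=True)
    panel = harmonize(sets)
    universe = set().union(*(s.df["snp"] for s in sets))
    accounted = set(panel.snp_ids) | {s for s, _ in panel.dropped}
    assert accounted == universe
    assert len(panel.snp_ids) + len(panel.dropped) == len(universe)


def test_flip_and_negate_leaves_betas_unchanged(rng):
    """Allele-relabelling invariance of the harmonized beta matrix."""
    from mrmediation.simulate import SimScenario, simulate_summary_stats

    sim = simulate_summary_stats(SimScenario(n_snps=25, seed=11))
    a, b = sim.sets["exposure"], sim.sets["outcome"]
    panel1 = harmonize([a, b])
    flipped = b.df.copy()
    flipped[["ea", "oa"]] = flipped[["oa", "ea"]].to_numpy()
    flipped["beta"] = -flipped["beta"]
    flipped["eaf"] = 1.0 - flipped["eaf"]
    b2 = type(b)(trait_id=b.trait_id, df=flipped, unit=b.unit)
    panel2 = harmonize([a, b2])
    pd.testing.assert_frame_equal(panel1.beta_matrix, panel2.beta_matrix)


def test_harmonize_is_idempotent(rng):
    from mrmediation.simulate import SimScenario, simulate_summary_stats

    sim = simulate_summary_stats(
        SimScenario(n_snps=20, beta1_true=(0.3,), beta2_true=(0.2,),
                    n_mediator=(80_000,), seed=3)
    )
    panel = harmonize([sim.sets[t] for t in sim.trait_order])
    again = harmonize(panel.to_sets())
    pd.testing.assert_frame_equal(panel.beta_matrix, again.beta_matrix)
    pd.testing.assert_frame_equal(panel.se_matrix, again.se_matrix)
    assert again.dropped == []
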