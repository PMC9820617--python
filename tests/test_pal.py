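"""Case-to-normal ratios and pathway activation level scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioma_cns5.cohort import ExpressionMatrix
from glioma_cns5.pal import (
    CnrMatrix,
    PathwayDefinition,
    batch_pal,
    compute_cnr,
    compute_pal,
    read_pathways,
    write_pathways,
)


def expr(data):
    return ExpressionMatrix(pd.DataFrame(data))


def cnr_from(data):
    df = pd.DataFrame(data, dtype=float)
    return CnrMatrix(df, df.mean(axis=1))


def pal_oracle(members, cnrs):
    """Direct evaluation of the PAL definition, term by term."""
    num = sum(arr * np.log10(cnrs[g]) * 100.0 for g, arr in members.items() if g in cnrs)
    den = sum(abs(arr) for g, arr in members.items() if g in cnrs)
    return num / den


class TestComputeCnr:
    def test_sample_equal_to_cohort_mean_gives_unit_cnr(self):
        e = expr({"s1": [1.0, 4.0], "s2": [3.0, 2.0], "s3": [2.0, 3.0]})
        cnr = compute_cnr(e, pseudocount=0.0)
        assert np.allclose(cnr.values["s3"], 1.0)

    def test_two_sample_hand_computation(self):
        e = expr({"s1": [1.0], "s2": [3.0]})
        cnr = compute_cnr(e, pseudocount=0.0)
        assert np.allclose(cnr.values.loc[0], [0.5, 1.5])

    def test_all_zero_gene_with_pseudocount_one(self):
        e = expr({"s1": [0.0], "s2": [0.0]})
        cnr = compute_cnr(e, pseudocount=1.0)
        assert np.allclose(cnr.values.to_numpy(), 1.0)

    def test_zero_without_pseudocount_instructs_pseudocount(self):
        e = expr({"s1": [0.0], "s2": [2.0]})
        with pytest.raises(ValueError, match="pseudocount"):
            compute_cnr(e, pseudocount=0.0)

    def test_explicit_reference_must_cover_genes(self):
        e = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["G1"]))
        with pytest.raises(ValueError, match="missing genes"):
            compute_cnr(e, reference=pd.Series({"G2": 1.0}))


@pytest.mark.parametrize(
    "members, cnrs, expected",
    [
        # log10(1) = 0 everywhere
        ({"A": 1.0, "B": -0.5}, {"A": 1.0, "B": 1.0}, 0.0),
        # a single unit-weight activator at a tenfold ratio scores 100
        ({"A": 1.0}, {"A": 10.0}, 100.0),
        # balanced activator/repressor at equal ratios cancel (|ARR| denominator 2)
        ({"A": 1.0, "B": -1.0}, {"A": 10.0, "B": 10.0}, 0.0),
        # mixed weights: (0.5*2*100 + 1*0*100) / 1.5
        ({"A": 0.5, "B": 1.0}, {"A": 100.0, "B": 1.0}, pytest.approx(200 / 3)),
    ],
)
def test_pal_closed_forms(members, cnrs, expected):
    genes = list(members)
    df = pd.DataFrame({"s": [cnrs[g] for g in genes]}, index=genes, dtype=float)
    cnr = CnrMatrix(df, df["s"])
    p = PathwayDefinition("toy", members)
    assert compute_pal(p, cnr, "s").value == expected


def test_pal_zero_at_reference_profile():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.lognormal(2, 1, size=(20, 5)),
                        index=[f"G{i}" for i in range(20)],
                        columns=[f"s{i}" for i in range(5)])
    e = ExpressionMatrix(vals)
    cnr = compute_cnr(e, pseudocount=1.0)
    # a synthetic sample equal to the reference scores 0 in every pathway
    ref_sample = ExpressionMatrix(pd.concat([vals, cnr.reference.rename("ref")], axis=1))
    cnr2 = compute_cnr(ref_sample, reference=cnr.reference, pseudocount=1.0)
    p = PathwayDefinition("p", {f"G{i}": a for i, a in zip(range(8), [1, -1, 0.5, -0.5, 1, 1, 0, 0.5])})
    assert compute_pal(p, cnr2, "ref").value == pytest.approx(0.0, abs=1e-12)


def test_log_linearity_shift_by_decade():
    p = PathwayDefinition("p", {"A": 1.0, "B": 1.0})
    df = pd.DataFrame({"s": [2.0, 5.0], "s10": [20.0, 50.0]}, index=["A", "B"])
    cnr = CnrMatrix(df, df["s"])
    assert compute_pal(p, cnr, "s10").value - compute_pal(p, cnr, "s").value == pytest.approx(100.0)


def test_member_permutation_and_split_recombination():
    rng = np.random.default_rng(1)
    genes = [f"G{i}" for i in range(12)]
    arrs = rng.choice([-1, -0.5, 0.5, 1], size=12)
    cnrs = pd.DataFrame({"s": rng.lognormal(0, 1, 12)}, index=genes)
    cnr = CnrMatrix(cnrs, cnrs["s"])
    members = dict(zip(genes, arrs))
    full = compute_pal(PathwayDefinition("p", members), cnr, "s").value
    # permutation invariance
    shuffled = dict(reversed(list(members.items())))
    assert compute_pal(PathwayDefinition("p", shuffled), cnr, "s").value == pytest.approx(full)
    # split by gene subsets, recombine with |ARR|-weighted average
    half1, half2 = dict(list(members.items())[:6]), dict(list(members.items())[6:])
    w1 = sum(abs(a) for a in half1.values())
    w2 = sum(abs(a) for a in half2.values())
    p1 = compute_pal(PathwayDefinition("a", half1), cnr, "s").value
    p2 = compute_pal(PathwayDefinition("b", half2), cnr, "s").value
    assert (w1 * p1 + w2 * p2) / (w1 + w2) == pytest.approx(full)


def test_pal_bound_by_max_log_ratio():
    rng = np.random.default_rng(2)
    genes = [f"G{i}" for i in range(9)]
    cnrs = pd.DataFrame({"s": rng.lognormal(0, 2, 9)}, index=genes)
    cnr = CnrMatrix(cnrs, cnrs["s"])
    members = dict(zip(genes, rng.choice([-1, -0.5, 0.5, 1], size=9)))
    val = compute_pal(PathwayDefinition("p", members), cnr, "s").value
    assert abs(val) <= 100 * np.abs(np.log10(cnrs["s"])).max() + 1e-9


@given(st.integers(0, 10_000))
@settings(max_examples=60, derandomize=True)
def test_pal_matches_direct_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 15))
    genes = [f"G{i}" for i in range(n)]
    arrs = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=n)
    if not np.any(arrs):
        arrs[0] = 1.0
    cnr_vals = rng.lognormal(0, 1.5, size=n)
    df = pd.DataFrame({"s": cnr_vals}, index=genes)
    cnr = CnrMatrix(df, df["s"])
    members = dict(zip(genes, arrs))
    got = compute_pal(PathwayDefinition("p", members), cnr, "s").value
    want = pal_oracle(members, dict(zip(genes, cnr_vals)))
    assert got == pytest.approx(want, rel=1e-12)


class TestBatchPal:
    def setup_method(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(10)]
        df = pd.DataFrame(rng.lognormal(0, 1, size=(10, 10)), index=genes,
                          columns=[f"s{i}" for i in range(10)])
        self.cnr = CnrMatrix(df, df.mean(axis=1))
        self.pathways = [
            PathwayDefinition(f"p{d}", {f"G{i}": 1.0 if i % 2 else -0.5 for i in range(3 * d)})
            for d in (1, 2, 3)
        ]

    def test_shape_and_finiteness(self):
        out = batch_pal(self.pathways, self.cnr)
        assert out.shape == (3, 10)
        assert np.isfinite(out.to_numpy()).all()

    def test_sign_symmetry(self):
        out = batch_pal(self.pathways, self.cnr)
        neg = batch_pal([p.negated() for p in self.pathways], self.cnr)
        assert np.allclose(out.to_numpy(), -neg.to_numpy())

    def test_duplicated_sample_column_gives_identical_pal(self):
        dup = self.cnr.values.copy()
        dup["s0_copy"] = dup["s0"]
        cnr = CnrMatrix(dup, self.cnr.reference)
        out = batch_pal(self.pathways, cnr)
        assert np.allclose(out["s0"], out["s0_copy"])

    def test_matches_per_sample_computation(self):
        out = batch_pal(self.pathways, self.cnr)
        for p in self.pathways:
            for s in ("s0", "s7"):
                assert out.loc[p.name, s] == pytest.approx(compute_pal(p, self.cnr, s).value)


class TestPathwayDefinition:
    def test_rejects_all_zero_arr(self):
        with pytest.raises(ValueError, match="nonzero ARR"):
            PathwayDefinition("p", {"A": 0.0})

    def test_rejects_out_of_range_arr(self):
        with pytest.raises(ValueError, match="ARR values"):
            PathwayDefinition("p", {"A": 0.7})

    def test_absent_members_reduce_coverage(self):
        df = pd.DataFrame({"s": [10.0]}, index=["A"])
        cnr = CnrMatrix(df, df["s"])
        p = PathwayDefinition("p", {"A": 1.0, "MISSING": 1.0})
        res = compute_pal(p, cnr, "s")
        assert res.coverage == 0.5 and res.n_used == 1
        assert res.value == pytest.approx(100.0)

    def test_no_member_present_raises(self):
        df = pd.DataFrame({"s": [1.0]}, index=["A"])
        cnr = CnrMatrix(df, df["s"])
        with pytest.raises(ValueError, match="no member"):
            compute_pal(PathwayDefinition("p", {"B": 1.0}), cnr, "s")

    def test_signed_denominator_mode(self):
        df = pd.DataFrame({"s": [10.0, 10.0]}, index=["A", "B"])
        cnr = CnrMatrix(df, df["s"])
        p = PathwayDefinition("p", {"A": 1.0, "B": -1.0})
        with pytest.raises(ValueError, match="denominator"):
            compute_pal(p, cnr, "s", signed_denominator=True)
        p2 = PathwayDefinition("p2", {"A": 1.0, "B": 0.5})
        got = compute_pal(p2, cnr, "s", signed_denominator=True).value
        assert got == pytest.approx((1.0 + 0.5) * 100 / 1.5)

    def test_tsv_roundtrip(self, tmp_path):
        pws = [PathwayDefinition("p1", {"A": 1.0, "B": -0.5}),
               PathwayDefinition("p2", {"C": 0.5})]
        write_pathways(pws, tmp_path / "p.tsv")
        back = read_pathways(tmp_path / "p.tsv")
        assert [(p.name, dict(p.members)) for p in back] == \
               [(p.name, dict(p.members)) for p in pws]
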