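"""Expression-pipeline tests: FPKM arithmetic, expression filtering,
normalization/GC correction, covariate adjustment, the linear-model DEG
test, BH FDR, fold changes, and DEG-set intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import piaoscan as ps
from piaoscan.degflow import ExpressionSet


def small_eset(counts_union, counts_whole=None, n_case=2,
               length=None, fpkm=None):
    cu = pd.DataFrame(counts_union)
    cu.index = [f"g{i}" for i in range(len(cu))]
    cu.columns = [f"s{j}" for j in range(cu.shape[1])]
    cw = cu.copy() if counts_whole is None else pd.DataFrame(
        counts_whole, index=cu.index, columns=cu.columns)
    length = pd.Series(1000, index=cu.index) if length is None else length
    gene_meta = pd.DataFrame({"length": length, "gc": 0.5}, index=cu.index)
    lib = cu.sum(axis=0).replace(0, 1)
    f = ps.compute_fpkm(cu, gene_meta["length"], lib) if fpkm is None else fpkm
    meta = pd.DataFrame(
        {
            "group": ["case"] * n_case + ["control"] * (cu.shape[1] - n_case),
            "day": (["D7", "D8", "D9"] * cu.shape[1])[: cu.shape[1]],
            "breed": ["Piao"] * n_case + ["Gushi"] * (cu.shape[1] - n_case),
            "lane": "L1",
        },
        index=cu.columns,
    )
    return ExpressionSet(cu, cw, f, gene_meta, meta, lib)


# ---------------------------------------------------------------- FPKM

def test_fpkm_direct_formula():
    fpkm = ps.compute_fpkm(pd.DataFrame({"s": [100, 0]}, index=["a", "b"]),
                           pd.Series([1000, 500], index=["a", "b"]),
                           pd.Series([10**6], index=["s"]))
    assert fpkm.loc["a", "s"] == pytest.approx(100.0)
    assert fpkm.loc["b", "s"] == 0.0


def test_fpkm_matches_elementwise_oracle(rng):
    counts = pd.DataFrame(rng.integers(0, 500, (30, 6)))
    length = pd.Series(rng.integers(200, 10_000, 30), index=counts.index)
    lib = counts.sum(axis=0)
    fpkm = ps.compute_fpkm(counts, length, lib)
    for i in counts.index:
        for j in counts.columns:
            expected = counts.loc[i, j] * 1e9 / (length[i] * lib[j])
            assert fpkm.loc[i, j] == expected


def test_fpkm_zero_lib_size_names_sample():
    with pytest.raises(ValueError, match="s"):
        ps.compute_fpkm(pd.DataFrame({"s": [1]}), pd.Series([100]),
                        pd.Series({"s": 0}))


# ---------------------------------------------------------------- filter

def test_filter_supports_eight_of_nine_cases():
    # gene supported in 8/9 case samples (0.889 ≥ 0.8) → retained
    n_case, n_ctrl = 9, 12
    cu = np.full((1, n_case + n_ctrl), 50)
    cu[0, 0] = 0                       # one unsupporting case sample
    cu[0, n_case:] = 0                 # no control support at all
    eset = small_eset(cu, n_case=n_case)
    assert ps.filter_expressed(eset) == ["g0"]


def test_filter_requires_both_count_models():
    cu = np.full((1, 6), 50)
    cw = np.full((1, 6), 9)            # whole-gene model below threshold
    eset = small_eset(cu, counts_whole=cw, n_case=3)
    assert ps.filter_expressed(eset) == []


def test_filter_keeps_gene_supported_everywhere():
    eset = small_eset(np.full((2, 6), 50), n_case=3)
    assert ps.filter_expressed(eset) == ["g0", "g1"]


def test_filter_matches_exhaustive_reimplementation(rng):
    for _ in range(20):
        n_case, n_ctrl = 4, 6
        cu = rng.integers(0, 30, (15, n_case + n_ctrl))
        cw = cu + rng.integers(0, 5, cu.shape)
        eset = small_eset(cu, counts_whole=cw, n_case=n_case)
        got = set(ps.filter_expressed(eset))
        expected = set()
        for g in eset.counts_union.index:
            ok = []
            for s in eset.counts_union.columns:
                ok.append(
                    eset.counts_union.loc[g, s] >= 10
                    and eset.counts_whole.loc[g, s] >= 10
                    and eset.fpkm.loc[g, s] > 0
                )
            case_ok = sum(o for o, grp in zip(ok, eset.sample_meta["group"])
                          if grp == "case")
            ctrl_ok = sum(o for o, grp in zip(ok, eset.sample_meta["group"])
                          if grp == "control")
            if case_ok / n_case >= 0.8 or ctrl_ok / n_ctrl >= 0.8:
                expected.add(g)
        assert got == expected


# ---------------------------------------------------------------- normalize

def test_log2_offset_formula():
    out = ps.normalize_log2(pd.DataFrame({"s": [100.0]}), offset=1.0)
    assert out.values.iloc[0, 0] == pytest.approx(np.log2(101), abs=1e-9)
    assert not out.gc_corrected


def test_zero_offset_with_zeros_rejected():
    with pytest.raises(ValueError, match="offset"):
        ps.normalize_log2(pd.DataFrame({"s": [0.0]}), offset=0.0)


def test_gc_correction_no_op_on_flat_noiseless_values(rng):
    genes = [f"g{i}" for i in range(60)]
    meta = pd.DataFrame({"length": rng.integers(300, 50_000, 60),
                         "gc": rng.uniform(0.3, 0.7, 60)}, index=genes)
    fpkm = pd.DataFrame({"s1": 64.0, "s2": 128.0}, index=genes)
    out = ps.normalize_log2(fpkm, meta, gc_correct=True)
    raw = ps.normalize_log2(fpkm, meta, gc_correct=False)
    assert np.abs(out.values - raw.values).to_numpy().max() < 1e-6


def test_gc_correction_removes_planted_linear_trend(rng):
    genes = [f"g{i}" for i in range(300)]
    gc = rng.uniform(0.3, 0.7, 300)
    meta = pd.DataFrame({"length": 1000, "gc": gc}, index=genes)
    base = rng.normal(6, 1, 300)
    slope = 4.0
    values = pd.DataFrame({"s1": base + slope * gc,
                           "s2": base + slope * gc + 0.5}, index=genes)
    fpkm = np.exp2(values) - 1.0
    out = ps.normalize_log2(pd.DataFrame(fpkm, index=genes), meta,
                            gc_correct=True)
    for col in out.values.columns:
        fit = np.polyfit(gc, out.values[col], 1)
        assert abs(fit[0]) < 0.05 * slope
        # per-sample mean preserved
        assert out.values[col].mean() == pytest.approx(
            np.log2(fpkm[col] + 1).mean(), abs=1e-8
        )


# ---------------------------------------------------------------- adjustment

def test_adjust_hand_solved_day_example():
    values = pd.DataFrame([[3.0, 5.0, 7.0]], index=["g"],
                          columns=["a", "b", "c"])
    cov = pd.DataFrame({"day": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
    out = ps.adjust_covariates(values, cov)
    np.testing.assert_allclose(out.values.to_numpy(), [[1.0, 1.0, 1.0]],
                               atol=1e-12)


def test_adjust_rejects_constant_covariate():
    values = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
    cov = pd.DataFrame({"flat": [2.0, 2.0, 2.0]}, index=["a", "b", "c"])
    with pytest.raises(ValueError, match="collinear"):
        ps.adjust_covariates(values, cov)


def test_adjust_orthogonal_covariate_is_no_op():
    values = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]],
                          columns=list("abcd"))
    cov = pd.DataFrame({"x": [1.0, 1.0, -1.0, -1.0]}, index=list("abcd"))
    out = ps.adjust_covariates(values, cov)
    np.testing.assert_allclose(out.values.to_numpy(), values.to_numpy(),
                               atol=1e-12)


def test_adjust_is_idempotent(rng):
    values = pd.DataFrame(rng.normal(size=(40, 12)),
                          columns=[f"s{i}" for i in range(12)])
    cov = pd.DataFrame(
        {"day": rng.integers(1, 4, 12).astype(float),
         "lane": rng.integers(0, 2, 12).astype(float)},
        index=values.columns,
    )
    once = ps.adjust_covariates(values, cov)
    twice = ps.adjust_covariates(once, cov)
    np.testing.assert_allclose(once.values.to_numpy(),
                               twice.values.to_numpy(), atol=1e-10)


# ---------------------------------------------------------------- lm_deg

def test_lm_identical_groups_give_null_coefficient():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
        columns=[f"s{i}" for i in range(6)],
    )
    group = pd.Series(["case"] * 3 + ["control"] * 3, index=values.columns)
    out = ps.lm_deg(values, group)
    assert out["coef"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out["p"].iloc[0] == pytest.approx(1.0)


def test_lm_p_invariant_to_sample_order_and_covariate_recoding(rng):
    values = pd.DataFrame(rng.normal(size=(50, 10)),
                          columns=[f"s{i}" for i in range(10)])
    group = pd.Series(["case"] * 5 + ["control"] * 5, index=values.columns)
    cov = pd.DataFrame({"day": rng.integers(1, 4, 10).astype(float)},
                       index=values.columns)
    base = ps.lm_deg(values, group, cov)
    perm = rng.permutation(10)
    shuffled = ps.lm_deg(values.iloc[:, perm], group.iloc[perm],
                         cov.iloc[perm])
    np.testing.assert_allclose(base["p"], shuffled["p"], atol=1e-10)
    recoded = ps.lm_deg(values, group, cov * 3.0 - 5.0)
    np.testing.assert_allclose(base["p"], recoded["p"], atol=1e-10)


def test_lm_requires_residual_df():
    values = pd.DataFrame(rng_vals := np.ones((1, 4)),
                          columns=list("abcd"))
    group = pd.Series(["case", "case", "control", "control"],
                      index=values.columns)
    cov = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                        "y": [1.0, 4.0, 9.0, 16.0]}, index=values.columns)
    with pytest.raises(ValueError, match="degrees of freedom"):
        ps.lm_deg(values, group, cov)


# ---------------------------------------------------------------- BH FDR

def bh_bruteforce(p):
    """Textbook step-up: q_i = min_{p_(j) ≥ p_(i)} min(1, m·p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q


def test_bh_printed_toy_vector():
    q = ps.bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)


def test_bh_single_p():
    assert ps.bh_fdr([0.03])[0] == pytest.approx(0.03)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_bruteforce_and_dominates_p(p):
    q = ps.bh_fdr(p)
    np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
    assert (q >= np.asarray(p) - 1e-12).all()


def test_bh_invariant_to_input_order(rng):
    p = rng.random(25)
    perm = rng.permutation(25)
    np.testing.assert_allclose(ps.bh_fdr(p)[perm], ps.bh_fdr(p[perm]),
                               atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        ps.bh_fdr([0.5, 1.2])


# ---------------------------------------------------------------- fold change

def test_fold_change_simple_ratio():
    fpkm = pd.DataFrame([[10.0, 10.0, 5.0, 5.0]], columns=list("abcd"))
    group = pd.Series(["case", "case", "control", "control"],
                      index=list("abcd"))
    out = ps.fold_change(fpkm, group, pseudo=0.0)
    assert out["fc"].iloc[0] == pytest.approx(2.0)
    assert out["higher"].iloc[0] == "case"


def test_fold_change_equal_means_is_one():
    fpkm = pd.DataFrame([[3.0, 3.0]], columns=["a", "b"])
    group = pd.Series(["case", "control"], index=["a", "b"])
    assert ps.fold_change(fpkm, group)["fc"].iloc[0] == pytest.approx(1.0)


def test_fold_change_pseudo_count_guards_zero():
    fpkm = pd.DataFrame([[0.0, 0.0, 3.56, 3.56]], columns=list("abcd"))
    group = pd.Series(["case", "case", "control", "control"],
                      index=list("abcd"))
    out = ps.fold_change(fpkm, group, pseudo=0.01)
    assert out["fc"].iloc[0] == pytest.approx(357.0)
    assert out["higher"].iloc[0] == "control"


# ---------------------------------------------------------------- intersection

def test_intersection_set_logic():
    report = ps.intersect_degs(
        {"m1": {"A", "B", "C"}, "m2": {"B", "C"}, "m3": {"B", "C", "D"}}
    )
    assert report.final == {"B", "C"}
    assert report.set_sizes == {"m1": 3, "m2": 2, "m3": 3}
    assert report.overlaps[frozenset({"m1", "m2", "m3"})] == 2


def test_intersection_of_duplicated_set_is_itself():
    s = {"x", "y"}
    assert ps.intersect_degs({"a": s, "b": set(s)}).final == s


def test_intersection_matches_bruteforce_on_random_sets(rng):
    ids = np.array([f"g{i}" for i in range(12_000)])
    sets = {
        name: set(rng.choice(ids, size, replace=False))
        for name, size in (("cuffdiff", 826), ("deseq2", 1451), ("lm", 1244))
    }
    report = ps.intersect_degs(sets, universe=ids)
    assert report.final == sets["cuffdiff"] & sets["deseq2"] & sets["lm"]


def test_intersection_excludes_unknown_ids():
    report = ps.intersect_degs(
        {"a": {"g1", "bogus"}, "b": {"g1"}}, universe={"g1", "g2"}
    )
    assert report.final == {"g1"}
    assert report.set_sizes["a"] == 1


# ---------------------------------------------------------------- welch caller

def test_welch_caller_flags_strong_effects(rng):
    values = pd.DataFrame(rng.normal(0, 0.2, (100, 10)),
                          columns=[f"s{i}" for i in range(10)])
    values.iloc[:5, :5] += 5.0
    group = pd.Series(["case"] * 5 + ["control"] * 5, index=values.columns)
    out = ps.welch_degs(values, group)
    assert set(out.index[out["deg"]]) == set(values.index[:5])
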