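import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stmir import datafusion as df
from stmir.types import ExprMatrix, StageError

from conftest import make_expr


# ---------------------------------------------------------------------------
# harmonize_mirna_names


def test_harmonize_collapses_arm_variants_to_median():
    m = make_expr(
        [[2, 6], [4, 2]],
        ["hsa-miR-21-3p", "hsa-miR-21-5p"],
        ["s1", "s2"],
        modality="miRNA",
    )
    out = df.harmonize_mirna_names(m)
    assert list(out.feature_ids) == ["hsa-mir-21"]
    assert out.values.loc["hsa-mir-21"].tolist() == [3.0, 4.0]


def test_harmonize_identity_for_singleton():
    m = make_expr([[1, 1]], ["hsa-let-7a"], ["s1", "s2"], modality="miRNA")
    out = df.harmonize_mirna_names(m)
    assert list(out.feature_ids) == ["hsa-let-7a"]
    assert out.values.iloc[0].tolist() == [1.0, 1.0]


def test_harmonize_three_rows_median_matches_numpy_oracle():
    # oracle: element-wise np.median over the collapsing rows
    vals = np.array([[1.0, 9.0], [5.0, 2.0], [9.0, 4.0]])
    m = make_expr(
        vals, ["hsa-miR-9-3p", "hsa-miR-9-5p", "hsa-miR-9"], ["s1", "s2"],
        modality="miRNA",
    )
    out = df.harmonize_mirna_names(m)
    np.testing.assert_allclose(
        out.values.loc["hsa-mir-9"].to_numpy(), np.median(vals, axis=0)
    )


def test_harmonize_merges_case_variants():
    m = make_expr(
        [[1, 1], [3, 3]], ["hsa-MIR-5", "hsa-mir-5"], ["s1", "s2"], modality="miRNA"
    )
    out = df.harmonize_mirna_names(m)
    assert list(out.feature_ids) == ["hsa-mir-5"]
    assert out.values.iloc[0].tolist() == [2.0, 2.0]


def test_harmonize_rejects_empty_and_wrong_modality():
    empty = make_expr(
        np.empty((0, 2)), [], ["s1", "s2"], modality="miRNA"
    )
    with pytest.raises(ValueError, match="no miRNA features"):
        df.harmonize_mirna_names(empty)
    mrna = make_expr([[1, 2]], ["g1"], ["s1", "s2"])
    with pytest.raises(ValueError, match="miRNA"):
        df.harmonize_mirna_names(mrna)


# ---------------------------------------------------------------------------
# filter_common_features


def test_filter_identity_when_no_zeros():
    a = make_expr([[1, 2], [3, 4]], ["g1", "g2"], ["a1", "a2"])
    b = make_expr([[5, 6], [7, 8]], ["g1", "g2"], ["b1", "b2"])
    fa, fb = df.filter_common_features(a, b)
    pd.testing.assert_frame_equal(fa.values, a.values)
    pd.testing.assert_frame_equal(fb.values, b.values)


def test_filter_zero_fraction_boundary():
    # 19/20 zeros (95%) > 90% -> dropped; 17/20 (85%) -> kept
    n = 20
    row_95 = np.zeros(n); row_95[0] = 1.0
    row_85 = np.zeros(n); row_85[:3] = 1.0
    a = make_expr(
        np.vstack([row_95, row_85]), ["drop", "keep"], [f"a{i}" for i in range(n)]
    )
    b = make_expr(
        np.ones((2, n)), ["drop", "keep"], [f"b{i}" for i in range(n)]
    )
    fa, fb = df.filter_common_features(a, b, max_zero_frac=0.9)
    assert list(fa.feature_ids) == ["keep"]
    assert list(fb.feature_ids) == ["keep"]


def test_filter_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    va = (rng.random((10, 8)) < 0.5) * rng.random((10, 8))
    vb = (rng.random((10, 8)) < 0.5) * rng.random((10, 8))
    feats = [f"g{i}" for i in range(10)]
    a = make_expr(va, feats, [f"a{i}" for i in range(8)])
    b = make_expr(vb, feats, [f"b{i}" for i in range(8)])
    frac = 0.4
    # brute-force oracle: per-row zero counting in plain Python
    expected = [
        f for i, f in enumerate(feats)
        if sum(v == 0 for v in va[i]) / 8 <= frac
        and sum(v == 0 for v in vb[i]) / 8 <= frac
    ]
    fa, fb = df.filter_common_features(a, b, max_zero_frac=frac)
    assert list(fa.feature_ids) == expected
    assert list(fb.feature_ids) == expected


def test_filter_empty_intersection_errors():
    a = make_expr([[1.0]], ["g1"], ["a1"])
    b = make_expr([[1.0]], ["g2"], ["b1"])
    with pytest.raises(ValueError, match="no shared features"):
        df.filter_common_features(a, b)


# ---------------------------------------------------------------------------
# log_transform


@pytest.mark.parametrize("x,base,expected", [(0, 2, 0.0), (3, 2, 2.0), (99, 10, 2.0)])
def test_log_transform_values(x, base, expected):
    m = make_expr([[x]], ["g1"], ["s1"])
    out = df.log_transform(m, base=base)
    assert out.stage == "log"
    assert out.values.iloc[0, 0] == pytest.approx(expected)


def test_log_transform_negative_identifies_cell():
    m = make_expr([[1, 2], [3, -4]], ["g1", "g2"], ["s1", "s2"])
    with pytest.raises(ValueError, match=r"g2.*s2"):
        df.log_transform(m)


def test_log_transform_rejects_wrong_stage():
    m = make_expr([[1.0]], ["g1"], ["s1"], stage="log")
    with pytest.raises(StageError):
        df.log_transform(m)


# ---------------------------------------------------------------------------
# intra_sample_percentile_rank


def test_percentile_rank_example_column():
    m = make_expr([[5.0], [1.0], [3.0]], ["g1", "g2", "g3"], ["s1"], stage="log")
    out = df.intra_sample_percentile_rank(m)
    assert out.values["s1"].tolist() == [0.75, 0.25, 0.5]
    assert out.stage == "percentile"


def test_percentile_rank_all_ties_mid():
    m = make_expr([[2.0], [2.0], [2.0]], ["g1", "g2", "g3"], ["s1"], stage="log")
    out = df.intra_sample_percentile_rank(m)
    assert out.values["s1"].tolist() == [0.5, 0.5, 0.5]


def test_percentile_rank_monotone_invariant():
    rng = np.random.default_rng(1)
    v = rng.random((30, 5))
    feats = [f"g{i}" for i in range(30)]
    samples = [f"s{i}" for i in range(5)]
    base = df.intra_sample_percentile_rank(make_expr(v, feats, samples, stage="log"))
    warped = df.intra_sample_percentile_rank(
        make_expr(np.exp(10 * v), feats, samples, stage="log")
    )
    pd.testing.assert_frame_equal(base.values, warped.values)


def test_percentile_rank_single_feature_errors():
    m = make_expr([[1.0, 2.0]], ["g1"], ["s1", "s2"], stage="log")
    with pytest.raises(ValueError, match="ranking undefined"):
        df.intra_sample_percentile_rank(m)


def test_percentile_rank_strictly_bounded():
    rng = np.random.default_rng(2)
    m = make_expr(rng.random((40, 6)), range(40), range(6), stage="log")
    out = df.intra_sample_percentile_rank(m)
    v = out.values.to_numpy()
    assert v.min() > 0 and v.max() < 1


# ---------------------------------------------------------------------------
# inverse_normal_transform


def _percentile_matrix(rng, n_feat, n_samp):
    v = rng.random((n_feat, n_samp)) * 0.98 + 0.01
    return make_expr(v, range(n_feat), range(n_samp), stage="percentile")


def test_int_median_maps_to_zero():
    m = make_expr(
        [[0.2, 0.5, 0.8]], ["g1"], ["s1", "s2", "s3"], stage="percentile"
    )
    out = df.inverse_normal_transform(m)
    assert out.values.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert out.stage == "z"


def test_int_antisymmetric():
    m = make_expr(
        [[0.1, 0.3, 0.5, 0.7, 0.9]], ["g1"], list("abcde"), stage="percentile"
    )
    out = df.inverse_normal_transform(m).values.to_numpy().ravel()
    np.testing.assert_allclose(out, -out[::-1], atol=1e-12)


def test_int_quantile_0975_frozen_value():
    # standard normal quantile oracle: Phi^{-1}(0.975) = 1.959964 (frozen)
    n = 39  # rank 38 of 39 -> 38/40 = 0.95... need r/(n+1) = 0.975 -> r=0.975*(n+1)
    # use n=39 samples so the top rank 39 gives 39/40 = 0.975
    rng = np.random.default_rng(3)
    v = np.sort(rng.random(n))[None, :]
    m = make_expr(v, ["g1"], [f"s{i}" for i in range(n)], stage="percentile")
    out = df.inverse_normal_transform(m)
    top = out.values.to_numpy().ravel()[np.argmax(v.ravel())]
    assert top == pytest.approx(1.959964, abs=1e-6)


def test_int_row_mean_zero_and_sd_matches_closed_form():
    rng = np.random.default_rng(4)
    n = 64
    m = _percentile_matrix(rng, 20, n)
    out = df.inverse_normal_transform(m).values.to_numpy()
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
    expected_sd = np.std(stats.norm.ppf(np.arange(1, n + 1) / (n + 1)))
    np.testing.assert_allclose(out.std(axis=1), expected_sd, rtol=1e-12)


def test_int_too_few_samples_errors():
    m = make_expr([[0.5]], ["g1"], ["s1"], stage="percentile")
    with pytest.raises(ValueError):
        df.inverse_normal_transform(m)


# ---------------------------------------------------------------------------
# integrate_cohorts


def _z_matrix(features, samples, cohort, seed=0):
    rng = np.random.default_rng(seed)
    return ExprMatrix(
        pd.DataFrame(
            rng.standard_normal((len(features), len(samples))),
            index=features, columns=samples,
        ),
        modality="mRNA", cohort=cohort, stage="z",
    )


def test_integrate_concatenates_columns():
    a = _z_matrix(["g1", "g2"], ["a1", "a2", "a3"], "A", 1)
    b = _z_matrix(["g1", "g2"], ["b1", "b2"], "B", 2)
    out = df.integrate_cohorts(a, b)
    assert out.n_samples == 5
    assert list(out.feature_ids) == ["g1", "g2"]
    assert out.sample_cohorts.tolist() == ["A", "A", "A", "B", "B"]


def test_integrate_self_duplicates_multiset():
    a = _z_matrix(["g1", "g2"], ["a1", "a2"], "A", 3)
    renamed = ExprMatrix(
        a.values.rename(columns={"a1": "b1", "a2": "b2"}), "mRNA", "B", "z"
    )
    out = df.integrate_cohorts(a, renamed)
    for g in ["g1", "g2"]:
        assert sorted(out.values.loc[g]) == sorted(a.values.loc[g].tolist() * 2)


def test_integrate_rejects_feature_mismatch_and_dup_samples():
    a = _z_matrix(["g1", "g2"], ["a1"], "A")
    b = _z_matrix(["g2", "g1"], ["b1"], "B")
    with pytest.raises(ValueError, match="feature order mismatch"):
        df.integrate_cohorts(a, b)
    c = _z_matrix(["g1", "g2"], ["a1"], "B")
    with pytest.raises(ValueError, match="duplicate sample_id"):
        df.integrate_cohorts(a, c)


# ---------------------------------------------------------------------------
# minmax_scale


def test_minmax_endpoints():
    m = _z_matrix(["g1"], ["s1", "s2", "s3"], "A")
    m.values.iloc[0] = [-1.0, 0.0, 3.0]
    out, params = df.minmax_scale(m)
    assert out.values.iloc[0].tolist() == [0.0, 0.25, 1.0]
    assert params.loc["g1", "min"] == -1.0 and params.loc["g1", "max"] == 3.0


def test_minmax_constant_feature_maps_to_zero():
    m = _z_matrix(["g1"], ["s1", "s2"], "A")
    m.values.iloc[0] = [2.0, 2.0]
    out, _ = df.minmax_scale(m)
    assert out.values.iloc[0].tolist() == [0.0, 0.0]


def test_minmax_roundtrip_algebraic_inverse():
    m = _z_matrix([f"g{i}" for i in range(10)], [f"s{i}" for i in range(7)], "A", 5)
    out, params = df.minmax_scale(m)
    back = df.minmax_unscale(out, params)
    np.testing.assert_allclose(back.to_numpy(), m.values.to_numpy(), atol=1e-12)


def test_minmax_external_params_clip_and_validate():
    m = _z_matrix(["g1"], ["s1", "s2"], "A")
    m.values.iloc[0] = [-5.0, 5.0]
    params = pd.DataFrame({"min": [0.0], "max": [1.0]}, index=["g1"])
    out, _ = df.minmax_scale(m, params=params)
    assert out.values.iloc[0].tolist() == [0.0, 1.0]
    bad = pd.DataFrame({"min": [0.0], "max": [1.0]}, index=["gX"])
    with pytest.raises(ValueError, match="absent"):
        df.minmax_scale(m, params=bad)


# ---------------------------------------------------------------------------
# build_training_set / integrate_pair


def test_build_training_set_intersects_samples(training_set, bulk_pair):
    mrna_a, mirna_a, *_ = bulk_pair
    assert training_set.n_samples == 270  # 150 + 120, fully paired
    assert training_set.X.index.equals(training_set.Y.index)


def test_build_training_set_feature_restrict_warns(training_set, bulk_pair, caplog):
    import logging
    from stmir import datafusion
    mrna_a, mirna_a, mrna_b, mirna_b = bulk_pair
    genes = list(mrna_a.feature_ids[:2]) + ["missing-gene"]
    with caplog.at_level(logging.WARNING):
        ts = datafusion.integrate_pair(
            mrna_a, mirna_a, mrna_b, mirna_b, feature_restrict=genes
        )
    assert len(ts.feature_genes) == 2
    assert "missing-gene" in caplog.text


def test_build_training_set_too_few_samples():
    rng = np.random.default_rng(6)
    feats = [f"g{i}" for i in range(5)]
    mrna = ExprMatrix(
        pd.DataFrame(rng.random((5, 5)), index=feats, columns=list("abcde")),
        "mRNA", "A", "scaled01",
    )
    mirna = ExprMatrix(
        pd.DataFrame(rng.random((3, 5)), index=["m1", "m2", "m3"], columns=list("abcde")),
        "miRNA", "A", "scaled01",
    )
    params = pd.DataFrame({"min": 0.0, "max": 1.0}, index=feats)
    with pytest.raises(ValueError, match="insufficient paired samples"):
        df.build_training_set(mrna, mirna, params, params)


def test_training_set_alignment_shuffle_invariant(bulk_pair):
    mrna_a, mirna_a, mrna_b, mirna_b = bulk_pair
    shuffled = ExprMatrix(
        mirna_a.values.sample(frac=1, axis=1, random_state=9),
        "miRNA", mirna_a.cohort, "raw",
    )
    ts1 = df.integrate_pair(mrna_a, mirna_a, mrna_b, mirna_b)
    ts2 = df.integrate_pair(mrna_a, shuffled, mrna_b, mirna_b)
    pd.testing.assert_frame_equal(ts1.Y, ts2.Y)
    pd.testing.assert_frame_equal(ts1.X, ts2.X)


# ---------------------------------------------------------------------------
# pipeline invariants


def test_monotone_batch_invariance_bitwise(truth):
    from stmir import synthdata
    plain = synthdata.generate_bulk_cohort(
        n_samples=50, cohort_label="A", seed=21, truth=truth
    )[0]
    warped = synthdata.generate_bulk_cohort(
        n_samples=50, cohort_label="A", seed=21, truth=truth,
        batch_distortion="scale-power",
    )[0]
    z_plain = df.rank_int_pipeline(plain).values.to_numpy()
    z_warped = df.rank_int_pipeline(warped).values.to_numpy()
    assert np.array_equal(z_plain, z_warped)


def test_stage_guard_never_recomputes():
    m = make_expr([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"], ["s1", "s2"], stage="raw")
    with pytest.raises(StageError):
        df.intra_sample_percentile_rank(m)
    with pytest.raises(StageError):
        df.inverse_normal_transform(m)
    with pytest.raises(StageError):
        df.minmax_scale(m)


def test_scaled01_bounds(training_set):
    for block in (training_set.X, training_set.Y):
        v = block.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0
        # non-constant columns span [0,1]
        spans = v.max(axis=0) - v.min(axis=0)
        assert (spans > 0).all()
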