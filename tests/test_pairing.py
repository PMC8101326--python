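import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mirpair.io import ExpressionMatrix
from mirpair.pairing import (PairRatioTransformer, UnivariateScreen,
                             build_pair_matrix, ct_pair_features, pair_id,
                             screen_logistic, univariate_screen)
from mirpair.simulate import SimConfig, quantize, render_ct, simulate_cohort


def _expr(values, mirnas=None, scale="log2"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    mirnas = mirnas or [f"m{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(
        values, index=mirnas, columns=[f"s{j}" for j in range(values.shape[1])]),
        scale)


@pytest.mark.parametrize("m", range(2, 11))
def test_pair_count_matches_enumeration(m, rng):
    expr = _expr(rng.normal(size=(m, 3)))
    pm = build_pair_matrix(expr)
    assert pm.n_pairs == m * (m - 1) // 2
    # brute-force enumeration oracle
    assert pm.pairs == sorted(itertools.combinations(sorted(expr.mirna_ids), 2))


def test_pair_values_and_orientation():
    expr = _expr([[5.0, 6.0], [3.0, 1.0]], mirnas=["b", "a"])
    pm = build_pair_matrix(expr)
    assert pm.pairs == [("a", "b")]
    np.testing.assert_array_equal(pm.values.loc["a|b"], [-2.0, -5.0])


def test_antisymmetry_of_orientation(rng):
    expr = _expr(rng.normal(size=(5, 8)))
    pm = build_pair_matrix(expr)
    v = expr.values
    for a, b in pm.pairs:
        np.testing.assert_array_equal(
            pm.values.loc[pair_id(a, b)].to_numpy(),
            -(v.loc[b].to_numpy() - v.loc[a].to_numpy()))


def test_unknown_mirna_and_too_few_refused(rng):
    expr = _expr(rng.normal(size=(3, 4)))
    with pytest.raises(KeyError, match="nope"):
        build_pair_matrix(expr, ["m0", "nope"])
    with pytest.raises(ValueError, match="at least 2"):
        build_pair_matrix(expr, ["m0"])


def test_sample_offset_cancels_bit_exactly():
    """The defining invariance: arbitrary per-sample offsets leave every
    pair feature unchanged, bit for bit, on grid-quantized data."""
    cfg = SimConfig(n_case=20, n_control=20, n_mirna=10, seed=3)
    expr, _, _ = simulate_cohort(cfg)
    base = build_pair_matrix(expr).values.to_numpy()
    rng = np.random.default_rng(0)
    for _ in range(5):
        off = quantize(rng.uniform(-10, 10, size=expr.shape[1]), cfg.quantum)
        shifted = ExpressionMatrix(expr.values + off[None, :], "log2")
        assert np.array_equal(build_pair_matrix(shifted).values.to_numpy(), base)


def test_sample_offset_cancels_for_arbitrary_floats(rng):
    # full-precision data: cancellation is no longer bit-exact but holds
    # to rounding error
    expr = _expr(rng.normal(8, 2, size=(6, 30)))
    base = build_pair_matrix(expr).values.to_numpy()
    off = rng.uniform(-10, 10, size=30)
    shifted = ExpressionMatrix(expr.values + off[None, :], "log2")
    np.testing.assert_allclose(build_pair_matrix(shifted).values.to_numpy(),
                               base, atol=1e-12)


def test_missing_member_propagates_to_feature():
    expr = _expr([[1.0, np.nan], [2.0, 3.0]])
    pm = build_pair_matrix(expr)
    assert pm.values.loc["m0|m1", "s0"] == -1.0
    assert np.isnan(pm.values.loc["m0|m1", "s1"])


# ------------------------------------------------------------------ Ct side

def test_delta_ct_value_and_orientation():
    # Ct(a)=20, Ct(b)=24: a is 16-fold more abundant, feature = +4
    ct = _expr([[20.0], [24.0]], mirnas=["a", "b"], scale="ct")
    pm = ct_pair_features(ct, [("a", "b")])
    assert pm.values.loc["a|b", "s0"] == 4.0


def test_ct_input_amount_shift_cancels(rng):
    vals = rng.uniform(18, 32, size=(4, 6))
    ct = _expr(vals, scale="ct")
    pairs = [("m0", "m1"), ("m2", "m3")]
    base = ct_pair_features(ct, pairs).values.to_numpy()
    shifted = _expr(vals + np.array([1.5] * 6)[None, :], scale="ct")
    np.testing.assert_allclose(ct_pair_features(shifted, pairs).values.to_numpy(),
                               base, atol=1e-12)


def test_noise_free_ct_rendering_equals_chip_features():
    cfg = SimConfig(n_case=10, n_control=10, n_mirna=8, ct_noise_sd=0.0, seed=9)
    expr, _, _ = simulate_cohort(cfg)
    ct = render_ct(expr, cfg)
    chip = build_pair_matrix(expr)
    qct = ct_pair_features(ct, chip.pairs)
    assert np.array_equal(chip.values.to_numpy(), qct.values.to_numpy())


def test_ct_missing_member_refused():
    ct = _expr([[20.0]], mirnas=["a"], scale="ct")
    with pytest.raises(KeyError):
        ct_pair_features(ct, [("a", "zzz")])


# ------------------------------------------------------------------- screen

def test_constant_feature_dropped_separating_kept():
    n = 30
    y = np.array([1] * 15 + [0] * 15)
    rng = np.random.default_rng(4)
    const = np.full(n, 2.0)
    sep = np.where(y == 1, 5.0, 1.0) + rng.uniform(0, 0.5, n)  # perfect split
    noise = rng.normal(size=n)
    X = np.column_stack([const, sep, noise])
    res = screen_logistic(X, y)
    assert res["constant"][0] and res["p_value"][0] == 1.0
    assert res["separated"][1] and res["p_value"][1] == 0.0
    assert np.isposinf(res["beta"][1])
    assert not res["separated"][2] and not res["constant"][2]


def test_screen_matches_statsmodels_logit(rng):
    n = 80
    y = (rng.random(n) < 0.5).astype(int)
    if y.sum() < 2 or y.sum() > n - 2:
        y[:2] = [0, 1]
    X = rng.normal(size=(n, 6))
    X[:, 0] += 0.8 * y  # one informative feature
    res = screen_logistic(X, y)
    for j in range(6):
        fit = sm.Logit(y, sm.add_constant(X[:, j])).fit(disp=0)
        assert res["beta"][j] == pytest.approx(fit.params[1], rel=1e-5)
        assert res["p_value"][j] == pytest.approx(fit.pvalues[1], rel=1e-4)


def test_screen_keeps_all_estimable_at_alpha_one(small_cohort):
    _, expr, _, _, y = small_cohort
    pm = build_pair_matrix(expr, labels=y)
    table, kept = univariate_screen(pm, alpha=1.0)
    assert kept.n_pairs == pm.n_pairs  # simulated features are never constant


def test_null_screen_type_one_error():
    rng = np.random.default_rng(12)
    n = 200
    X = rng.normal(size=(n, 200))
    y = np.array([1] * 100 + [0] * 100)
    res = screen_logistic(X, y)
    frac = float(np.mean(res["p_value"] < 0.05))
    assert 0.02 <= frac <= 0.09


def test_screen_flags_planted_pairs(small_cohort):
    _, expr, _, truth, y = small_cohort
    pm = build_pair_matrix(expr, labels=y)
    table, kept = univariate_screen(pm, alpha=0.05)
    for a, b in truth["planted_pairs"]:
        assert table.loc[pair_id(a, b), "kept"]


# ------------------------------------------------------------- transformers

def test_transformer_matches_build_pair_matrix(small_cohort):
    _, expr, _, _, y = small_cohort
    tr = PairRatioTransformer().fit(expr.samples_by_mirnas())
    feats = tr.transform(expr.samples_by_mirnas())
    pm = build_pair_matrix(expr)
    np.testing.assert_array_equal(feats.to_numpy(), pm.X().to_numpy())
    assert list(feats.columns) == list(pm.X().columns)


def test_screen_transformer_filters_columns(small_cohort):
    _, expr, _, truth, y = small_cohort
    X = PairRatioTransformer().fit_transform(expr.samples_by_mirnas())
    sc = UnivariateScreen(alpha=0.05).fit(X, y)
    out = sc.transform(X)
    assert list(out.columns) == sc.kept_
    assert set(pair_id(a, b) for a, b in truth["planted_pairs"]) <= set(sc.kept_)
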