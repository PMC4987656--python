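"""Unit accounting, RPKM arithmetic, sub-genome sums and fold contrasts."""

import math

import numpy as np
import pandas as pd
import pytest

from kranzless import quantify as qt
from kranzless.errors import ConfigError


def _count_matrix(pairs, singles, tissues=None):
    samples = [f"s{i}" for i in range(pairs.shape[1])]
    ids = [f"t{i}" for i in range(pairs.shape[0])]
    meta = pd.DataFrame({
        "sample_id": samples,
        "genotype": samples,
        "tissue": tissues or ["x"] * len(samples),
        "stage": ["x"] * len(samples),
    }).set_index("sample_id")
    return qt.CountMatrix(
        pair_counts=pd.DataFrame(pairs, index=ids, columns=samples),
        singleton_counts=pd.DataFrame(singles, index=ids, columns=samples),
        sample_meta=meta,
    )


def test_read_units_pairs_count_double():
    cm = _count_matrix(np.array([[3]]), np.array([[2]]))
    assert read_value(qt.read_units(cm)) == 8


def read_value(df):
    return df.values[0, 0]


def test_read_units_matches_elementwise_loop():
    rng = np.random.default_rng(1)
    pairs = rng.integers(0, 50, (20, 4))
    singles = rng.integers(0, 20, (20, 4))
    units = qt.read_units(_count_matrix(pairs, singles)).values
    for i in range(20):
        for j in range(4):
            assert units[i, j] == 2 * pairs[i, j] + singles[i, j]


def test_read_units_rejects_negative():
    cm = _count_matrix(np.array([[1]]), np.array([[1]]))
    cm.pair_counts.iloc[0, 0] = -1
    with pytest.raises(ConfigError, match="non-negative"):
        qt.read_units(cm)


def test_rpkm_closed_form_and_scale_invariance():
    units = pd.DataFrame({"s": [1000.0]}, index=["t"])
    rpkm = qt.compute_rpkm(units, pd.Series({"t": 1000.0}),
                           pd.Series({"s": 1_000_000.0}))
    assert rpkm.values.loc["t", "s"] == pytest.approx(1000.0)
    # doubling every count (and hence the library) leaves RPKM unchanged
    rng = np.random.default_rng(2)
    u = pd.DataFrame(rng.integers(1, 100, (10, 3)).astype(float))
    lengths = pd.Series(rng.integers(200, 2000, 10).astype(float))
    r1 = qt.compute_rpkm(u, lengths).values
    r2 = qt.compute_rpkm(2 * u, lengths).values
    pd.testing.assert_frame_equal(r1, r2)
    # length doubling halves RPKM at fixed counts
    r3 = qt.compute_rpkm(u, 2 * lengths, u.sum(axis=0)).values
    assert np.allclose(r3.values, r1.values / 2)


def test_rpkm_matches_spreadsheet_recomputation():
    rng = np.random.default_rng(3)
    units = pd.DataFrame(rng.integers(0, 500, (20, 4)).astype(float))
    lengths = pd.Series(rng.integers(300, 3000, 20).astype(float))
    rpkm = qt.compute_rpkm(units, lengths)
    lib = units.values.sum(axis=0)
    for i in range(20):
        for j in range(4):
            expected = 1e9 * units.values[i, j] / (lengths[i] * lib[j])
            assert rpkm.values.values[i, j] == pytest.approx(expected)


def test_rpkm_rejects_zero_library():
    units = pd.DataFrame({"good": [1.0], "empty": [0.0]}, index=["t"])
    with pytest.raises(ConfigError, match="empty"):
        qt.compute_rpkm(units, pd.Series({"t": 100.0}))


def test_subgenome_aggregate_sums_and_unknown_report():
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0, 7.0]},
        index=["g_A", "g_B", "g_D", "g_X"],
    )
    rpkm = qt.RpkmMatrix(values=values,
                         lengths=pd.Series(1000.0, index=values.index),
                         library_units=pd.Series({"s1": 1e6}))
    ann = pd.DataFrame({
        "transcript_id": values.index,
        "gene": ["g"] * 4,
        "subgenome": ["A", "B", "D", "unknown"],
    })
    table = qt.subgenome_aggregate(rpkm, ann)
    assert table.abd_sum.loc["g", "s1"] == pytest.approx(6.0)
    assert table.unknown_subgenome == ["g_X"]
    assert table.per_copy.loc[("g", "B"), "s1"] == pytest.approx(2.0)


def test_aggregation_is_order_invariant():
    rng = np.random.default_rng(4)
    ids = [f"g{i}_{s}" for i in range(5) for s in "ABD"]
    values = pd.DataFrame(rng.random((15, 2)), index=ids, columns=["s1", "s2"])
    ann = pd.DataFrame({
        "transcript_id": ids,
        "gene": [i.split("_")[0] for i in ids],
        "subgenome": [i.split("_")[1] for i in ids],
    })
    rpkm = lambda v: qt.RpkmMatrix(  # noqa: E731
        values=v, lengths=pd.Series(1000.0, index=v.index),
        library_units=pd.Series({"s1": 1e6, "s2": 1e6}))
    t1 = qt.subgenome_aggregate(rpkm(values), ann)
    perm = values.sample(frac=1, random_state=0)
    t2 = qt.subgenome_aggregate(rpkm(perm), ann)
    pd.testing.assert_frame_equal(t1.abd_sum.sort_index(), t2.abd_sum.sort_index())


@pytest.mark.parametrize("num,den,fold,rounded", [
    (36.2, 0.29, 124.82758620689656, 125),
    (39166.0, 512.3, 76.45129806753855, 76),
    (5.0, 5.0, 1.0, 1),
])
def test_fold_change_arithmetic(num, den, fold, rounded):
    c = qt.fold_change(num, den)
    assert c.fold == pytest.approx(fold)
    assert c.fold_rounded == rounded


def test_fold_change_floor_and_errors():
    with pytest.raises(ConfigError, match="denominator"):
        qt.fold_change(10.0, 0.0)
    c = qt.fold_change(10.0, 0.0, floor=0.5)
    assert c.fold == pytest.approx(20.0)
    flat = qt.fold_change(0.1, 0.2, floor=0.5)
    assert flat.undefined and flat.direction == "flat" and math.isnan(flat.fold)


def test_relative_contrast_product_conventions():
    a = qt.fold_change(36.2, 0.29)
    b = qt.fold_change(39166.0, 512.3)
    rel = qt.relative_contrast(a, b)
    assert rel.rounded_product == 9500
    assert rel.raw_product == pytest.approx((36.2 / 0.29) * (39166.0 / 512.3))
    one = qt.fold_change(2.0, 2.0)
    assert qt.relative_contrast(one, one).rounded_product == 1
    undef = qt.fold_change(0.1, 0.2, floor=0.5)
    assert qt.relative_contrast(a, undef).undefined


@pytest.mark.parametrize("x,want", [(76.45, 76), (124.83, 125), (0.5, 1),
                                    (-0.5, -1), (2.5, 3)])
def test_round_half_away(x, want):
    assert qt.round_half_away(x) == want


def test_library_units_default_to_column_sums():
    rng = np.random.default_rng(5)
    units = pd.DataFrame(rng.integers(0, 100, (30, 3)).astype(float))
    rpkm = qt.compute_rpkm(units, pd.Series(1000.0, index=units.index))
    assert np.allclose(rpkm.library_units.values, units.sum(axis=0).values)
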