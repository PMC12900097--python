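"""Dice, RVD, Wilcoxon signed-rank and dataset aggregation."""
import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from tractformer3d import (dice_score, evaluate_dataset, rvd_score,
                           wilcoxon_signed_rank)
from tractformer3d.evaluate import _rank_sum_distribution


# --- Dice --------------------------------------------------------------------

def test_dice_identity_is_one(rng):
    m = rng.uniform(size=(6, 6, 6)) > 0.5
    assert dice_score(m, m) == 1.0


def test_dice_worked_example():
    pred = np.zeros(200, bool)
    gt = np.zeros(200, bool)
    pred[:100] = True          # |pred| = 100
    gt[40:120] = True          # |gt| = 80, overlap = 60
    assert dice_score(pred, gt) == pytest.approx(2 * 60 / 180)


def test_dice_empty_conventions():
    e = np.zeros((3, 3, 3), bool)
    f = e.copy()
    f[1, 1, 1] = True
    assert dice_score(e, e) == 1.0
    assert dice_score(e, f) == 0.0
    assert dice_score(f, e) == 0.0


def test_dice_matches_voxel_loop_oracle(rng):
    a = rng.uniform(size=(5, 5, 5)) > 0.6
    b = rng.uniform(size=(5, 5, 5)) > 0.6
    inter = sum(1 for idx in np.ndindex(a.shape) if a[idx] and b[idx])
    na = sum(1 for idx in np.ndindex(a.shape) if a[idx])
    nb = sum(1 for idx in np.ndindex(a.shape) if b[idx])
    want = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
    assert dice_score(a, b) == pytest.approx(want, abs=1e-12)


@given(st.integers(0, 2 ** 27 - 1), st.integers(0, 2 ** 27 - 1))
def test_dice_symmetric_and_bounded(seed_a, seed_b):
    a = np.random.default_rng(seed_a).uniform(size=(4, 4, 4)) > 0.5
    b = np.random.default_rng(seed_b).uniform(size=(4, 4, 4)) > 0.5
    d = dice_score(a, b)
    assert 0.0 <= d <= 1.0
    assert d == dice_score(b, a)


def test_adding_shared_voxel_never_decreases_dice():
    """Enumerate all pairs of 2x2 masks; setting one common off-voxel in
    both masks never lowers the Dice score."""
    cells = list(itertools.product([0, 1], repeat=4))
    for pa in cells:
        for pb in cells:
            a = np.array(pa, bool).reshape(2, 2)
            b = np.array(pb, bool).reshape(2, 2)
            base = dice_score(a, b)
            for idx in np.ndindex(2, 2):
                if not a[idx] and not b[idx]:
                    a2, b2 = a.copy(), b.copy()
                    a2[idx] = b2[idx] = True
                    assert dice_score(a2, b2) >= base - 1e-12


# --- RVD ---------------------------------------------------------------------

def test_rvd_examples():
    gt = np.zeros(100, bool)
    gt[:80] = True
    pred = np.zeros(100, bool)
    pred[:80] = True
    assert rvd_score(pred, gt) == 0.0
    pred = np.zeros(130, bool)
    pred[:100] = True
    gt2 = np.zeros(130, bool)
    gt2[:80] = True
    assert rvd_score(pred, gt2) == pytest.approx(20 / 80)
    assert rvd_score(np.zeros(50, bool), np.ones(50, bool)) == 1.0


def test_rvd_not_symmetric_and_empty_gt_rejected():
    a = np.ones(10, bool)
    b = np.zeros(10, bool)
    b[:5] = True
    assert rvd_score(a, b) != rvd_score(b, a)
    with pytest.raises(ValueError):
        rvd_score(a, np.zeros(10, bool))


def test_metric_shape_mismatch():
    with pytest.raises(ValueError):
        dice_score(np.zeros((2, 2)), np.zeros((3, 2)))


# --- Wilcoxon ----------------------------------------------------------------

def test_equal_inputs_are_degenerate():
    with pytest.warns(UserWarning):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.n_used == 0
    assert r.p_value == 1.0


def test_five_positive_differences_exact_p():
    r = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
    assert r.method == "exact"
    assert r.p_value == pytest.approx(2 / 32)


def test_exact_path_matches_scipy_enumeration_small_n(rng):
    for n in range(2, 11):
        for _ in range(20):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            ours = wilcoxon_signed_rank(a, b)
            ref = scipy_wilcoxon(a, b, mode="exact", zero_method="wilcox")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_rank_sum_distribution_equals_brute_enumeration(rng):
    """DP distribution == direct enumeration of all 2^n sign patterns."""
    from scipy.stats import rankdata
    d = rng.normal(size=8)
    ranks = rankdata(np.abs(d))
    scaled = np.rint(2 * ranks).astype(int)
    counts = _rank_sum_distribution(scaled)
    brute = np.zeros_like(counts)
    for signs in itertools.product([0, 1], repeat=8):
        brute[int(np.dot(signs, scaled))] += 1
    np.testing.assert_array_equal(counts, brute)


def test_normal_approximation_close_to_exact_at_boundary(rng):
    """n = 26 uses the approximation; compare with the exact distribution
    computed on the same data."""
    from scipy.stats import rankdata
    a = rng.normal(size=26)
    b = rng.normal(size=26)
    r = wilcoxon_signed_rank(a, b)
    assert r.method == "normal"
    d = (a - b)[(a - b) != 0]
    ranks = rankdata(np.abs(d))
    scaled = np.rint(2 * ranks).astype(int)
    counts = _rank_sum_distribution(scaled)
    w2 = int(round(2 * r.statistic))
    exact_p = min(1.0, 2 * counts[:w2 + 1].sum() / 2.0 ** d.size)
    assert abs(r.p_value - exact_p) < 0.005


def test_p_value_always_in_unit_interval(rng):
    for n in (3, 10, 40):
        for _ in range(10):
            r = wilcoxon_signed_rank(rng.normal(size=n), rng.normal(size=n))
            assert 0.0 <= r.p_value <= 1.0
            assert r.n_used <= n


# --- dataset aggregation -----------------------------------------------------

def _vol(bits, shape=(4, 4, 4)):
    out = np.zeros(np.prod(shape), np.uint8)
    out[:len(bits)] = bits
    return out.reshape(shape)


def test_perfect_predictions_aggregate(phantoms32):
    gts = [ph.labels for ph in phantoms32[:2]]
    res = evaluate_dataset([g.data for g in gts], gts)
    assert res.mean_dsc == 1.0
    assert res.std_dsc == 0.0
    assert res.mean_rvd == 0.0
    assert len(res.table) == 2 * 6


def test_hand_computed_two_subject_three_tract_aggregate():
    gt1 = np.stack([_vol([1] * 8), _vol([1] * 4), _vol([1] * 10)], axis=-1)
    gt2 = np.stack([_vol([1] * 6), _vol([1] * 8), _vol([1] * 2)], axis=-1)
    pr1 = np.stack([_vol([1] * 8), _vol([1] * 2), _vol([1] * 5)], axis=-1)
    pr2 = np.stack([_vol([1] * 3), _vol([1] * 8), _vol([1] * 4)], axis=-1)
    res = evaluate_dataset([pr1, pr2], [gt1, gt2])
    dscs = [2 * 8 / 16, 2 * 2 / 6, 2 * 5 / 15,
            2 * 3 / 9, 2 * 8 / 16, 2 * 2 / 6]
    rvds = [0.0, 2 / 4, 5 / 10, 3 / 6, 0.0, 2 / 2]
    assert res.mean_dsc == pytest.approx(np.mean(dscs))
    assert res.std_dsc == pytest.approx(np.std(dscs, ddof=1))
    assert res.mean_rvd == pytest.approx(np.mean(rvds))
    assert res.std_rvd == pytest.approx(np.std(rvds, ddof=1))
    assert len(res.size_table) == 3


def test_wilcoxon_composes_with_metric_table(phantoms32, rng):
    gts = [ph.labels for ph in phantoms32[:2]]
    noisy = []
    for g in gts:
        d = g.data.copy()
        flip = rng.uniform(size=d.shape) < 0.05
        noisy.append(np.where(flip, 1 - d, d).astype(np.uint8))
    res_a = evaluate_dataset(noisy, gts)
    res_b = evaluate_dataset([g.data for g in gts], gts)
    via_tables = wilcoxon_signed_rank(res_a.table["dsc"], res_b.table["dsc"])
    direct = wilcoxon_signed_rank(res_a.table["dsc"].to_numpy(),
                                  res_b.table["dsc"].to_numpy())
    assert via_tables.p_value == direct.p_value


def test_pairing_violations_rejected():
    with pytest.raises(ValueError):
        evaluate_dataset([np.zeros((2, 2, 2, 1), np.uint8)], [])
    with pytest.raises(ValueError):
        evaluate_dataset([np.zeros((2, 2, 2, 1), np.uint8)],
                         [np.zeros((3, 2, 2, 1), np.uint8)])
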