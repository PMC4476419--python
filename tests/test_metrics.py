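"""Evaluation statistics against brute-force oracles and printed examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iterprot import metrics as mx


# ---------------------------------------------------------------------------
# Q3


def test_q3_examples():
    assert mx.q3(np.array(list("HHEC")), np.array(list("HHEC"))) == 1.0
    assert mx.q3(np.array(list("HHEC")), np.array(list("HHCC"))) == 0.75


def test_q3_rejects_foreign_labels():
    with pytest.raises(ValueError):
        mx.q3(np.array(["H", "X"]), np.array(["H", "H"]))


def test_pooled_q3_is_residue_weighted_mean(rng):
    """Corpus Q3 equals total correct / total residues, not the mean of
    per-protein fractions."""
    lengths = [5, 40, 11]
    trues, preds = [], []
    for L in lengths:
        trues.append(rng.choice(list("CHE"), L))
        preds.append(rng.choice(list("CHE"), L))
    pooled = mx.q3(np.concatenate(trues), np.concatenate(preds))
    brute = sum((t == p).sum() for t, p in zip(trues, preds)) / sum(lengths)
    assert pooled == pytest.approx(brute)


# ---------------------------------------------------------------------------
# Periodic MAE


def test_wraparound_error_is_20_not_340():
    assert mx.periodic_mae(np.array([170.0]), np.array([-170.0])) == \
        pytest.approx(20.0)


def test_zero_error_for_identical_angles(rng):
    a = rng.uniform(-180, 180, 50)
    assert mx.periodic_mae(a, a) == 0.0


def _wrap_min_oracle(t, p):
    """Minimize |t - p + 360k| over k in {-1, 0, 1}."""
    return np.mean([min(abs(ti - pi + 360 * k) for k in (-1, 0, 1))
                    for ti, pi in zip(t, p)])


def test_periodic_mae_matches_brute_force_oracle(rng):
    t = rng.uniform(-180, 180, 2000)
    p = rng.uniform(-180, 180, 2000)
    assert mx.periodic_mae(t, p) == pytest.approx(_wrap_min_oracle(t, p),
                                                  abs=1e-9)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_periodic_mae_symmetric_and_shift_invariant(seed):
    rng = np.random.default_rng(seed)
    t = rng.uniform(-180, 180, 20)
    p = rng.uniform(-180, 180, 20)
    m = mx.periodic_mae(t, p)
    assert mx.periodic_mae(p, t) == pytest.approx(m)
    assert mx.periodic_mae(t + 360.0, p) == pytest.approx(m)


def test_all_masked_raises():
    with pytest.raises(ValueError):
        mx.periodic_mae(np.array([10.0]), np.array([20.0]),
                        mask=np.array([False]))


# ---------------------------------------------------------------------------
# Two-state angle accuracy


def test_phi_two_state_boundary():
    # 60 and 100 both lie in the [0, 150) state
    assert mx.two_state_angle_accuracy(np.array([60.0]), np.array([100.0]),
                                       "phi") == 1.0


def test_psi_two_state_boundary():
    # -150 is outside [-100, 60), 0 is inside -> different states
    assert mx.two_state_angle_accuracy(np.array([-150.0]), np.array([0.0]),
                                       "psi") == 0.0


def test_two_state_perfect_prediction(rng):
    a = rng.uniform(-180, 180, 100)
    for which in ("phi", "psi"):
        assert mx.two_state_angle_accuracy(a, a, which) == 1.0


def test_constant_majority_bin_lower_bound(rng):
    a = rng.uniform(-180, 180, 500)
    for which in ("phi", "psi"):
        bins = mx.two_state_bin(a, which)
        majority = 1.0 if bins.mean() >= 0.5 else 0.0
        const = np.full_like(a, 100.0 if which == "phi" else 0.0)
        const_bin = mx.two_state_bin(const, which)[0]
        acc = mx.two_state_angle_accuracy(a, const, which)
        expect = bins.mean() if const_bin == 1 else 1 - bins.mean()
        assert acc == pytest.approx(expect)
        if const_bin == majority:
            assert acc >= 0.5


# ---------------------------------------------------------------------------
# Confusion matrix


def test_perfect_prediction_is_diagonal(rng):
    t = rng.choice(list("CHE"), 60)
    m = mx.misclassification_matrix(t, t)
    assert (np.diag(m.values).sum()) == 60
    assert m.values.sum() == 60


def test_all_coil_prediction_concentrates_in_c_column():
    t = np.array(list("HHHEEECC"))
    p = np.array(list("CCCCCCCC"))
    m = mx.misclassification_matrix(t, p)
    assert m.loc["H", "C"] == 3 and m.loc["E", "C"] == 3
    assert m.values.sum() == len(t)


def test_q3_equals_trace_over_total(rng):
    t = rng.choice(list("CHE"), 200)
    p = rng.choice(list("CHE"), 200)
    m = mx.misclassification_matrix(t, p)
    assert mx.q3(t, p) == pytest.approx(np.trace(m.values) / m.values.sum())


def test_pairwise_rates_cover_three_pairs(rng):
    t = rng.choice(list("CHE"), 100)
    p = rng.choice(list("CHE"), 100)
    rates = mx.pairwise_confusion_rates(mx.misclassification_matrix(t, p))
    assert set(rates) == {"H<->E", "H<->C", "E<->C"}
    assert all(0 <= v <= 1 for v in rates.values())


# ---------------------------------------------------------------------------
# Pearson and per-AA table


def test_pearson_linear_relations(rng):
    x = rng.normal(size=30)
    assert mx.pearson_cc(x, 2 * x + 1) == pytest.approx(1.0)
    assert mx.pearson_cc(x, -x) == pytest.approx(-1.0)


def test_pearson_constant_raises():
    with pytest.raises(ValueError):
        mx.pearson_cc(np.ones(10), np.arange(10.0))


def test_per_aa_table_frequencies_sum_to_100(tiny_records):
    seqs = [r.sequence for r in tiny_records]
    trues = [r.ss for r in tiny_records]
    table = mx.per_aa_accuracy_table(seqs, trues, trues)
    body = table.drop(index="Overall")
    assert body["frequency"].sum() == pytest.approx(100.0)
    assert body["abundance"].sum() == sum(len(s) for s in seqs)
    assert (body["accuracy"] == 100.0).all()
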