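"""Replicate resampling, Delta aggregation and percentile-tier selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from toxsae.dsae import NetworkSpec, build_network
from toxsae.selection import (
    DeltaProfile,
    ReplicateErrors,
    delta_profile,
    resample_split,
    run_replicates,
    tier_select,
)


def _profile(delta, rsids=None):
    delta = np.asarray(delta, float)
    if rsids is None:
        rsids = [f"rs{i}" for i in range(len(delta))]
    return DeltaProfile(delta=delta, unhealthy_mean=np.abs(delta),
                        healthy_mean=np.zeros_like(delta), rsids=rsids)


def test_split_sizes_and_disjointness():
    labels = np.r_[np.zeros(100, int), np.ones(20, int)]
    train, test = resample_split(labels, seed=0)
    assert len(train) == 80 and len(test) == 40
    assert (labels[train] == 0).all()
    assert (labels[test] == 1).sum() == 20
    assert not set(train) & set(test)
    assert set(train) | set(test) == set(range(120))


def test_split_requires_majority_of_healthy():
    labels = np.r_[np.zeros(10, int), np.ones(10, int)]
    with pytest.raises(ValueError, match="imbalance"):
        resample_split(labels, seed=0)


def test_split_deterministic_per_seed():
    labels = np.r_[np.zeros(50, int), np.ones(5, int)]
    a = resample_split(labels, seed=3)
    b = resample_split(labels, seed=3)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = resample_split(labels, seed=4)
    assert not np.array_equal(a[0], c[0])


def _zero_trainer(spec, X_train, seed):
    """Stub model with x_hat identically zero (all parameters zeroed)."""
    model = build_network(spec, seed=seed)
    for W, b in zip(model.weights, model.biases):
        W[:] = 0.0
        b[:] = 0.0
    return model


def test_replicate_means_match_brute_force_with_stub_model():
    rng = np.random.default_rng(5)
    n, j = 40, 4
    X = rng.integers(0, 3, size=(n, j)).astype(float)
    labels = np.r_[np.zeros(n - 8, int), np.ones(8, int)]
    spec = NetworkSpec(input_width=j, encoder_widths=(3, 2),
                       decoder_widths=(3,), encoder_activations=("tanh", "sigmoid"),
                       decoder_activations=("tanh", "linear"), epochs=1)
    reps = run_replicates(X, labels, spec, b=3, master_seed=6,
                          trainer=_zero_trainer)
    assert reps.b == 3 and reps.minority_count == 8
    # with x_hat == 0 the error is the squared scaled input; recompute by hand
    for r, seed in enumerate(reps.replicate_seeds):
        train, test = resample_split(labels, seed=seed)
        scaled = X[test] / 2.0
        expect_un = (scaled[labels[test] == 1] ** 2).mean(axis=0)
        expect_he = (scaled[labels[test] == 0] ** 2).mean(axis=0)
        assert np.allclose(reps.unhealthy_means[r], expect_un)
        assert np.allclose(reps.healthy_means[r], expect_he)


def test_replicates_deterministic_end_to_end():
    rng = np.random.default_rng(7)
    X = rng.integers(0, 3, size=(60, 5)).astype(float)
    labels = np.r_[np.zeros(50, int), np.ones(10, int)]
    spec = NetworkSpec(input_width=5, encoder_widths=(4, 2),
                       decoder_widths=(4,), encoder_activations=("tanh", "sigmoid"),
                       decoder_activations=("tanh", "linear"), epochs=15)
    a = run_replicates(X, labels, spec, b=2, master_seed=8)
    b = run_replicates(X, labels, spec, b=2, master_seed=8)
    assert np.array_equal(a.unhealthy_means, b.unhealthy_means)
    assert np.array_equal(a.healthy_means, b.healthy_means)
    assert a.replicate_seeds == b.replicate_seeds


def test_delta_profile_hand_computation():
    reps = ReplicateErrors(
        unhealthy_means=[[4.0, 0.0]], healthy_means=[[2.0, 0.0]],
        replicate_seeds=[0], minority_count=1,
    )
    prof = delta_profile(reps, ["rs1", "rs2"])
    assert np.allclose(prof.delta, [2.0, 0.0])


def test_delta_profile_equal_replicate_weight_oracle():
    """Exhaustive hand computation on a small fixture: average the class
    means over replicates with equal weight, then subtract."""
    rng = np.random.default_rng(9)
    un = rng.random((4, 5))
    he = rng.random((4, 5))
    reps = ReplicateErrors(un, he, replicate_seeds=list(range(4)), minority_count=2)
    prof = delta_profile(reps, [f"rs{i}" for i in range(5)])
    expect = np.zeros(5)
    for j in range(5):
        s_un = sum(un[b][j] for b in range(4)) / 4
        s_he = sum(he[b][j] for b in range(4)) / 4
        expect[j] = s_un - s_he
    assert np.allclose(prof.delta, expect)
    assert np.allclose(prof.delta, prof.unhealthy_mean - prof.healthy_mean)


def test_identical_class_means_give_zero_delta():
    m = np.random.default_rng(10).random((3, 4))
    prof = delta_profile(
        ReplicateErrors(m, m.copy(), replicate_seeds=[0, 1, 2], minority_count=1),
        [f"rs{i}" for i in range(4)],
    )
    assert np.allclose(prof.delta, 0.0)


def _brute_force_tier(delta, p):
    """Independent oracle: linear-interpolation percentile from sorted
    order statistics, strict membership."""
    x = sorted(delta)
    n = len(x)
    pos = (p / 100) * (n - 1)
    lo = int(np.floor(pos))
    frac = pos - lo
    cut = x[lo] if lo == n - 1 else x[lo] + frac * (x[lo + 1] - x[lo])
    return {i for i, d in enumerate(delta) if d > cut}


def test_tier_select_matches_brute_force_on_43_distinct_values():
    rng = np.random.default_rng(11)
    delta = rng.normal(size=43)
    assert len(set(delta)) == 43
    report = tier_select(_profile(delta))
    for p in (70, 80, 90, 95):
        members = {report.table.index.get_loc(r) for r in report.tier_members(p)}
        assert members == _brute_force_tier(delta, p)
    assert len(report.tier_members(70)) == 13  # top 30% of 43 distinct reals


def test_tier_sizes_for_distinct_values():
    delta = np.arange(43, dtype=float)
    report = tier_select(_profile(delta))
    sizes = {p: len(report.tier_members(p)) for p in (70, 80, 90, 95)}
    assert sizes == {70: 13, 80: 9, 90: 5, 95: 3}


def test_effect_label_mapping():
    delta = np.arange(43, dtype=float)
    report = tier_select(_profile(delta))
    t = report.table
    # in p90 but not p95 -> large; p80-only -> moderate; p70-only -> small
    in90_not95 = t[t["p90"] & ~t["p95"]]
    assert (in90_not95["effect_label"] == "large").all()
    in80_only = t[t["p80"] & ~t["p90"]]
    assert (in80_only["effect_label"] == "moderate").all()
    in70_only = t[t["p70"] & ~t["p80"]]
    assert (in70_only["effect_label"] == "small").all()
    assert (t.loc[~t["p70"], "tier"] == "none").all()


def test_constant_delta_selects_nothing_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        report = tier_select(_profile(np.ones(10)))
    for p in (70, 80, 90, 95):
        assert report.tier_members(p) == []


def test_literature_cross_reference(panel):
    rng = np.random.default_rng(12)
    delta = rng.normal(size=43)
    prof = _profile(delta, rsids=[e.rsid for e in panel])
    report = tier_select(prof, panel=panel, endpoint="urinary_frequency")
    t = report.table
    assert (t["identified"] == (t["tier"] != "none")).all()
    hits = t[t["identified_for_this_endpoint"]]
    assert (hits["literature_endpoint"] == "urinary_frequency").all()
    assert t.loc["rs10519410", "literature_OR"] == 3.7


def test_nonfinite_delta_rejected():
    with pytest.raises(ValueError):
        tier_select(_profile([1.0, np.nan, 0.0]))


@settings(max_examples=200, derandomize=True)
@given(arrays(np.float64, st.integers(2, 60),
              elements=st.floats(-1e6, 1e6, allow_nan=False)))
def test_tiers_are_nested_for_any_delta(delta):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = tier_select(_profile(delta))
    p70, p80 = set(report.tier_members(70)), set(report.tier_members(80))
    p90, p95 = set(report.tier_members(90)), set(report.tier_members(95))
    assert p95 <= p90 <= p80 <= p70


def test_selection_tsv_output(tmp_path, panel):
    delta = np.linspace(-1, 1, 43)
    prof = _profile(delta, rsids=[e.rsid for e in panel])
    report = tier_select(prof, panel=panel, endpoint="nocturia")
    path = tmp_path / "sel.tsv"
    report.to_tsv(path)
    import pandas as pd

    back = pd.read_csv(path, sep="\t")
    assert len(back) == 43
    assert {"rsid", "delta", "tier", "effect_label", "identified"} <= set(back.columns)
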