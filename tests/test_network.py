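"""Correlation, power adjacency, TOM and module detection contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import _oracles
from cofosnet.datasets import CountMatrix
from cofosnet.network import (
    UNASSIGNED,
    adjacency,
    build_network,
    correlation_matrix,
    detect_modules,
    pick_soft_power,
    scale_free_fit_r2,
    topological_overlap,
)
from cofosnet.simulate import CountSimConfig, GroupSpec, ModuleSpec, planted_modules, simulate_counts


def _matrix_from_array(arr, prefix="R"):
    regions = [f"{prefix}{i:02d}" for i in range(arr.shape[0])]
    subs = pd.DataFrame(
        {
            "subject_id": [f"s{j}" for j in range(arr.shape[1])],
            "phenotype": "AGG",
            "sex": "male",
            "virus_group": "none",
        }
    )
    return CountMatrix(pd.DataFrame(arr, index=regions, columns=subs["subject_id"]), subs)


def test_correlation_identical_and_opposed_profiles():
    base = np.array([1, 5, 2, 8], float)
    neg = 2 * base.mean() - base  # negation about the mean
    arr = np.vstack([base, base, neg]).astype(int)
    S, regions = correlation_matrix(_matrix_from_array(arr))
    assert S[0, 1] == pytest.approx(1.0)
    assert S[0, 2] == pytest.approx(-1.0)
    assert np.diag(S) == pytest.approx(np.ones(3))


def test_correlation_matches_pairwise_formula():
    rng = np.random.default_rng(0)
    arr = rng.integers(0, 500, size=(5, 4))
    S, _ = correlation_matrix(_matrix_from_array(arr))
    x = arr.astype(float)
    for i in range(5):
        for j in range(5):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert S[i, j] == pytest.approx(expected, abs=1e-12)


def test_correlation_zero_variance_policies():
    arr = np.vstack([np.arange(4), np.full(4, 7), np.arange(4) ** 2]).astype(int)
    with pytest.warns(UserWarning):
        S, regions = correlation_matrix(_matrix_from_array(arr))
    assert len(regions) == 2
    with pytest.warns(UserWarning):
        S, regions = correlation_matrix(_matrix_from_array(arr), zero_variance="zero")
    assert len(regions) == 3
    assert S[1, 0] == 0.0 and S[1, 1] == 1.0


@pytest.mark.parametrize(
    "s, beta, mode, expected",
    [
        (1.0, 7.0, "unsigned", 1.0),
        (0.5, 2.0, "unsigned", 0.25),
        (-0.5, 2.0, "unsigned", 0.25),
        (-0.5, 2.0, "signed-hybrid", 0.0),
        (0.5, 2.0, "signed-hybrid", 0.25),
    ],
)
def test_adjacency_definition(s, beta, mode, expected):
    S = np.array([[1.0, s], [s, 1.0]])
    A = adjacency(S, beta, mode)
    assert A[0, 1] == pytest.approx(expected)
    assert A[0, 0] == 0.0  # diagonal removed for connectivity/TOM purposes


def test_adjacency_monotone_in_power():
    rng = np.random.default_rng(1)
    S = rng.uniform(-1, 1, size=(8, 8))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    a3, a5 = adjacency(S, 3.0), adjacency(S, 5.0)
    off = ~np.eye(8, dtype=bool)
    assert (a5[off] <= a3[off] + 1e-15).all()


def test_tom_hand_examples():
    assert topological_overlap(np.zeros((4, 4)))[np.triu_indices(4, 1)] == pytest.approx(0.0)
    complete = np.ones((4, 4)) - np.eye(4)
    tom = topological_overlap(complete)
    # l=2, k=3 -> (2+1)/(3+1-1) = 1
    assert tom == pytest.approx(np.ones((4, 4)))


@pytest.mark.parametrize("seed", range(5))
def test_tom_matches_triple_loop(seed):
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 1, size=(10, 10))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    assert topological_overlap(A) == pytest.approx(_oracles.tom_triple_loop(A), abs=1e-10)


@given(
    arrays(np.float64, (7, 7), elements=st.floats(0, 1, allow_nan=False)),
)
def test_tom_bounds_property(raw):
    A = (raw + raw.T) / 2
    np.fill_diagonal(A, 0.0)
    tom = topological_overlap(A)
    assert tom.min() >= 0.0 and tom.max() <= 1.0
    assert np.allclose(tom, tom.T)
    assert np.diag(tom) == pytest.approx(np.ones(7))


def test_tom_rejects_invalid_adjacency():
    bad = np.array([[0.0, 1.5], [1.5, 0.0]])
    with pytest.raises(ValueError):
        topological_overlap(bad)
    with pytest.raises(ValueError):
        topological_overlap(np.array([[1.0, 0.2], [0.2, 1.0]]))


def test_permutation_equivariance():
    cfg = CountSimConfig(
        n_regions=20, n_subjects_per_group=15, groups=(GroupSpec("AGG", "male"),),
        module_spec=(ModuleSpec("m", 8, 0.7),), group_module_effects={}, seed=2,
    )
    m = simulate_counts(cfg)
    net_a = build_network(m, beta_power=4.0)
    perm = np.random.default_rng(0).permutation(20)
    shuffled = CountMatrix(m.counts.iloc[perm], m.subjects)
    net_b = build_network(shuffled, beta_power=4.0)
    pos = {r: i for i, r in enumerate(net_b.region_ids)}
    reorder = [pos[r] for r in net_a.region_ids]
    assert net_b.S[np.ix_(reorder, reorder)] == pytest.approx(net_a.S)
    assert net_b.tom[np.ix_(reorder, reorder)] == pytest.approx(net_a.tom)
    assert {r: net_b.modules[r] for r in net_a.region_ids} == net_a.modules


def test_detect_modules_block_diagonal_tom():
    tom = np.eye(10)
    tom[:5, :5] = 0.9
    tom[5:, 5:] = 0.9
    np.fill_diagonal(tom, 1.0)
    regions = [f"R{i}" for i in range(10)]
    labels = detect_modules(tom, regions, min_module_size=3)
    mods = {labels[r] for r in regions[:5]}, {labels[r] for r in regions[5:]}
    assert len(mods[0]) == 1 and len(mods[1]) == 1
    assert mods[0] != mods[1]
    assert UNASSIGNED not in (mods[0] | mods[1])


def test_detect_modules_min_size_dominates():
    tom = np.eye(6)
    tom[:3, :3] = 0.8
    np.fill_diagonal(tom, 1.0)
    labels = detect_modules(tom, [f"R{i}" for i in range(6)], min_module_size=5)
    assert set(labels.values()) == {UNASSIGNED}


def test_detect_modules_recovers_planted_structure():
    from sklearn.metrics import adjusted_rand_score

    cfg = CountSimConfig(
        n_regions=45, n_subjects_per_group=20,
        groups=(GroupSpec("AGG", "male"), GroupSpec("AGG", "female")),
        module_spec=(
            ModuleSpec("m1", 8, 0.6), ModuleSpec("m2", 10, 0.6),
            ModuleSpec("m3", 12, 0.6), ModuleSpec("m4", 15, 0.6),
        ),
        group_module_effects={}, seed=42,
    )
    m = simulate_counts(cfg)
    truth = planted_modules(cfg)
    network = build_network(m, beta_power=4.0)
    ari = adjusted_rand_score(
        [truth[r] for r in network.region_ids],
        [network.modules[r] for r in network.region_ids],
    )
    assert ari >= 0.9


def test_pick_soft_power_contracts():
    rng = np.random.default_rng(3)
    noise = rng.standard_normal((30, 12))
    S = np.corrcoef(noise)
    with pytest.warns(UserWarning):
        power = pick_soft_power(S, r2_threshold=0.99, fallback=4.0)
    assert power == 4.0
    # single candidate equal to the fallback is returned unconditionally
    with pytest.warns(UserWarning):
        assert pick_soft_power(S, [7.0], r2_threshold=0.99, fallback=7.0) == 7.0
    with pytest.raises(ValueError):
        pick_soft_power(S, [])
    assert 0.0 <= scale_free_fit_r2(np.abs(rng.standard_normal(50))) <= 1.0
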