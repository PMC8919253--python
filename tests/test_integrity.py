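"""Integrity parameter, break classification, probability tables, census."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cexfrag.chem import Atom, MolecularGraph, cystine_topology
from cexfrag.integrity import (
    BondBaseline,
    baselines_from_thermal,
    bond_distance_series,
    break_probability_table,
    classify_break,
    fragment_census,
    integrity_series,
    integrity_value,
    thermal_baseline,
)
from cexfrag.simulate import Trajectory


def make_trajectory(pos_frames, dt=1.0):
    pos = np.asarray(pos_frames, float)
    return Trajectory(
        np.arange(len(pos)) * dt, pos, np.zeros_like(pos), {"seed": 0}
    )


# ---------------------------------------------------------------------------
# Distance series


def test_constant_distance():
    traj = make_trajectory([[[0, 0, 0], [1.5, 0, 0]]] * 4)
    assert np.allclose(bond_distance_series(traj, (0, 1)), 1.5)


def test_3_4_5_triangle():
    traj = make_trajectory([[[0, 0, 0], [3, 4, 0]]])
    assert bond_distance_series(traj, (0, 1))[0] == pytest.approx(5.0)


def test_linear_separation_matches_closed_form():
    d0, v = 1.2, 0.05
    frames = [[[0, 0, 0], [d0 + v * t, 0, 0]] for t in range(50)]
    d = bond_distance_series(make_trajectory(frames), (0, 1))
    assert np.allclose(d, d0 + v * np.arange(50))


def test_invalid_atom_indices():
    traj = make_trajectory([[[0, 0, 0], [1, 0, 0]]])
    with pytest.raises(IndexError):
        bond_distance_series(traj, (0, 5))


# ---------------------------------------------------------------------------
# Baselines


def test_baseline_constant_series():
    b = thermal_baseline(np.full(10, 1.5))
    assert (b.mu, b.sigma, b.d0) == (1.5, 0.0, 1.5)


def test_baseline_two_points_population_sigma():
    b = thermal_baseline(np.array([1.4, 1.6]))
    assert b.mu == pytest.approx(1.5)
    assert b.sigma == pytest.approx(0.1)  # population, not sample, std
    assert b.d0 == pytest.approx(1.6)


def test_baseline_pooling_order_invariant():
    rng = np.random.default_rng(3)
    runs = [rng.normal(1.8, 0.05, 200) for _ in range(3)]
    a = thermal_baseline(runs)
    b = thermal_baseline(np.concatenate(runs[::-1]))
    assert a.mu == pytest.approx(b.mu)
    assert a.sigma == pytest.approx(b.sigma)


def test_baseline_requires_samples():
    with pytest.raises(ValueError):
        thermal_baseline(np.array([1.5]))


def test_right_skewed_thermal_distribution_d0_exceeds_median():
    """The +1 sigma shift compensates the right skew of anharmonic bond-
    length distributions: d0 lies above the median for a Morse-like series."""
    rng = np.random.default_rng(11)
    d = 1.5 + rng.lognormal(mean=-3.0, sigma=0.8, size=20_000)
    b = thermal_baseline(d)
    assert b.d0 > np.median(d)


# ---------------------------------------------------------------------------
# Integrity kernel


def test_xi_is_one_at_or_below_reference():
    base = BondBaseline(frozenset({0, 1}), 1.5, 0.1)
    d = np.array([0.5, 1.0, 1.55, 1.6])
    assert np.all(integrity_value(d, base.d0) == 1.0)


def test_xi_scalar_oracle_one_decay_length():
    # hand value: exp(-1) at d = d0 + lambda, lambda = decay_scale * d0
    assert integrity_value(3.2, 1.6) == pytest.approx(math.exp(-1.0), abs=1e-12)
    assert integrity_value(2.4, 1.6, decay_scale=0.5) == pytest.approx(
        math.exp(-1.0), abs=1e-12
    )


def test_xi_far_limit_below_1pct():
    assert integrity_value(16.0, 1.6) < 0.01


def test_xi_monotone_beyond_reference():
    d = np.linspace(1.6, 8.0, 200)
    xi = integrity_value(d, 1.6)
    assert np.all(np.diff(xi) <= 0)


def test_xi_rejects_negative_distance():
    with pytest.raises(ValueError):
        integrity_value(np.array([1.0, -0.1]), 1.6)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    arrays(
        float,
        st.integers(1, 50),
        elements=st.floats(0.0, 1e6, allow_nan=False),
    ),
    st.floats(0.1, 10.0),
    st.floats(0.05, 5.0),
)
def test_xi_bounded_on_arbitrary_series(d, d0, decay):
    xi = integrity_value(d, d0, decay)
    assert np.all((0.0 <= xi) & (xi <= 1.0))


# ---------------------------------------------------------------------------
# Break classification


def _series(xi_values, dt=10.0):
    base = BondBaseline(frozenset({0, 1}), 1.0, 0.0)
    # invert the kernel to get distances giving the requested xi exactly
    xi = np.asarray(xi_values, float)
    d = np.where(xi >= 1.0, 1.0, 1.0 - np.log(xi))
    return integrity_series(d, base, np.arange(len(d)) * dt)


def test_always_intact():
    assert classify_break(_series(np.ones(50))) is False


def test_broken_at_end():
    xi = np.concatenate([np.ones(30), np.full(20, 1e-6)])
    assert classify_break(_series(xi)) is True  # last 200 fs below threshold


def test_transient_dip_recovers():
    xi = np.ones(60)
    xi[25:30] = 0.01  # mid-trajectory stretch that re-forms
    assert classify_break(_series(xi)) is False


def test_threshold_validation():
    with pytest.raises(ValueError):
        classify_break(_series(np.ones(5)), threshold=1.5)


def test_classification_matches_brute_force_oracle():
    """50 random series against an independently coded re-evaluation of the
    kernel + trailing-window rule (plain Python, no shared code)."""
    rng = np.random.default_rng(17)
    threshold, persistence, decay = 0.5, 100.0, 1.0
    for case in range(50):
        n = rng.integers(30, 200)
        dt = rng.uniform(2.0, 10.0)
        d0 = rng.uniform(1.0, 3.0)
        d = rng.uniform(0.2, 6.0, n)
        base = BondBaseline(frozenset({0, 1}), d0, 0.0)
        ours = classify_break(
            integrity_series(d, base, np.arange(n) * dt), threshold, persistence
        )
        # --- oracle: scalar math only ---
        t_end = (n - 1) * dt
        flags = []
        for k in range(n):
            if k * dt < t_end - persistence:
                continue
            xi = 1.0 if d[k] <= d0 else math.exp(-(d[k] - d0) / (decay * d0))
            flags.append(xi < threshold)
        assert ours == all(flags), f"case {case}"


# ---------------------------------------------------------------------------
# Tables and census on constructed ensembles


def chain_graph():
    """H3-C0-C1-C2-H4 five-atom chain with labeled backbone bonds."""
    atoms = [
        Atom(0, "C", "C1"), Atom(1, "C", "C2"), Atom(2, "C", "C3"),
        Atom(3, "H", "H1"), Atom(4, "H", "H2"),
    ]
    bonds = {frozenset(p) for p in [(0, 1), (1, 2), (0, 3), (2, 4)]}
    return MolecularGraph(atoms, bonds, charge=0)


def chain_trajectory(break_01: bool):
    """Straight-line chain; optionally atom 0 (+its H) flies away."""
    frames = []
    for t in range(40):
        x0 = -1.5 - (0.5 * t if break_01 else 0.0)
        frames.append(
            [[x0, 0, 0], [0, 0, 0], [1.5, 0, 0], [x0 - 1.1, 0, 0], [2.6, 0, 0]]
        )
    return make_trajectory(frames, dt=10.0)


@pytest.fixture(scope="module")
def chain_baselines():
    g = chain_graph()
    return {
        b: BondBaseline(b, 1.45, 0.08) if all(i < 3 for i in b)
        else BondBaseline(b, 1.05, 0.05)
        for b in g.bonds
    }


@pytest.mark.parametrize(
    "n_broken,n_total,expected_pct",
    [(0, 18, 0), (18, 18, 100), (7, 18, 39), (4, 18, 22)],
)
def test_break_probabilities_and_rounding(
    chain_baselines, n_broken, n_total, expected_pct
):
    """Per-trajectory counting maps k-of-18 event counts to the reported
    integer percentages (7/18 -> 39, 4/18 -> 22)."""
    g = chain_graph()
    trajs = [chain_trajectory(i < n_broken) for i in range(n_total)]
    table = break_probability_table(
        trajs, chain_baselines, {"backbone-01": [frozenset({0, 1})]}, g
    )
    row = table.iloc[0]
    assert row.n_events == n_broken
    assert row.n_opportunities == n_total
    assert row.probability_pct_rounded == expected_pct
    assert row.ci95_low_pct <= row.probability_pct <= row.ci95_high_pct
    assert 0 <= row.ci95_low_pct and row.ci95_high_pct <= 100


def test_counting_modes_differ_for_symmetric_class(chain_baselines):
    """A class with two members broken in the same runs: per-trajectory
    probability is double the per-bond-copy probability."""
    g = chain_graph()
    trajs = [chain_trajectory(i < 9) for i in range(18)]
    classes = {"backbone": [frozenset({0, 1}), frozenset({1, 2})]}
    per_traj = break_probability_table(
        trajs, chain_baselines, classes, g, counting="trajectory"
    )
    per_bond = break_probability_table(
        trajs, chain_baselines, classes, g, counting="bond"
    )
    assert per_traj.iloc[0].probability_pct == pytest.approx(50.0)
    assert per_bond.iloc[0].probability_pct == pytest.approx(25.0)
    assert per_bond.iloc[0].n_opportunities == 36


def test_unknown_class_member_rejected(chain_baselines):
    g = chain_graph()
    with pytest.raises(KeyError):
        break_probability_table(
            [chain_trajectory(False)],
            chain_baselines,
            {"bogus": [frozenset({0, 4})]},
            g,
        )


def test_census_intact_parent(cystine, baselines, refgeom):
    traj = make_trajectory([refgeom] * 30, dt=10.0)
    census = fragment_census([traj], baselines, cystine)
    assert len(census) == 1
    assert census.iloc[0].nominal_mz_plus1 == 241
    assert census.iloc[0]["count"] == 1


def test_census_disulfide_release(cystine, baselines, refgeom):
    """Manually translating the S2 unit away from both CH2 carbons must be
    counted as an intact disulfide cation at nominal m/z 64."""
    s1 = cystine.atom_by_label("S1").index
    s2 = cystine.atom_by_label("S2").index
    frames = []
    for t in range(30):
        pos = refgeom.copy()
        pos[[s1, s2]] += np.array([0.0, 0.0, 1.0 * t])
        frames.append(pos)
    census = fragment_census([make_trajectory(frames, dt=10.0)], baselines, cystine)
    assert 64 in set(census.nominal_mz_plus1)
    assert "S2" in set(census.formula)


def test_census_mass_closure(cystine, baselines, start_frames, ff_charged):
    """Every census row's formula is a sub-multiset of the parent and each
    trajectory's fragments sum exactly to the parent composition."""
    from cexfrag.chem import parse_formula
    from cexfrag.simulate import SimulationConfig, explode

    cfg = SimulationConfig(duration_ps=0.5, save_stride=4)
    trajs = [explode(f, cystine, ff_charged, cfg) for f in start_frames[:4]]
    census = fragment_census(trajs, baselines, cystine)
    parent = cystine.composition().as_dict()
    assert census["count"].sum() >= len(trajs)
    for formula in census.formula:
        counts = parse_formula(formula).as_dict()
        assert all(counts[e] <= parent[e] for e in counts)


def test_census_empty_ensemble_rejected(cystine, baselines):
    with pytest.raises(ValueError):
        fragment_census([], baselines, cystine)


def test_majority_of_default_ensemble_fragments(
    cystine, baselines, start_frames, ff_charged
):
    """With the default +3 protocol, most 1 ps trajectories end with at
    least one broken bond — the regime the break statistics assume."""
    from cexfrag.integrity import broken_bonds
    from cexfrag.simulate import SimulationConfig, explode

    cfg = SimulationConfig(duration_ps=1.0, save_stride=4)
    n_broken = 0
    frames = start_frames[:8]
    for f in frames:
        traj = explode(f, cystine, ff_charged, cfg)
        n_broken += bool(broken_bonds(traj, baselines))
    assert n_broken > len(frames) / 2
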