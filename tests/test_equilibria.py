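import numpy as np
import pytest

from embedgrn.embedding import EmbeddingMap, embed, toggle_subsystem
from embedgrn.equilibria import (
    MARGINAL,
    SADDLE,
    STABLE,
    UNSTABLE,
    axis_equilibria_2d,
    axis_stability_condition,
    interior_stability_condition,
    embedded_axis_stability_condition,
    lifted_interior_stability_condition,
    classify,
    default_box,
    find_equilibria,
    interior_equilibria_2d,
    jacobian,
    saddle_distances,
)
from embedgrn.models import toggle_rhs, tristable_rhs, twonode_rhs
from embedgrn.params import NodeParams, TwoNodeParams
from embedgrn.search import sample_params


def analytic_jacobian_twonode(state, params):
    """Hand-derived Jacobian of the two-node model (independent oracle)."""
    x, y = state
    p1, p2 = params.first, params.second
    j11 = p1.gain / ((1 + p1.self_sat * x) ** 2 * (1 + p1.cross * y)) - p1.deg
    j12 = -p1.gain * x * p1.cross / ((1 + p1.self_sat * x) * (1 + p1.cross * y) ** 2)
    j21 = -p2.gain * y * p2.cross / ((1 + p2.self_sat * y) * (1 + p2.cross * x) ** 2)
    j22 = p2.gain / ((1 + p2.self_sat * y) ** 2 * (1 + p2.cross * x)) - p2.deg
    return np.array([[j11, j12], [j21, j22]])


class TestClassify:
    @pytest.mark.parametrize(
        "eigs,expected",
        [
            ([-1.0, -2.0], STABLE),
            ([-1.0, 2.0], SADDLE),
            ([1.0, 2.0], UNSTABLE),
            ([1e-12, -1.0], MARGINAL),
            ([complex(-1, 5), complex(-1, -5)], STABLE),
        ],
    )
    def test_cases(self, eigs, expected):
        assert classify(eigs, tol=1e-8) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify([])


class TestJacobian:
    def test_linear_decay(self):
        J = jacobian(lambda s: -np.asarray(s), np.array([0.3]))
        np.testing.assert_allclose(J, [[-1.0]], rtol=1e-8)

    def test_toggle_at_origin(self, toggle_params):
        J = jacobian(lambda s: toggle_rhs(s, toggle_params), np.zeros(2))
        np.testing.assert_allclose(J, [[-1.0, 0.0], [0.0, -1.0]], atol=1e-7)

    def test_against_analytic_oracle(self, generic_twonode, rng):
        for state in rng.uniform(0.1, 5, (20, 2)):
            J = jacobian(lambda s: twonode_rhs(s, generic_twonode), state)
            np.testing.assert_allclose(
                J, analytic_jacobian_twonode(state, generic_twonode), rtol=1e-5, atol=1e-6
            )


class TestAxisEquilibria:
    def test_formula(self):
        p = TwoNodeParams.from_values(2.0, 1.0, 1.0, 1.0, 3.0, 2.0, 1.0, 1.0)
        eqs = axis_equilibria_2d(p)
        states = sorted(tuple(e.state) for e in eqs)
        assert states[0] == (0.0, 0.0)
        np.testing.assert_allclose(states[1], (0.0, 1.0))  # ye = (3-1)/(1*2)
        np.testing.assert_allclose(states[2], (1.0, 0.0))  # xe = (2-1)/(1*1)

    def test_gain_equal_deg_gives_origin_only(self):
        p = TwoNodeParams.from_values(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        eqs = axis_equilibria_2d(p)
        assert len(eqs) == 1
        np.testing.assert_array_equal(eqs[0].state, [0.0, 0.0])

    def test_residual_oracle_on_random_draws(self, rng):
        for _ in range(50):
            p = sample_params(rng)
            for e in axis_equilibria_2d(p):
                assert e.residual < 1e-12 * max(1.0, *np.abs(e.state))


class TestInteriorEquilibria:
    def test_residual_oracle_on_random_draws(self, rng):
        found = 0
        for _ in range(500):
            p = sample_params(rng)
            for e in interior_equilibria_2d(p):
                found += 1
                resid = np.max(np.abs(twonode_rhs(e.state, p)))
                assert resid < 1e-10 * max(1.0, *np.abs(e.state))
                assert np.all(e.state > 0)
        assert found > 0  # the draw distribution does produce interior states

    def test_condition_gate_empty(self):
        # strong symmetric cross-repression with weak gains: no interior state
        p = TwoNodeParams.from_values(0.5, 1.0, 5.0, 1.0, 0.5, 1.0, 5.0, 1.0)
        assert interior_equilibria_2d(p) == []

    def test_multistart_cross_check(self, rng):
        # closed-form union equals the multistart result on random draws
        for seed in range(60):
            p = sample_params(np.random.default_rng(seed + 10_000))
            closed = axis_equilibria_2d(p) + interior_equilibria_2d(p)
            hint = max((float(np.max(e.state)) for e in closed), default=1.0)
            box = default_box(p, extra=[hint])
            numeric = find_equilibria(lambda s: twonode_rhs(s, p), box, seed=1)
            a = sorted(tuple(np.round(e.state, 6)) for e in closed)
            b = sorted(tuple(np.round(e.state, 6)) for e in numeric)
            assert a == b, f"draw seed {seed + 10_000}: closed {a} != multistart {b}"


class TestFindEquilibria:
    def test_toggle_counts(self, toggle_params):
        eqs = find_equilibria(lambda s: toggle_rhs(s, toggle_params), [[0, 6]] * 2)
        assert len(eqs) == 3
        assert sorted(e.classification for e in eqs) == [SADDLE, STABLE, STABLE]

    def test_embedded_toggle_counts(self, toggle_params):
        primary = toggle_subsystem(toggle_params, ("z", "u"), auxiliaries=("u",))
        secondary = toggle_subsystem(toggle_params, ("x", "y"))
        es = embed(primary, secondary, EmbeddingMap.sum_of("u", ("x", "y")))
        eqs = find_equilibria(es.rhs, [[0, 6]] * 3)
        assert len(eqs) == 5
        assert sorted(e.classification for e in eqs) == [SADDLE, SADDLE, STABLE, STABLE, STABLE]

    def test_linear_system(self):
        eqs = find_equilibria(lambda s: -s, [[0, 2]])
        assert len(eqs) == 1
        np.testing.assert_allclose(eqs[0].state, [0.0], atol=1e-12)
        assert eqs[0].classification == STABLE

    def test_deterministic(self, toggle_params):
        run = lambda: find_equilibria(lambda s: toggle_rhs(s, toggle_params), [[0, 6]] * 2, seed=3)
        states1 = np.stack([e.state for e in run()])
        states2 = np.stack([e.state for e in run()])
        np.testing.assert_array_equal(states1, states2)

    def test_bad_box(self):
        with pytest.raises(ValueError):
            find_equilibria(lambda s: -s, [[-1, 2]])
        with pytest.raises(ValueError):
            find_equilibria(lambda s: -s, [[0, np.inf]])


class TestAxisStabilityCondition:
    def test_origin_instability_condition(self):
        p = TwoNodeParams.from_values(2.0, 1.0, 1.0, 1.0, 2.0, 1.0, 1.0, 1.0)
        assert axis_stability_condition(p, "origin")

    def test_axis_condition_matches_eigenvalues(self, rng):
        checked = 0
        for _ in range(300):
            p = sample_params(rng)
            if p.first.gain <= p.first.deg:
                continue
            eqs = [e for e in axis_equilibria_2d(p) if e.state[0] > 0]
            if not eqs or eqs[0].classification == MARGINAL:
                continue
            cond = axis_stability_condition(p, "x_axis")
            assert cond == (eqs[0].classification == STABLE)
            checked += 1
        assert checked > 50

    def test_boundary_is_strict(self):
        # gamma1/(1 + sigma2*xe) == k4 exactly: condition must be False
        p = TwoNodeParams.from_values(2.0, 1.0, 1.0, 1.0, 2.0, 1.0, 1.0, 1.0)
        # xe = 1, so gamma1/(1+1*1) = 1 = k4
        assert not axis_stability_condition(p, "x_axis")


class TestInteriorStabilityCondition:
    def test_matches_eigenvalues_on_random_draws(self, rng):
        checked = 0
        for _ in range(2000):
            p = sample_params(rng)
            for e in interior_equilibria_2d(p):
                if e.classification == MARGINAL:
                    continue
                assert interior_stability_condition(p, e.state) == (e.classification == STABLE)
                checked += 1
        assert checked > 20

    def test_no_cross_repression_always_true(self):
        p = TwoNodeParams.from_values(2.0, 1.0, 0.0, 1.0, 2.0, 1.0, 0.0, 1.0)
        assert interior_stability_condition(p, [1.0, 1.0])


def _random_3d_draw(seed):
    rng = np.random.default_rng(seed)
    return sample_params(rng), sample_params(rng)


class TestEmbeddedStabilityConditions:
    def test_axis_conditions_match_3d_eigenvalues(self):
        checked = 0
        for seed in range(400):
            xy, zu = _random_3d_draw(seed)
            rhs = lambda s: tristable_rhs(s, xy, zu)
            px, pz = xy.first, zu.first
            if px.gain <= px.deg or pz.gain <= pz.deg:
                continue
            if not axis_stability_condition(xy, "x_axis"):
                continue  # precondition: 2-D stability
            xe = (px.gain - px.deg) / (px.deg * px.self_sat)
            eigs = np.linalg.eigvals(jacobian(rhs, np.array([xe, 0.0, 0.0])))
            cls = classify(eigs)
            if cls == MARGINAL:
                continue
            assert embedded_axis_stability_condition(xy, zu, "x_axis") == (cls == STABLE)
            checked += 1
        assert checked > 30

    def test_z_axis_condition(self):
        checked = 0
        for seed in range(400):
            xy, zu = _random_3d_draw(seed + 10_000)
            pz = zu.first
            if pz.gain <= pz.deg or pz.self_sat == 0:
                continue
            ze = (pz.gain - pz.deg) / (pz.deg * pz.self_sat)
            rhs = lambda s: tristable_rhs(s, xy, zu)
            eigs = np.linalg.eigvals(jacobian(rhs, np.array([0.0, 0.0, ze])))
            cls = classify(eigs)
            if cls == MARGINAL:
                continue
            assert embedded_axis_stability_condition(xy, zu, "z_axis") == (cls == STABLE)
            checked += 1
        assert checked > 30

    def test_interior_lift_condition(self):
        checked = 0
        for seed in range(3000):
            xy, zu = _random_3d_draw(seed + 20_000)
            interior = [
                e for e in interior_equilibria_2d(xy) if e.classification == STABLE
            ]
            for e in interior:
                point = np.array([e.state[0], e.state[1], 0.0])
                rhs = lambda s: tristable_rhs(s, xy, zu)
                eigs = np.linalg.eigvals(jacobian(rhs, point))
                cls = classify(eigs)
                if cls == MARGINAL:
                    continue
                assert lifted_interior_stability_condition(xy, zu, e.state) == (cls == STABLE)
                checked += 1
        assert checked > 10

    def test_strong_repression_limit(self):
        xy, zu = _random_3d_draw(0)
        # x* + y* -> large: condition holds whenever cross_z > 0
        assert lifted_interior_stability_condition(xy, zu, [1e12, 1e12]) == (zu.first.cross > 0)


class TestSaddleDistances:
    def _eq(self, state, classification):
        from embedgrn.equilibria import Equilibrium

        return Equilibrium(
            state=np.asarray(state, dtype=float),
            residual=0.0,
            eigenvalues=np.array([-1.0]),
            classification=classification,
        )

    def test_three_four_five(self):
        eqs = [self._eq([0, 0, 0], STABLE), self._eq([3, 4, 0], SADDLE)]
        table = saddle_distances(eqs)
        assert len(table) == 1
        np.testing.assert_allclose(table["distance"].iloc[0], 5.0)
        assert bool(table["is_min"].iloc[0])

    def test_matches_brute_force(self, rng):
        stables = [self._eq(s, STABLE) for s in rng.uniform(0, 5, (4, 3))]
        saddles = [self._eq(s, SADDLE) for s in rng.uniform(0, 5, (3, 3))]
        table = saddle_distances(stables + saddles)
        assert len(table) == 12
        for _, row in table.iterrows():
            expected = np.linalg.norm(
                stables[int(row["stable"])].state - saddles[int(row["saddle"])].state
            )
            np.testing.assert_allclose(row["distance"], expected)

    def test_order_invariance_of_distances(self, rng):
        pts = [self._eq(s, STABLE) for s in rng.uniform(0, 5, (3, 2))]
        sds = [self._eq(s, SADDLE) for s in rng.uniform(0, 5, (2, 2))]
        t1 = saddle_distances(pts + sds)
        t2 = saddle_distances(list(reversed(pts)) + sds)
        assert sorted(t1["distance"].round(12)) == sorted(t2["distance"].round(12))

    def test_no_saddles_warns(self):
        with pytest.warns(UserWarning):
            table = saddle_distances([self._eq([0, 0], STABLE)])
        assert table.empty
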