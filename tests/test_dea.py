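import numpy as np
import pytest

from shadea.dea import (
    DEAError,
    DEAInstance,
    brute_force_oracle,
    solve_all,
    solve_input_oriented,
    solve_output_oriented,
)

from conftest import random_instance, xy_instance


class TestTiny3:
    """Known VRS answers on the 3-point fixture A(2,2), B(4,4), C(4,2)."""

    def test_input_oriented_theta(self, tiny3):
        inst = xy_instance(tiny3)
        res = solve_input_oriented(inst, "C")
        assert res.rte == pytest.approx(0.5, abs=1e-9)
        # peer is A: lambda puts all weight there
        assert res.lambdas[inst.index("A")] == pytest.approx(1.0, abs=1e-6)

    def test_output_oriented_phi(self, tiny3):
        inst = xy_instance(tiny3)
        res = solve_output_oriented(inst, "C")
        assert res.theta == pytest.approx(2.0, abs=1e-9)
        assert res.rte == pytest.approx(0.5, abs=1e-9)

    def test_frontier_members_score_one(self, tiny3):
        inst = xy_instance(tiny3)
        for dmu in ("A", "B"):
            assert solve_input_oriented(inst, dmu).rte == pytest.approx(1.0, abs=1e-9)
            assert solve_output_oriented(inst, dmu).rte == pytest.approx(1.0, abs=1e-9)

    def test_solve_all_matches_oracle(self, tiny3):
        inst = xy_instance(tiny3)
        rtes = {r.dmu_id: r.rte for r in solve_all(inst, "input")}
        assert rtes == pytest.approx({"A": 1.0, "B": 1.0, "C": 0.5}, abs=1e-9)


class TestOracle:
    def test_tiny3_input_and_output(self, tiny3):
        inst = xy_instance(tiny3)
        assert brute_force_oracle(inst, "C", "input", grid=1e-3) == pytest.approx(0.5, abs=1e-3)
        assert brute_force_oracle(inst, "C", "output", grid=1e-3) == pytest.approx(0.5, abs=1e-3)

    def test_grid_refinement_tightens_bound(self, tiny3):
        # theta* = 0.5 is on the grid, so probe an off-grid optimum
        inst = random_instance(np.random.default_rng(1), n_dmu=4)
        lp = solve_input_oriented(inst, "D2").rte
        coarse = abs(brute_force_oracle(inst, "D2", "input", grid=0.05) - lp)
        fine = abs(brute_force_oracle(inst, "D2", "input", grid=0.01) - lp)
        assert fine <= coarse + 1e-12

    def test_scope_guard(self):
        rng = np.random.default_rng(0)
        big = random_instance(rng, n_dmu=8)
        with pytest.raises(DEAError, match="oracle"):
            brute_force_oracle(big, "D0", "input")

    @pytest.mark.parametrize("orientation", ["input", "output"])
    def test_lp_matches_oracle_on_random_instances(self, orientation):
        rng = np.random.default_rng(2024)
        grid = 0.02
        worst = 0.0
        for _ in range(50):
            inst = random_instance(rng, n_dmu=4, m_in=2, m_out=1)
            for dmu in inst.dmu_ids:
                lp = (
                    solve_input_oriented(inst, dmu)
                    if orientation == "input"
                    else solve_output_oriented(inst, dmu)
                ).rte
                oracle = brute_force_oracle(inst, dmu, orientation, grid=grid)
                worst = max(worst, abs(lp - oracle))
                # oracle only explores a grid subset of the simplex
                assert lp <= oracle + 1e-9
        assert worst <= 2 * grid


class TestProperties:
    @pytest.mark.parametrize("orientation", ["input", "output"])
    def test_scores_in_unit_interval_and_someone_efficient(self, orientation):
        rng = np.random.default_rng(7)
        for _ in range(20):
            inst = random_instance(rng, n_dmu=8, m_in=3, m_out=2)
            results = solve_all(inst, orientation)
            rtes = np.array([r.rte for r in results])
            assert ((rtes >= 0) & (rtes <= 1 + 1e-12)).all()
            assert any(r.efficient for r in results)
            lam_sums = [r.lambdas.sum() for r in results]
            assert np.allclose(lam_sums, 1.0, atol=1e-6)

    def test_adding_a_dmu_never_raises_rte(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            inst = random_instance(rng, n_dmu=6, m_in=2, m_out=2)
            base = {r.dmu_id: r.rte for r in solve_all(inst, "input")}
            extra = DEAInstance(
                dmu_ids=inst.dmu_ids + ["NEW"],
                X=np.vstack([inst.X, rng.uniform(0.5, 5.0, size=(1, 2))]),
                Y=np.vstack([inst.Y, rng.uniform(0.5, 5.0, size=(1, 2))]),
            )
            grown = {r.dmu_id: r.rte for r in solve_all(extra, "input")}
            for dmu, rte in base.items():
                assert grown[dmu] <= rte + 1e-7

    def test_units_invariance_of_input_orientation(self):
        rng = np.random.default_rng(13)
        inst = random_instance(rng, n_dmu=6, m_in=2, m_out=2)
        scaled = DEAInstance(dmu_ids=inst.dmu_ids, X=inst.X * 37.5, Y=inst.Y)
        a = [r.rte for r in solve_all(inst, "input")]
        b = [r.rte for r in solve_all(scaled, "input")]
        assert a == pytest.approx(b, abs=1e-7)

    def test_orientations_agree_on_frontier_membership(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            inst = random_instance(rng, n_dmu=7, m_in=2, m_out=2)
            eff_in = {r.dmu_id for r in solve_all(inst, "input") if r.efficient}
            eff_out = {r.dmu_id for r in solve_all(inst, "output") if r.efficient}
            assert eff_in == eff_out

    def test_permuting_dmus_leaves_scores_unchanged(self):
        rng = np.random.default_rng(19)
        inst = random_instance(rng, n_dmu=6, m_in=2, m_out=1)
        perm = rng.permutation(6)
        shuffled = DEAInstance(
            dmu_ids=[inst.dmu_ids[i] for i in perm], X=inst.X[perm], Y=inst.Y[perm]
        )
        a = {r.dmu_id: r.rte for r in solve_all(inst, "input")}
        b = {r.dmu_id: r.rte for r in solve_all(shuffled, "input")}
        assert a == pytest.approx(b, abs=1e-8)

    def test_dominating_dmu_is_the_efficient_one(self, frontier4):
        inst = xy_instance(frontier4)
        res = {r.dmu_id: r for r in solve_all(inst, "input")}
        assert res["F1"].efficient
        assert not res["F4"].efficient

    def test_single_dmu_scores_one(self):
        inst = DEAInstance(dmu_ids=["only"], X=np.array([[3.0]]), Y=np.array([[2.0]]))
        assert solve_input_oriented(inst, "only").rte == pytest.approx(1.0)
        assert solve_output_oriented(inst, "only").rte == pytest.approx(1.0)


class TestValidation:
    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DEAError, match="strictly positive"):
            DEAInstance(dmu_ids=["a", "b"], X=np.array([[1.0], [0.0]]), Y=np.array([[1.0], [1.0]]))

    def test_all_zero_outputs_rejected(self):
        with pytest.raises(DEAError):
            DEAInstance(dmu_ids=["a", "b"], X=np.array([[1.0], [1.0]]), Y=np.array([[0.0], [1.0]]))

    def test_nan_rejected(self):
        with pytest.raises(DEAError, match="NaN"):
            DEAInstance(dmu_ids=["a"], X=np.array([[np.nan]]), Y=np.array([[1.0]]))

    def test_unknown_dmu(self, tiny3):
        inst = xy_instance(tiny3)
        with pytest.raises(DEAError, match="unknown"):
            solve_input_oriented(inst, "Z")
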