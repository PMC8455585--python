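import numpy as np
import pytest

from ligandfield import constants, synthdata, waterswap as ws
from ligandfield.waterswap import (LambdaSchedule, SwapState, ToyBox,
                                   default_lambda_schedule,
                                   estimate_free_energy, replica_exchange,
                                   run_window, select_identity_cluster,
                                   swap_components, swap_energy,
                                   swap_gradient)


@pytest.fixture(scope="module")
def swap_state():
    return synthdata.make_swap_system(seed=2, n_waters=10)


class TestSchedule:
    def test_default_schedule_values(self):
        s = default_lambda_schedule()
        assert len(s) == 16
        assert s.values[0] == 0.005
        assert s.values[-1] == 0.995
        diffs = np.diff(s.values)
        assert np.allclose(diffs, 0.066, atol=1e-12)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            LambdaSchedule((0.0, 0.5))          # endpoint not allowed
        with pytest.raises(ValueError):
            LambdaSchedule((0.5, 0.4))          # not increasing


class TestEnergy:
    def test_total_reassembles_from_components(self, swap_state):
        for lam in (0.0, 0.25, 0.8, 1.0):
            st = swap_state.copy()
            st.lam = lam
            total, comp = swap_energy(st)
            manual = (comp["E_proteinbox"] + comp["E_waterbox"]
                      + comp["E_ligand"] + comp["E_cluster"]
                      + (1 - lam) * (comp["E_ligand:proteinbox"]
                                     + comp["E_cluster:waterbox"])
                      + lam * (comp["E_cluster:proteinbox"]
                               + comp["E_ligand:waterbox"]))
            assert total == pytest.approx(manual, abs=1e-9)

    def test_eight_components_present(self, swap_state):
        comp = swap_components(swap_state)
        assert set(comp) == {
            "E_proteinbox", "E_waterbox", "E_ligand", "E_cluster",
            "E_ligand:proteinbox", "E_cluster:waterbox",
            "E_cluster:proteinbox", "E_ligand:waterbox"}

    def test_analytic_gradient_matches_finite_difference(self, swap_state):
        h = 1e-4
        for lam in (0.1, 0.5, 0.9):
            st = swap_state.copy()
            st.lam = lam
            g = swap_gradient(st)
            st.lam = lam + h
            ep, _ = swap_energy(st)
            st.lam = lam - h
            em, _ = swap_energy(st)
            assert g == pytest.approx((ep - em) / (2 * h), abs=1e-6)

    def test_endpoint_energies_decouple_swapped_species(self, swap_state):
        # at lambda = 0 the energy carries no cluster-in-protein-box or
        # ligand-in-water-box contribution, and vice versa at lambda = 1
        st = swap_state.copy()
        st.lam = 0.0
        e0, c = swap_energy(st)
        manual0 = (c["E_proteinbox"] + c["E_waterbox"] + c["E_ligand"]
                   + c["E_cluster"] + c["E_ligand:proteinbox"]
                   + c["E_cluster:waterbox"])
        assert e0 == pytest.approx(manual0, abs=1e-9)
        st.lam = 1.0
        e1, c = swap_energy(st)
        manual1 = (c["E_proteinbox"] + c["E_waterbox"] + c["E_ligand"]
                   + c["E_cluster"] + c["E_cluster:proteinbox"]
                   + c["E_ligand:waterbox"])
        assert e1 == pytest.approx(manual1, abs=1e-9)

    def test_softcore_finite_at_overlap(self):
        # cross terms stay finite when swapped species overlap bulk
        box = ToyBox(np.zeros((2, 3)), [1.6, 1.6], [0.15, 0.15],
                     [0.0, 0.0], ["ligand", "water"])
        e = ws._group_energy(box, np.array([0]), np.array([1]), soft=True)
        assert np.isfinite(e)
        with pytest.raises(ValueError):
            ws._group_energy(box, np.array([0]), np.array([1]), soft=False)


class TestClusterSelection:
    def test_cluster_size_matches_ligand(self, swap_state):
        lig = swap_state.protein_box.indices("ligand")
        assert swap_state.cluster_ids.size == lig.size

    def test_nearest_water_low_index_tie_break(self):
        # one-particle ligand at origin; two waters equidistant
        pb = ToyBox(np.array([[0.0, 0.0, 0.0]]), [1.6], [0.15], [0.0],
                    ["ligand"], (20.0, 20.0, 20.0))
        wb = ToyBox(np.array([[2.0, 0.0, 0.0], [-2.0, 0.0, 0.0]]),
                    [1.6, 1.6], [0.15, 0.15], [0.0, 0.0],
                    ["water", "water"], (20.0, 20.0, 20.0))
        st = SwapState(pb, wb, np.empty(0, dtype=int))
        assert select_identity_cluster(st).tolist() == [0]

    def test_insufficient_waters_rejected(self):
        pb = ToyBox(np.zeros((2, 3)) + [[0, 0, 0], [2, 0, 0]],
                    [1.6, 1.6], [0.15, 0.15], [0.0, 0.0],
                    ["ligand", "ligand"])
        wb = ToyBox(np.array([[1.0, 0.0, 0.0]]), [1.6], [0.15], [0.0],
                    ["water"])
        with pytest.raises(ValueError):
            select_identity_cluster(SwapState(pb, wb, np.empty(0, dtype=int)))


class TestSampling:
    def test_run_window_deterministic_given_seed(self, swap_state):
        a = run_window(swap_state, 0.5, 300, seed=4)
        b = run_window(swap_state, 0.5, 300, seed=4)
        assert np.array_equal(a["gradient_trace"], b["gradient_trace"])
        assert a["acceptance"] == b["acceptance"]

    def test_run_window_burn_in_discard(self, swap_state):
        out = run_window(swap_state, 0.5, 400, seed=1, sample_every=10,
                         equilibration=0.4)
        n_total = len(out["gradient_trace"])
        assert n_total == 40
        assert len(out["gradients"]) == n_total - int(n_total * 0.4)

    def test_ideal_gas_has_zero_energy_and_high_acceptance(self):
        # zero charge, zero epsilon: the energy is identically zero, so
        # every attempted move passes the Metropolis test (the reflection
        # sphere is widened so no proposal is vetoed geometrically)
        pb = ToyBox(np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]]),
                    np.full(3, 1.6), np.zeros(3), np.zeros(3),
                    ["ligand", "water", "water"])
        wb = ToyBox(np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                    np.full(2, 1.6), np.zeros(2), np.zeros(2),
                    ["water", "water"])
        st = SwapState(pb, wb, np.array([0]))
        out = run_window(st, 0.5, 500, seed=0, reflection_radius=1e9)
        assert out["acceptance"] == 1.0
        assert np.allclose(out["energy_trace"], 0.0)

    def test_input_validation(self, swap_state):
        with pytest.raises(ValueError):
            run_window(swap_state, 0.5, 0, seed=0)
        with pytest.raises(ValueError):
            SwapState(swap_state.protein_box, swap_state.water_box,
                      swap_state.cluster_ids, lam=1.5)


class TestEstimators:
    @staticmethod
    def harmonic_windows(k_a, k_b, n_samples=4000, seed=0,
                         temperature=300.0):
        """Exact gradient samples for U(lam) = 0.5 k(lam) x^2.

        dU/dlam = 0.5 (k_b - k_a) x^2 with x ~ N(0, kT / k(lam)); the
        closed-form free energy difference is (kT/2) ln(k_b / k_a).
        """
        rng = np.random.default_rng(seed)
        kt = constants.KBOLTZ * temperature
        windows = []
        for lam in default_lambda_schedule().values:
            k = (1 - lam) * k_a + lam * k_b
            x = rng.normal(0.0, np.sqrt(kt / k), size=n_samples)
            windows.append({"lambda": lam,
                            "gradients": 0.5 * (k_b - k_a) * x ** 2})
        return windows, 0.5 * kt * np.log(k_b / k_a)

    def test_harmonic_closed_form_agreement(self):
        windows, dg_exact = self.harmonic_windows(1.0, 4.0)
        res = estimate_free_energy(windows)
        sem_total = float(np.sqrt((res.gradient_sems ** 2).sum()) * 0.066)
        for est in (res.dg_ti, res.dg_fep, res.dg_bar):
            assert est == pytest.approx(dg_exact, abs=max(5 * sem_total, 0.02))
        # mutual agreement of the three estimators
        assert max(res.dg_ti, res.dg_fep, res.dg_bar) - \
            min(res.dg_ti, res.dg_fep, res.dg_bar) < 0.05
        assert res.dg_average == pytest.approx(
            (res.dg_ti + res.dg_fep + res.dg_bar) / 3)

    def test_constant_gradient_exact_for_all_estimators(self):
        windows = [{"lambda": lam, "gradients": np.full(50, 2.5)}
                   for lam in default_lambda_schedule().values]
        res = estimate_free_energy(windows)
        assert res.dg_ti == pytest.approx(2.5, abs=1e-9)
        assert res.dg_fep == pytest.approx(2.5, abs=1e-9)
        assert res.dg_bar == pytest.approx(2.5, abs=1e-6)

    def test_estimator_input_validation(self):
        with pytest.raises(ValueError):
            estimate_free_energy([{"lambda": 0.5, "gradients": np.ones(50)}])
        short = [{"lambda": l, "gradients": np.ones(3)} for l in (0.2, 0.8)]
        with pytest.raises(ValueError):
            estimate_free_energy(short)


class TestEndToEnd:
    def test_symmetric_swap_free_energy_is_zero(self):
        st = synthdata.make_swap_system(seed=5, n_waters=10, symmetric=True)
        out = ws.run_waterswap(st.protein_box, st.water_box, n_steps=600,
                               n_replicates=2, seed=5)
        # the swap exchanges identical species: dG = 0 within MC error
        assert abs(out["average"]) < max(4 * out["error"], 0.05)

    def test_replica_exchange_windows_cover_schedule(self, swap_state):
        windows = replica_exchange(swap_state.protein_box.copy(),
                                   swap_state.water_box.copy(),
                                   n_steps=400, period=100, seed=0)
        lams = [w["lambda"] for w in windows]
        assert lams == list(default_lambda_schedule().values)
        assert all(len(w["gradients"]) >= 10 for w in windows)
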