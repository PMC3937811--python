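"""Objective, penalty system and the genetic optimizer."""

import numpy as np
import pytest

from sdpgap import (
    Contrast,
    Dataset,
    FitConfig,
    FitProblem,
    default_pc_scheme,
    estimate_uncertainty,
    ga_optimize,
    penalty,
    reduced_chi_squared,
)
from sdpgap.fitting import PenaltyWeights

from conftest import make_sdp


class TestReducedChiSquared:
    def test_perfect_model_is_zero(self):
        I = np.linspace(1, 10, 30)
        assert reduced_chi_squared(I, I, np.ones(30), 5) == 0.0

    def test_one_sigma_residuals_closed_form(self):
        n, p = 40, 7
        I = np.zeros(n)
        model = np.ones(n)  # residual = sigma everywhere
        assert reduced_chi_squared(I, model, np.ones(n), p) == pytest.approx(
            n / (n - p)
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            reduced_chi_squared(np.ones(5), np.ones(5), np.ones(5), 5)

    def test_unit_noise_calibration(self, popc_truth):
        """Chi^2_red at the true parameters averages ~1 over noisy replicates."""
        import sdpgap.synthetic as syn

        q, I0 = syn.forward_curve(popc_truth, popc_truth.datasets[0])
        rng = np.random.default_rng(101)
        sigma_rel = 0.01
        vals = []
        for _ in range(200):
            eps = rng.normal(0.0, sigma_rel, I0.size)
            I = I0 * (1 + eps)
            vals.append(reduced_chi_squared(I, I0, sigma_rel * np.abs(I0), 0))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)


class TestPenalty:
    def test_feasible_state_scores_zero(self, pc_scheme):
        sdp = make_sdp(pc_scheme)  # headgroup volumes sum to exactly 331
        assert penalty(sdp, pc_scheme) == 0.0

    def test_proximity_walls_are_hard(self, pc_scheme):
        sdp = make_sdp(pc_scheme, z_CholCH3=21.0, z_PCN=18.0)  # 3 A apart
        assert penalty(sdp, pc_scheme) == np.inf
        sdp = make_sdp(pc_scheme, z_CG=17.5, D_C=14.32)  # 3.2 A apart
        assert penalty(sdp, pc_scheme) == np.inf

    def test_headgroup_volume_penalty_monotone(self, pc_scheme):
        def with_headgroup_excess(extra):
            sdp = make_sdp(pc_scheme)
            sdp.volumes = dict(sdp.volumes)
            sdp.volumes["PCN"] += extra
            return penalty(sdp, pc_scheme)

        p5, p10 = with_headgroup_excess(5.0), with_headgroup_excess(10.0)
        assert 0 < p5 < p10

    def test_negative_water_flagged(self, pc_scheme):
        # blow up the CG width so headgroup + envelope overfill space
        sdp = make_sdp(pc_scheme, sigma_CG=1.5, z_CG=13.5, D_C=14.5)
        sdp.volumes = dict(sdp.volumes)
        sdp.volumes["CG"] *= 1.0  # keep volumes; geometry alone overfills
        sdp2 = make_sdp(pc_scheme, z_CG=13.0, sigma_CG=1.6, D_C=14.32)
        assert penalty(sdp2, pc_scheme) > 0.0


class TestObjective:
    def _problem(self, truth, n_ds=1):
        import sdpgap.synthetic as syn

        datasets = syn.generate(truth, seed=5)[:n_ds]
        return FitProblem(truth.scheme, datasets, V_L=truth.sdp.V_L)

    def _truth_vector(self, prob, truth, lat):
        vals = {
            "dz_CholCH3": truth.sdp.z_CholCH3 - truth.sdp.z_PCN,
            "z_PCN": truth.sdp.z_PCN,
            "dz_CG": truth.sdp.z_CG - truth.sdp.D_C,
            "sigma_PCN": truth.sdp.sigma_PCN,
            "sigma_CG": truth.sdp.sigma_CG,
            "sigma_CH3": truth.sdp.sigma_CH3,
            "sigma_HC": truth.sdp.sigma_HC,
            "D_C": truth.sdp.D_C,
        }
        for c in truth.scheme.components:
            vals[f"V_{c.name}"] = truth.sdp.volumes[c.name]
        for ds in prob.datasets:
            if ds.geometry == "mlv":
                vals[f"d@{ds.name}"] = lat.d
                vals[f"N@{ds.name}"] = float(lat.N)
                vals[f"eta@{ds.name}"] = lat.eta
                vals[f"N_diff@{ds.name}"] = lat.N_diff
        return np.array([vals[s.name] for s in prob.free])

    def test_objective_near_unity_at_truth(self, popc_truth):
        prob = self._problem(popc_truth)
        x = self._truth_vector(prob, popc_truth, popc_truth.datasets[0].lattice)
        assert prob.objective(x) == pytest.approx(1.0, abs=0.35)

    def test_pooled_equals_per_dataset_sums(self, popc_truth):
        import sdpgap.synthetic as syn

        joint = syn.scenario_library()["popc_joint"]
        datasets = syn.generate(joint, seed=5)
        prob = FitProblem(joint.scheme, datasets, V_L=joint.sdp.V_L)
        x = self._truth_vector(prob, joint, joint.datasets[0].lattice)
        sdp, lattices = prob.decode(x)
        ss = 0.0
        from sdpgap.fitting import _profile_scale_background

        for ds, lat in zip(datasets, lattices):
            M = prob._shape(ds, sdp, lat)
            s, b = _profile_scale_background(ds.q, ds.I, ds.sigma, M, True)
            ss += float(np.sum(((ds.I - s * M - b) / ds.sigma) ** 2))
        expected = ss / (prob.n_points - prob.n_free)
        assert prob.objective(x) == pytest.approx(expected, rel=1e-12)

    def test_out_of_wall_candidate_rejected(self, popc_truth):
        prob = self._problem(popc_truth)
        x = self._truth_vector(prob, popc_truth, popc_truth.datasets[0].lattice)
        names = [s.name for s in prob.free]
        x_bad = x.copy()
        x_bad[names.index("dz_CG")] = 3.5  # beyond the 2 A wall bound
        sdp, _ = prob.decode(x_bad)
        assert penalty(sdp, prob.scheme) == np.inf


class TestGAOptimize:
    def _bowl(self, x):
        return float(np.sum((x - 0.3) ** 2))

    def test_quadratic_bowl_found(self):
        cfg = FitConfig(
            population_size=60, max_generations=80, stagnation_generations=80, seed=4
        )
        ga = ga_optimize(self._bowl, -np.ones(5), np.ones(5), cfg)
        assert np.allclose(ga.x, 0.3, atol=1e-2)

    def test_fixed_seed_bitwise_reproducible(self):
        cfg = FitConfig(
            population_size=40, max_generations=30, stagnation_generations=30, seed=9
        )
        ga1 = ga_optimize(self._bowl, -np.ones(4), np.ones(4), cfg)
        ga2 = ga_optimize(self._bowl, -np.ones(4), np.ones(4), cfg)
        np.testing.assert_array_equal(ga1.x, ga2.x)
        np.testing.assert_array_equal(ga1.population, ga2.population)
        assert ga1.history == ga2.history

    def test_best_fitness_never_increases(self):
        cfg = FitConfig(
            population_size=40, max_generations=60, stagnation_generations=60, seed=2
        )
        ga = ga_optimize(self._bowl, -np.ones(6), np.ones(6), cfg)
        h = np.array(ga.history)
        assert np.all(np.diff(h) <= 0)

    def test_stagnation_stops_after_quota(self):
        calls = {"n": 0}

        def flat(x):
            calls["n"] += 1
            return 1.0  # no improvement ever

        cfg = FitConfig(
            population_size=20,
            max_generations=500,
            stagnation_generations=12,
            seed=1,
            islands=1,
        )
        ga = ga_optimize(flat, np.zeros(3), np.ones(3), cfg)
        assert ga.generations == 12

    def test_bounds_respected_in_final_population(self):
        cfg = FitConfig(
            population_size=40, max_generations=40, stagnation_generations=40, seed=3
        )
        lo, hi = np.array([-2.0, 0.5]), np.array([-1.0, 0.7])
        ga = ga_optimize(self._bowl, lo, hi, cfg)
        assert np.all(ga.population >= lo) and np.all(ga.population <= hi)


class TestUncertainty:
    def _mock_result(self, offset):
        from sdpgap.fitting import FitResult

        return FitResult(
            params={"D_C": 14.0 + offset, "z_PCN": 18.5 - offset},
            chi2_red=1.0,
            chi2_red_per_dataset=[1.0],
            sdp=None,
            structure=None,
            ensemble=[],
            spread={},
            generations=10,
            seed=0,
        )

    def test_identical_runs_zero_spread(self):
        res = [self._mock_result(0.0)] * 3
        out = estimate_uncertainty(res)
        assert out["D_C"]["std"] == 0.0
        assert out["D_C"]["min"] == out["D_C"]["max"]

    def test_spread_statistics(self):
        res = [self._mock_result(o) for o in (-0.5, 0.0, 0.5)]
        out = estimate_uncertainty(res)
        assert out["D_C"]["min"] == pytest.approx(13.5)
        assert out["D_C"]["max"] == pytest.approx(14.5)
        assert out["D_C"]["rel_pct"] == pytest.approx(
            100 * np.std([13.5, 14.0, 14.5]) / 14.0
        )

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            estimate_uncertainty([self._mock_result(0.0)])


class TestDatasetValidation:
    def test_short_dataset_rejected(self):
        q = np.linspace(0.01, 0.1, 10)
        with pytest.raises(ValueError, match="20 points"):
            Dataset(q=q, I=np.ones(10), sigma=np.ones(10))

    def test_nonmonotone_q_rejected(self):
        q = np.linspace(0.01, 0.5, 30)
        q[5] = q[4]
        with pytest.raises(ValueError, match="increasing"):
            Dataset(q=q, I=np.ones(30), sigma=np.ones(30))
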