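"""Synthetic-data generator: curve family, ionograms, datasets, structures."""

import dataclasses

import numpy as np
import pytest

from dmsprops import dms, io, synthetic
from dmsprops.records import Behavior, CurveParams
from dmsprops.conformers import toy_potential, _with_dihedrals


def _params(behavior, **kw):
    base = dict(amplitude_a=6.0, amplitude_c=0.0, turn_sv=4000.0, shape_p=1.8)
    base.update(kw)
    return CurveParams(behavior=behavior, **base)


class TestCurveFamily:
    def test_type_a_monotone_non_increasing(self):
        p = _params(Behavior.A)
        cv = synthetic.dispersion_cv(p, synthetic.DEFAULT_SV_GRID)
        assert np.all(np.diff(cv) <= 0)

    def test_type_c_monotone_non_decreasing(self):
        p = _params(Behavior.C, amplitude_a=0.0, amplitude_c=3.0)
        cv = synthetic.dispersion_cv(p, synthetic.DEFAULT_SV_GRID)
        assert np.all(np.diff(cv) >= 0)

    def test_type_b_interior_minimum_near_analytic(self):
        p = _params(Behavior.B, amplitude_c=2.0, turn_sv=2500.0)
        grid = synthetic.DEFAULT_SV_GRID
        cv = synthetic.dispersion_cv(p, grid)
        im = int(np.argmin(cv))
        assert 0 < im < len(grid) - 1
        dense = np.linspace(grid[0], grid[-1], 100000)
        analytic = dense[np.argmin(synthetic.dispersion_cv(p, dense))]
        assert abs(grid[im] - analytic) <= 250.0  # one grid step

    def test_temperature_strictly_weakens_clustering(self):
        p = _params(Behavior.B, amplitude_c=2.0, turn_sv=2500.0)
        excursions = []
        for temp in (150.0, 225.0, 300.0):
            cv = synthetic.dispersion_cv(
                dataclasses.replace(p, temperature_C=temp), synthetic.DEFAULT_SV_GRID
            )
            excursions.append(-cv.min())
        assert excursions[0] > excursions[1] > excursions[2]

    def test_param_invariants_enforced(self):
        with pytest.raises(ValueError):
            _params(Behavior.A, amplitude_c=1.0)  # A requires c = 0
        with pytest.raises(ValueError):
            _params(Behavior.C, amplitude_a=1.0)  # C requires a = 0
        with pytest.raises(ValueError):
            _params(Behavior.B, turn_sv=5000.0)  # beyond sv_max

    def test_simulate_rejects_bad_inputs(self):
        p = _params(Behavior.A)
        with pytest.raises(ValueError):
            synthetic.simulate_dispersion(p, np.array([]), 0.0)
        with pytest.raises(ValueError):
            synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, -0.1)

    def test_simulation_deterministic(self):
        p = _params(Behavior.B, amplitude_c=2.0, turn_sv=2500.0)
        c1 = synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.3, seed=5)
        c2 = synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.3, seed=5)
        assert np.array_equal(c1.cv, c2.cv)


class TestIonograms:
    def _curve(self):
        p = _params(Behavior.B, amplitude_c=2.0, turn_sv=2500.0)
        return synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.0, seed=0)

    def test_noiseless_argmax_at_cv_opt(self):
        curve = self._curve()
        igs = synthetic.simulate_ionograms(curve, (-15, 10), 0.1, 1.0, noise_frac=0.0)
        assert len(igs) == len(curve)
        for ig, cv_opt in zip(igs, curve.cv):
            assert abs(ig.cv[np.argmax(ig.intensity)] - cv_opt) <= 0.1

    def test_same_seed_bitwise_identical(self):
        curve = self._curve()
        a = synthetic.simulate_ionograms(curve, (-15, 10), 0.1, 1.0, 0.05, seed=7)
        b = synthetic.simulate_ionograms(curve, (-15, 10), 0.1, 1.0, 0.05, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.intensity, y.intensity)

    def test_window_excluding_peak_names_sv(self):
        curve = self._curve()
        with pytest.raises(ValueError, match="SV="):
            synthetic.simulate_ionograms(curve, (5.0, 10.0), 0.1, 1.0)

    def test_fit_roundtrip_recovers_centers(self):
        """Peak fits recover the generator's CV_opt within 3 fitted widths
        for at least 95% of 200 noisy peaks."""
        curve = self._curve()
        n_ok = n_tot = 0
        seed = 7
        while n_tot < 200:
            seed += 1
            igs = synthetic.simulate_ionograms(
                curve, (-15, 10), 0.1, 1.0, noise_frac=0.02, seed=seed
            )
            for ig, cv_true in zip(igs, curve.cv):
                fit = dms.fit_peak(ig)
                if not fit.converged:
                    continue
                n_tot += 1
                n_ok += abs(fit.cv_opt - cv_true) <= 3.0 * fit.sigma
                if n_tot >= 200:
                    break
        assert n_ok / n_tot >= 0.95


class TestDataset:
    def test_89_records_each_with_a_label(self):
        records, truths = synthetic.generate_dataset(89, seed=1)
        assert len(records) == len(truths) == 89
        assert all(len(r.properties) >= 1 for r in records)

    def test_no_missingness_means_all_labels(self):
        records, _ = synthetic.generate_dataset(
            30, seed=2, missing_rates={k: 0.0 for k in synthetic.DEFAULT_MISSING_RATES}
        )
        for r in records:
            assert set(r.properties) == {"ccs", "pkb", "logd", "epsa", "permeability"}

    def test_zero_noise_labels_match_link_functions(self):
        """With noise off every label equals g(params, ccs), recomputed
        independently from the documented affine links."""
        records, truths = synthetic.generate_dataset(
            25, seed=4, noise_scale=0.0,
            missing_rates={k: 0.0 for k in synthetic.DEFAULT_MISSING_RATES},
        )
        for rec, truth in zip(records, truths):
            p, ccs = truth.curve_params, truth.true_ccs
            d = synthetic.excursion_depth(p)
            for prop, link in synthetic.PROPERTY_LINKS.items():
                expected = (
                    link["b0"] + link["bd"] * d + link["bt"] * p.turn_sv
                    + link["bc"] * (1000.0 / ccs)
                )
                assert rec.properties[prop] == pytest.approx(expected, abs=1e-9)
            assert ccs == pytest.approx(
                synthetic.CCS_BASE + synthetic.CCS_PER_AMPLITUDE_C * p.amplitude_c
            )

    def test_byte_identical_for_fixed_seed(self, tmp_path):
        paths = []
        for tag in ("a", "b"):
            records, truths = synthetic.generate_dataset(20, seed=9)
            d = tmp_path / tag
            d.mkdir()
            io.write_dispersion_csv([r.curve for r in records], d / "disp.csv")
            io.write_property_table(records, d / "props.csv")
            io.write_ground_truth_json(truths, d / "gt.json")
            paths.append(d)
        for name in ("disp.csv", "props.csv", "gt.json"):
            assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()

    def test_rejects_tiny_or_bad_mix(self):
        with pytest.raises(ValueError):
            synthetic.generate_dataset(1, seed=0)
        with pytest.raises(ValueError):
            synthetic.generate_dataset(10, class_mix={"quinoline": 0.7}, seed=0)

    def test_noiseless_b_draws_classify_as_b_with_accurate_turn(self, rng):
        """100 noiseless type-B parameter draws: classification always
        returns B and the turn-around lies within one grid step of the
        dense-grid minimum of the curve family."""
        dense = np.linspace(1.0, 4000.0, 40000)
        for i in range(100):
            p = synthetic.sample_curve_params("B", rng)
            curve = synthetic.simulate_dispersion(p, synthetic.DEFAULT_SV_GRID, 0.0, seed=i)
            call = dms.classify_behavior(curve)
            assert call.behavior is Behavior.B
            analytic = dense[np.argmin(synthetic.dispersion_cv(p, dense))]
            assert abs(call.turn_sv - analytic) <= 250.0


class TestToyStructure:
    def test_single_atom(self):
        s = synthetic.generate_toy_structure(1, 0, seed=0)
        assert s.n_atoms == 1 and s.rotatable_dihedrals == []

    @pytest.mark.parametrize("seed", range(10))
    def test_charges_sum_to_plus_one(self, seed):
        s = synthetic.generate_toy_structure(15, 5, seed=seed)
        assert abs(s.charges.sum() - 1.0) < 1e-9

    def test_impossible_rotatable_count_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_toy_structure(5, 3, seed=0)

    def test_single_dihedral_torsion_scan_has_multiple_minima(self):
        """A 1-degree torsion scan of the toy potential over the single
        rotatable dihedral shows at least two local minima."""
        s = synthetic.generate_toy_structure(6, 1, seed=3)
        assert len(s.rotatable_dihedrals) == 1
        angles = np.deg2rad(np.arange(-180.0, 180.0, 1.0))
        energies = np.array(
            [toy_potential(_with_dihedrals(s, np.array([a])))[0] for a in angles]
        )
        n_minima = sum(
            energies[i] < energies[i - 1] and energies[i] < energies[(i + 1) % len(energies)]
            for i in range(len(energies))
        )
        assert n_minima >= 2
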