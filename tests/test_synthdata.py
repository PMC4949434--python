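"""Generator behaviour: ground truth, interpolation, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from emtscreen import synthdata as sd
from emtscreen.parameters import (
    EPITHELIAL_ANCHOR,
    MESENCHYMAL_ANCHOR,
    PARAMETER_NAMES,
    anchor_vector,
    sd_vector,
)


class TestSimulateField:
    def test_epithelial_field_forms_requested_islets(self):
        spec = sd.epithelial_spec(islet_count_mean=8, noise_sd=0.0)
        fld = sd.simulate_field(spec, (256, 256), seed=3)
        n_islets = len(np.unique(fld.truth_colony_ids))
        assert 5 <= n_islets <= 11  # ~8 distinct islets
        # median pairwise distance within an islet stays below the spread
        for k in np.unique(fld.truth_colony_ids):
            pts = fld.truth_centers[fld.truth_colony_ids == k]
            if len(pts) < 2:
                continue
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            pair = d[np.triu_indices(len(pts), 1)]
            assert np.median(pair) < spec.islet_spread_px

    def test_dispersed_field_has_larger_nn_distance(self):
        epi = sd.simulate_field(sd.epithelial_spec(noise_sd=0.0), seed=5)
        mes = sd.simulate_field(sd.mesenchymal_spec(noise_sd=0.0), seed=5)

        def mean_nn(pts):
            d, _ = cKDTree(pts).query(pts, k=2)
            return d[:, 1].mean()

        assert mean_nn(mes.truth_centers) > mean_nn(epi.truth_centers)

    def test_toxic_field_emits_at_most_fifth_of_nominal_count(self):
        spec = sd.toxic_spec(nuclei_count_mean=120)
        for seed in range(5):
            fld = sd.simulate_field(spec, seed=seed)
            assert len(fld.truth_centers) <= 0.2 * spec.nuclei_count_mean

    def test_centers_conserved_and_inside_image(self):
        fld = sd.simulate_field(sd.mesenchymal_spec(), (128, 192), seed=2)
        assert len(fld.truth_centers) == len(fld.truth_colony_ids)
        assert (fld.truth_centers[:, 0] >= 0).all()
        assert (fld.truth_centers[:, 0] <= 127).all()
        assert (fld.truth_centers[:, 1] <= 191).all()
        ids = np.unique(fld.truth_colony_ids)
        assert ids.min() >= 0 and len(ids) == ids.max() + 1  # contiguous

    def test_deterministic_given_seed(self):
        a = sd.simulate_field(sd.partial_spec(0.4), seed=9)
        b = sd.simulate_field(sd.partial_spec(0.4), seed=9)
        np.testing.assert_array_equal(a.nuclei_image, b.nuclei_image)
        np.testing.assert_array_equal(a.fibronectin_image, b.fibronectin_image)
        np.testing.assert_array_equal(a.truth_centers, b.truth_centers)

    def test_invalid_shape_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_field(sd.mesenchymal_spec(), (32, 32), seed=0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.PhenotypeSpec(label="epithelial", severity=1.5)
        with pytest.raises(sd.ConfigurationError):
            sd.PhenotypeSpec(label="wrong")
        with pytest.raises(sd.ConfigurationError):
            sd.PhenotypeSpec(label="mesenchymal", nuclei_count_mean=-3)


class TestSimulateProfile:
    def test_zero_noise_severity_zero_is_epithelial_anchor(self):
        vec = sd.simulate_profile(sd.epithelial_spec(noise_sd=0.0), seed=0)
        np.testing.assert_array_equal(vec, anchor_vector(EPITHELIAL_ANCHOR))

    def test_zero_noise_midpoint_is_anchor_average(self):
        vec = sd.simulate_profile(sd.partial_spec(0.5, noise_sd=0.0), seed=0)
        mid = 0.5 * (anchor_vector(EPITHELIAL_ANCHOR)
                     + anchor_vector(MESENCHYMAL_ANCHOR))
        np.testing.assert_allclose(vec, mid, rtol=0, atol=1e-12)

    def test_monte_carlo_mean_matches_interpolation(self):
        spec = sd.partial_spec(0.3)
        n = 10_000
        draws = np.array([sd.simulate_profile(spec, seed=s) for s in range(n)])
        expected = sd.profile_mean(spec)
        se = sd_vector() / np.sqrt(n)
        informative = se > 0
        dev = np.abs(draws.mean(axis=0) - expected)[informative]
        assert (dev < 3 * se[informative]).all()
        np.testing.assert_array_equal(draws.mean(axis=0)[~informative],
                                      expected[~informative])

    def test_marginal_sd_matches_assay_sd(self):
        draws = np.array([sd.simulate_profile(sd.mesenchymal_spec(), seed=s)
                          for s in range(4000)])
        sds = draws.std(axis=0)
        target = sd_vector()
        ok = target > 0
        np.testing.assert_allclose(sds[ok], target[ok], rtol=0.1)


class TestSimulatePlate:
    def test_all_negative_noise_free_profiles_identical(self):
        layout = sd.PlateLayout("P1", 96, {
            wid: sd.WellSpec("neg_dmso") for wid in sd.well_ids(96)[:16]})
        df = sd.simulate_plate(layout, sd.ScreenTruth(), seed=1, noise_sd=0.0)
        vals = df[list(PARAMETER_NAMES)].to_numpy()
        assert np.ptp(vals, axis=0).max() == 0.0

    def test_plate_effect_is_additive_per_parameter(self):
        layout = sd.PlateLayout("P1", 96, {
            wid: sd.WellSpec("neg_dmso") for wid in sd.well_ids(96)[:16]})
        effect = np.arange(len(PARAMETER_NAMES), dtype=float)
        base = sd.simulate_plate(layout, sd.ScreenTruth(), plate_effect=None, seed=4)
        shifted = sd.simulate_plate(layout, sd.ScreenTruth(), plate_effect=effect,
                                    seed=4)
        diff = (shifted[list(PARAMETER_NAMES)].mean()
                - base[list(PARAMETER_NAMES)].mean()).to_numpy()
        np.testing.assert_allclose(diff, effect, atol=1e-9)

    def test_unknown_library_compound_rejected(self):
        layout = sd.PlateLayout("P1", 96, {"A01": sd.WellSpec("neg_dmso"),
                                           "A02": sd.WellSpec("library", "GHOST", 10.0)})
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_plate(layout, sd.ScreenTruth(), seed=0)

    def test_control_severity_decreases_with_concentration(self):
        sevs = [sd.control_severity("GW6604", c) for c in sd.CONTROL_LADDER_UM]
        assert all(a < b for a, b in zip(sevs, sevs[1:]))
        assert sd.control_severity("GW6604", 10.0) < 0.05
        assert sd.control_severity("LY-364947", 10.0) < 0.001

    def test_deterministic_given_seed(self, small_screen):
        raw2 = sd.simulate_screen(small_screen["layouts"], small_screen["truth"],
                                  seed=123)
        pd.testing.assert_frame_equal(small_screen["raw"], raw2)


class TestDoseSeries:
    def test_midpoint_and_asymptotes(self):
        ds = sd.simulate_dose_series(2.0, 1.3, top=10.0, bottom=2.0,
                                     concentrations=[2.0], noise_sd=0.0)
        assert ds["response"].iloc[0] == pytest.approx(6.0)
        lo = sd.simulate_dose_series(2.0, 1.3, 10.0, 2.0, [1e-8], 0.0)
        hi = sd.simulate_dose_series(2.0, 1.3, 10.0, 2.0, [1e8], 0.0)
        assert lo["response"].iloc[0] == pytest.approx(10.0, abs=1e-6)
        assert hi["response"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_dose_series(2.0, 1.0, 1.0, 0.0, [1.0, -1.0])
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_dose_series(-2.0, 1.0, 1.0, 0.0, [1.0])


class TestDilutionGrid:
    def test_two_point_grid(self):
        np.testing.assert_allclose(sd.make_dilution_grid(12.0, 2, 4.0), [12.0, 3.0])

    def test_invalid_arguments_rejected(self):
        for bad in ((0, 5, 3), (10, 1, 3), (10, 5, 1.0)):
            with pytest.raises(sd.ConfigurationError):
                sd.make_dilution_grid(*bad)


class TestTranslocationField:
    def test_anchor_ratios_at_extremes(self):
        f0 = sd.simulate_translocation_field(0.0, n_cells=16, seed=1)
        f1 = sd.simulate_translocation_field(1.0, n_cells=16, seed=1)
        assert f0.truth_ratio == pytest.approx(sd.RATIO_STIMULATED)
        assert f1.truth_ratio == pytest.approx(sd.RATIO_UNSTIMULATED)

    def test_out_of_range_inhibition_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.simulate_translocation_field(1.2)


class TestLayoutsAndTruth:
    def test_layout_yaml_round_trip(self, tmp_path):
        layout = sd.default_layout("P007", 384, ["CMPA", "CMPB"])
        path = tmp_path / "layout.yaml"
        layout.to_yaml(path)
        back = sd.PlateLayout.from_yaml(path)
        assert back.plate_id == "P007"
        assert back.wells == layout.wells

    def test_invalid_well_id_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.PlateLayout("P1", 384, {"Q01": sd.WellSpec("neg_dmso")})
        assert not sd.validate_well_id("Q01", 384)
        assert sd.validate_well_id("P24", 384)
        assert not sd.validate_well_id("I01", 96)

    def test_truth_classes_must_be_disjoint(self):
        with pytest.raises(sd.ConfigurationError):
            sd.ScreenTruth(active_compounds={"A": 0.9}, toxic_compounds={"A"})
        with pytest.raises(sd.ConfigurationError):
            sd.ScreenTruth(active_compounds={"A": 0.9}, receptor_like={"B"})

    def test_default_screen_covers_library(self):
        layouts, truth = sd.default_screen(n_plates=2, seed=0)
        lib = {ws.compound_id for lay in layouts for ws in lay.wells.values()
               if ws.role == "library"}
        covered = (set(truth.active_compounds) | truth.toxic_compounds
                   | truth.inactive_compounds)
        assert lib == covered
        assert len(truth.active_compounds) == round(0.01 * len(lib))
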