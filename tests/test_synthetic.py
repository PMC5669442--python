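import numpy as np
import pytest

from radsurv.errors import ConfigError, ValidationError
from radsurv.features import BinningSpec, discretize, glrl, grey_level_nonuniformity
from radsurv.features.shape import roundness, shape_features
from radsurv.survival import harrell_c
from radsurv.synthetic import (
    CohortSpec,
    PhantomSpec,
    dice,
    make_cohort,
    make_phantom,
    make_reader_pair,
)


class TestPhantom:
    def test_determinism_per_seed(self):
        spec = PhantomSpec(seed=4, spiculation_amplitude=0.1)
        v1, m1 = make_phantom(spec)
        v2, m2 = make_phantom(spec)
        np.testing.assert_array_equal(v1.intensities, v2.intensities)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_smooth_equal_radii_is_spherical(self):
        spec = PhantomSpec(
            shape=(30, 40, 40), spacing=(1.0, 1.0, 1.0),
            radii_mm=(11.0, 11.0, 11.0), spiculation_amplitude=0.0, seed=0,
        )
        _, mask = make_phantom(spec)
        f = shape_features(mask)
        assert f["roundness"] >= 0.95
        assert f["sphericity"] >= 0.95

    def test_spiculation_monotonically_reduces_roundness(self):
        values = []
        for amp in (0.0, 0.08, 0.16, 0.24, 0.32):
            spec = PhantomSpec(
                shape=(36, 48, 48), spacing=(1.0, 1.0, 1.0),
                radii_mm=(10.0, 10.0, 10.0), spiculation_amplitude=amp,
                spiculation_count=10, seed=7,
            )
            _, mask = make_phantom(spec)
            values.append(roundness(mask))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_texture_variance_orders_gln_fixed_bin_width(self):
        # with fixed-bin-width discretization, stronger texture spreads runs
        # over more grey levels, so grey-level nonuniformity trends DOWN with
        # texture variance (GLN is a run-concentration measure: it is large
        # when runs pile up in few levels)
        variances = (400.0, 900.0, 1600.0, 3600.0, 6400.0)
        glns = []
        for var in variances:
            spec = PhantomSpec(
                texture_variance_hu2=var, texture_correlation_mm=6.0, seed=3
            )
            vol, mask = make_phantom(spec)
            droi = discretize(vol, mask, BinningSpec(mode="fixed_width", bin_width=50.0))
            glns.append(grey_level_nonuniformity(glrl(droi)))
        slope = np.polyfit(np.log(variances), glns, 1)[0]
        assert slope < 0
        assert glns[-1] < 0.9 * glns[0]

    def test_oversized_radii_rejected(self):
        with pytest.raises(ConfigError):
            PhantomSpec(shape=(10, 10, 10), spacing=(1, 1, 1), radii_mm=(20, 5, 5))


class TestReaderPair:
    def test_zero_perturbation_identity(self, small_phantom):
        _, mask = small_phantom
        reader_b = make_reader_pair(mask, perturbation_mm=0.0, seed=1)
        np.testing.assert_array_equal(reader_b.voxels, mask.voxels)
        assert reader_b.reader_id == "B"

    def test_default_perturbation_keeps_dice_high(self):
        rng = np.random.default_rng(21)
        dices = []
        for i in range(12):
            radii = tuple(float(r) for r in rng.uniform(7.5, 10.5, 3))
            spec = PhantomSpec(radii_mm=radii, spiculation_amplitude=0.1,
                               seed=100 + i)
            _, mask = make_phantom(spec)
            reader_b = make_reader_pair(mask, perturbation_mm=0.5, seed=200 + i)
            dices.append(dice(mask.voxels, reader_b.voxels))
        assert min(dices) >= 0.85

    def test_volume_more_stable_than_roundness_across_readers(self):
        # segmentation noise perturbs the surface more than the bulk, so the
        # volume ICC should dominate the roundness ICC over a phantom set
        from radsurv.stability import icc_from_matrix

        rng = np.random.default_rng(5)
        vols, rounds = [], []
        for i in range(15):
            radii = tuple(float(r) for r in rng.uniform(7.0, 11.0, 3))
            spec = PhantomSpec(radii_mm=radii, spiculation_amplitude=0.12, seed=300 + i)
            _, mask = make_phantom(spec)
            reader_b = make_reader_pair(mask, perturbation_mm=0.7, seed=400 + i)
            fa = shape_features(mask)
            fb = shape_features(reader_b)
            vols.append((fa["volume"], fb["volume"]))
            rounds.append((fa["roundness"], fb["roundness"]))
        icc_vol = icc_from_matrix(np.array(vols))
        icc_round = icc_from_matrix(np.array(rounds))
        assert icc_vol > icc_round

    def test_destructive_perturbation_rejected(self):
        spec = PhantomSpec(shape=(16, 20, 20), spacing=(1, 1, 1), radii_mm=(3, 3, 3))
        _, mask = make_phantom(spec)
        with pytest.raises(ValidationError):
            make_reader_pair(mask, perturbation_mm=6.0, seed=1, min_dice=0.8)


class TestCohort:
    def test_determinism_per_seed(self):
        c1 = make_cohort(CohortSpec(seed=8))
        c2 = make_cohort(CohortSpec(seed=8))
        assert c1.data.equals(c2.data)

    def test_null_model_concordance_near_half(self):
        spec = CohortSpec(
            n=800, seed=2, coefficients={}, clone_block=False,
            age_log_hr_per_decade=0.0, diameter_log_hr_per_mm=0.0,
        )
        cohort = make_cohort(spec)
        times, events = cohort.survival()
        c = harrell_c(cohort.features("followup").iloc[:, 0], times, events)
        assert abs(c - 0.5) < 0.06

    def test_censoring_fraction_near_target(self):
        for target in (0.1, 0.3):
            cohort = make_cohort(CohortSpec(n=1000, seed=6, censoring_rate=target))
            observed = 1.0 - cohort.data["event"].mean()
            assert abs(observed - target) < 0.05

    def test_true_linear_predictor_is_prognostic(self):
        cohort = make_cohort(CohortSpec(n=500, seed=10))
        times, events = cohort.survival()
        c = harrell_c(np.array(cohort.data.attrs["true_linear_predictor"]), times, events)
        assert c > 0.6

    def test_responders_shrink_diameters(self):
        cohort = make_cohort(CohortSpec(n=400, seed=12))
        d = cohort.data
        resp = d["recist_response"] == "responder"
        shrink = 1.0 - d["followup_diameter"] / d["baseline_diameter"]
        assert (shrink[resp] >= 0.30 - 1e-9).all()
        assert shrink[resp].mean() > shrink[~resp].mean()

    def test_infeasible_censoring_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(censoring_rate=1.0)
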