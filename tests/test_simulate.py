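"""Synthetic-data generator: layouts, truth implanting, channels, cohorts."""

import inspect

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvseg import simulate
from cnvseg.preprocess import fit_plane, log2_ratio


class TestMakeLayout:
    def test_probe_count_is_floor_length_over_spacing(self, small_layout):
        assert len(small_layout) == 1000
        assert small_layout.chroms == ["1"]

    def test_default_spacing_matches_platform(self):
        sig = inspect.signature(simulate.make_layout)
        assert sig.parameters["spacing_bp"].default == 2509
        assert simulate.DEFAULT_SPACING_BP == 2509

    def test_same_seed_identical_layouts(self):
        a = simulate.make_layout(2, 100 * 2509, seed=7)
        b = simulate.make_layout(2, 100 * 2509, seed=7)
        pd.testing.assert_frame_equal(a.probes, b.probes)

    def test_different_seed_changes_grid_assignment(self):
        a = simulate.make_layout(1, 100 * 2509, seed=0)
        b = simulate.make_layout(1, 100 * 2509, seed=1)
        assert not a.probes[["grid_x", "grid_y"]].equals(b.probes[["grid_x", "grid_y"]])

    def test_grid_capacity_error(self):
        with pytest.raises(ValueError, match="grid"):
            simulate.make_layout(1, 100 * 2509, grid_dims=(5, 5), seed=0)

    def test_positions_strictly_increasing_and_grid_unique(self):
        lay = simulate.make_layout(3, 50 * 2509, seed=3)
        for chrom in lay.chroms:
            pos = lay.probes.loc[lay.probes["chrom"] == chrom, "pos"].to_numpy()
            assert np.all(np.diff(pos) > 0)
        assert not lay.probes.duplicated(["grid_x", "grid_y"]).any()


class TestImplantTruth:
    def test_empty_region_list_gives_zero_track(self, small_layout):
        t = simulate.implant_truth(small_layout, [])
        assert not t.shift.any()

    def test_region_shifts_exactly_the_overlapping_probes(self, small_layout):
        pos = small_layout.probes["pos"].to_numpy()
        # region spanning probes 100..150 (0-based), i.e. 51 probes
        t = simulate.implant_truth(
            small_layout, [("1", int(pos[100]), int(pos[150]), "gain")]
        )
        assert t.shifted_probe_count == 51
        assert np.all(t.shift[100:151] == simulate.DEFAULT_CLASS_SHIFTS["gain"])
        assert not t.shift[:100].any() and not t.shift[151:].any()

    def test_default_amplification_shift_clears_calling_bound(self):
        assert simulate.DEFAULT_CLASS_SHIFTS["amplification"] > 1.0
        assert simulate.DEFAULT_CLASS_SHIFTS["deletion"] < -1.0

    def test_overlapping_regions_rejected(self, small_layout):
        with pytest.raises(ValueError, match="overlap"):
            simulate.implant_truth(
                small_layout,
                [("1", 10_000, 50_000, "gain"), ("1", 40_000, 90_000, "loss")],
            )

    def test_shift_sign_must_match_class(self):
        with pytest.raises(ValueError, match="sign"):
            simulate.TruthRegion("1", 1, 10, "gain", -0.4)

    def test_truth_conservation(self, small_layout):
        """Shifted probe count equals the sum of per-region overlap counts."""
        pos = small_layout.probes["pos"].to_numpy()
        regions = [
            ("1", int(pos[10]), int(pos[40]), "gain"),
            ("1", int(pos[100]), int(pos[120]), "deletion"),
            ("1", int(pos[500]), int(pos[500]), "amplification"),
        ]
        t = simulate.implant_truth(small_layout, regions)
        per_region = [
            np.count_nonzero((pos >= r.start) & (pos <= r.end)) for r in t.regions
        ]
        assert t.shifted_probe_count == sum(per_region) == 31 + 21 + 1


class TestSimulateChannels:
    def test_noiseless_flat_array_has_zero_log2_ratio(self, small_layout):
        ch = simulate.simulate_channels(small_layout, noise_sd=0.0, seed=0)
        assert np.allclose(np.log2(ch.test / ch.ref), 0.0, atol=1e-12)

    def test_in_region_mean_within_clt_bound(self, small_layout):
        pos = small_layout.probes["pos"].to_numpy()
        t = simulate.implant_truth(
            small_layout,
            [("1", int(pos[0]), int(pos[499]), "amplification")],
        )
        ch = simulate.simulate_channels(small_layout, t, noise_sd=0.15, seed=42)
        mean = np.log2(ch.test / ch.ref)[:500].mean()
        assert abs(mean - 1.3) < 3 * 0.15 / np.sqrt(500)

    def test_gradient_recovered_by_plane_fit(self, small_layout):
        ch = simulate.simulate_channels(
            small_layout, noise_sd=0.0, gradient=(0.01, 0.0), seed=0
        )
        gx, gy, _ = fit_plane(
            small_layout.probes["grid_x"].to_numpy(float),
            small_layout.probes["grid_y"].to_numpy(float),
            np.log2(ch.test / ch.ref),
        )
        assert abs(gx - 0.01) < 1e-9 and abs(gy) < 1e-9

    def test_noise_calibration(self, small_layout):
        """Residuals about the truth shift behave like zero-mean noise."""
        pos = small_layout.probes["pos"].to_numpy()
        t = simulate.implant_truth(small_layout, [("1", int(pos[100]), int(pos[300]), "loss")])
        sd = 0.2
        ch = simulate.simulate_channels(small_layout, t, noise_sd=sd, seed=9)
        resid = np.log2(ch.test / ch.ref) - t.shift
        assert abs(resid.mean()) < 4 * sd / np.sqrt(len(resid))

    def test_determinism_and_positivity(self, small_layout):
        a = simulate.simulate_channels(small_layout, noise_sd=0.3, seed=5)
        b = simulate.simulate_channels(small_layout, noise_sd=0.3, seed=5)
        assert np.array_equal(a.test, b.test) and np.array_equal(a.ref, b.ref)
        assert np.all(a.test > 0) and np.all(a.ref > 0)

    def test_nonpositive_baseline_rejected(self, small_layout):
        with pytest.raises(ValueError, match="baseline"):
            simulate.simulate_channels(small_layout, baseline_intensity=0.0)


class TestSimulateCohort:
    @pytest.fixture
    def tiny_layout(self):
        return simulate.make_layout(1, 50 * 2509, seed=0)

    def _spec(self, layout, penetrance):
        pos = layout.probes["pos"].to_numpy()
        region = simulate.TruthRegion("1", int(pos[10]), int(pos[30]), "gain", 0.4)
        return [simulate.RecurrentRegionSpec(region=region, penetrance=penetrance)]

    def test_full_penetrance_present_in_all_samples(self, tiny_layout):
        _, truth = simulate.simulate_cohort(
            tiny_layout, self._spec(tiny_layout, 1.0),
            n_samples=20, private_cnv_rate=0.0, noise_sd=0.0, seed=0,
        )
        assert len(truth.carriage[0]) == 20
        assert all(len(truth.regions_by_sample[s]) == 1 for s in truth.sample_ids)

    def test_penetrance_within_binomial_interval(self, tiny_layout):
        n = 1000
        _, truth = simulate.simulate_cohort(
            tiny_layout, self._spec(tiny_layout, 0.6),
            n_samples=n, private_cnv_rate=0.0, noise_sd=0.0, seed=1,
        )
        lo, hi = stats.binom.interval(0.99, n, 0.6)
        assert lo <= len(truth.carriage[0]) <= hi

    def test_default_cohort_size_is_twenty(self):
        sig = inspect.signature(simulate.simulate_cohort)
        assert sig.parameters["n_samples"].default == 20

    def test_private_cnvs_do_not_overlap(self, tiny_layout):
        _, truth = simulate.simulate_cohort(
            tiny_layout, self._spec(tiny_layout, 0.5),
            n_samples=10, private_cnv_rate=1.0, private_probe_span=(3, 8),
            noise_sd=0.0, seed=2,
        )
        for sid in truth.sample_ids:
            regions = sorted(truth.regions_by_sample[sid], key=lambda r: (r.chrom, r.start))
            for a, b in zip(regions, regions[1:]):
                assert a.chrom != b.chrom or a.end < b.start


class TestSimulateQpcr:
    def test_three_replicates_per_sample_gene_row(self):
        t = simulate.simulate_qpcr(2.0, ct_sd=0.2, n_tumor=4, n_control=3, seed=0)
        assert len(t) == 7
        assert {"ct_rep1", "ct_rep2", "ct_rep3",
                "ref_ct_rep1", "ref_ct_rep2", "ref_ct_rep3"} <= set(t.columns)

    def test_zero_sd_fold_one_gives_identical_group_means(self):
        t = simulate.simulate_qpcr(1.0, ct_sd=0.0, n_tumor=3, n_control=3, seed=0)
        dct = t[["ct_rep1", "ct_rep2", "ct_rep3"]].mean(axis=1) - t[
            ["ref_ct_rep1", "ref_ct_rep2", "ref_ct_rep3"]
        ].mean(axis=1)
        expr = 2.0 ** (-dct)
        assert expr[t.group == "tumor"].mean() == pytest.approx(
            expr[t.group == "control"].mean(), abs=1e-12
        )

    def test_ct_values_within_instrument_range(self):
        t = simulate.simulate_qpcr(6.61, ct_sd=1.0, seed=3)
        reps = t[["ct_rep1", "ct_rep2", "ct_rep3",
                  "ref_ct_rep1", "ref_ct_rep2", "ref_ct_rep3"]].to_numpy()
        assert np.all(reps > 0) and np.all(reps < 45)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            simulate.simulate_qpcr(0.0)
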