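"""Ground-truth correctness of the synthetic data generators."""

import numpy as np
import pandas as pd
import pytest

import thromboquant as tq
from thromboquant.synth import InfeasiblePackingError
from skimage.measure import label as cc_label


class TestScene:
    def test_empty_scene(self):
        s = tq.gen_scene(0, seed=1)
        assert s.truth_coverage == 0.0
        assert s.truth_features == []
        assert not s.truth_mask.any()

    def test_single_square_coverage_is_area_ratio(self):
        s = tq.gen_scene(1, seed=3, areas=[10_000])
        assert s.truth_coverage == sum(s.truth_features) / s.truth_mask.size
        # placed rectangle area is the requested one up to integer rounding
        assert s.truth_coverage == pytest.approx(10_000 / 262_144, rel=0.05)

    def test_determinism_under_fixed_seed(self):
        a = tq.gen_scene(50, seed=7)
        b = tq.gen_scene(50, seed=7)
        assert np.array_equal(a.pixel_grid, b.pixel_grid)
        assert np.array_equal(a.truth_mask, b.truth_mask)
        assert a.truth_features == b.truth_features

    def test_truth_conservation_and_connectivity(self):
        s = tq.gen_scene(30, seed=11)
        assert s.truth_coverage == sum(s.truth_features) / s.truth_mask.size
        lab = cc_label(s.truth_mask, connectivity=2)
        assert sorted(np.bincount(lab.ravel())[1:]) == s.truth_features
        assert len(s.truth_features) == 30  # non-overlap mode keeps features apart

    def test_foreground_exceeds_background_before_noise(self):
        s = tq.gen_scene(10, seed=2, noise_sd=0.0)
        assert s.pixel_grid[s.truth_mask].min() > s.pixel_grid[~s.truth_mask].mean()

    def test_infeasible_packing_raises(self):
        with pytest.raises(InfeasiblePackingError, match="70%"):
            tq.gen_scene(30, seed=1, shape=(64, 64), areas=[200.0] * 30)
        with pytest.raises(InfeasiblePackingError):
            tq.gen_scene(40, seed=1, shape=(80, 80), areas=[140.0] * 40, max_tries=50)

    def test_aggregate_mode_records_merged_components(self):
        s = tq.gen_scene(60, seed=5, shape=(128, 128), overlap="aggregate")
        lab = cc_label(s.truth_mask, connectivity=2)
        assert sorted(np.bincount(lab.ravel())[1:]) == s.truth_features
        assert len(s.truth_features) <= 60

    def test_ellipse_shapes_supported(self):
        s = tq.gen_scene(5, seed=9, feature_shape="ellipse")
        assert len(s.truth_features) == 5


class TestSeries:
    def test_fully_stable_series_matches_scene(self):
        scene = tq.gen_scene(10, seed=4, shape=(128, 128), noise_sd=0.0)
        ser = tq.gen_series(scene, 1.0, seed=4, noise_sd=0.0)
        assert np.array_equal(ser.stable_mask, scene.truth_mask)
        for f in ser.frames:
            assert np.array_equal(f > 50, scene.truth_mask)

    def test_zero_stable_fraction_empty_mask(self):
        scene = tq.gen_scene(10, seed=4, shape=(128, 128))
        ser = tq.gen_series(scene, 0.0, seed=4)
        assert not ser.stable_mask.any()

    def test_half_stable_fraction_within_granularity(self):
        scene = tq.gen_scene(60, seed=6, shape=(512, 512), mean_area=60)
        ser = tq.gen_series(scene, 0.5, seed=6, noise_sd=0.0)
        total = scene.truth_mask.sum()
        # recount persistence directly from the emitted frames
        fg = np.stack([f > 50 for f in ser.frames])
        persisting = fg.all(axis=0).sum()
        assert persisting / total == pytest.approx(0.5, abs=0.02)
        assert persisting == ser.stable_mask.sum()

    def test_stable_mask_subset_of_every_frame(self):
        scene = tq.gen_scene(20, seed=8, shape=(128, 128))
        ser = tq.gen_series(scene, 0.4, seed=8, noise_sd=0.0)
        for f in ser.frames:
            assert (ser.stable_mask <= (f > 50)).all()

    def test_frame_count_spans_duration(self):
        scene = tq.gen_scene(5, seed=1, shape=(64, 64))
        ser = tq.gen_series(scene, 0.5, seed=1, duration_s=60, interval_s=2)
        assert len(ser.frames) * ser.frame_interval == 60

    def test_bad_duration_rejected(self):
        scene = tq.gen_scene(5, seed=1, shape=(64, 64))
        with pytest.raises(ValueError, match="multiple"):
            tq.gen_series(scene, 0.5, seed=1, duration_s=61, interval_s=2)


class TestStack:
    def test_volume_equals_mean_height(self):
        st = tq.gen_stack(seed=3)
        assert st.truth_volume_per_area == pytest.approx(st.truth_height_map.mean())

    def test_columns_contiguous_from_bottom(self):
        st = tq.gen_stack(seed=3, noise_sd=0.0)
        occ = np.stack([s > 50 for s in st.slices])
        h = occ.sum(axis=0)
        for i in range(occ.shape[0]):
            assert np.array_equal(occ[i], h > i)
        assert np.allclose(h * st.slice_spacing, st.truth_height_map)


class TestParameterMatrix:
    def test_zero_noise_rows_equal_type_means(self):
        truth = tq.planted_matrix_truth(seed=5, n_surfaces=12, noise_sd=0.0)
        means, _ = tq.gen_parameter_matrix(truth)
        for sid, t in zip(truth.surface_ids, truth.true_type):
            assert np.allclose(means.loc[sid], truth.type_mean_vectors.loc[t])

    def test_reproducible_table(self):
        t = tq.planted_matrix_truth(seed=5)
        m1, r1 = tq.gen_parameter_matrix(t)
        m2, r2 = tq.gen_parameter_matrix(t)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_separation_dominates_noise(self):
        """ANOVA-style decomposition: between-type variance well above within."""
        truth = tq.planted_matrix_truth(seed=5, separation=4.0)
        means, _ = tq.gen_parameter_matrix(truth)
        overall = means.mean(axis=1).to_numpy()
        types = truth.true_type
        grand = overall.mean()
        between = sum(
            (types == t).sum() * (overall[types == t].mean() - grand) ** 2
            for t in (1, 2, 3)
        ) / (len(overall) - 1)
        within = sum(
            ((overall[types == t] - overall[types == t].mean()) ** 2).sum()
            for t in (1, 2, 3)
        ) / (len(overall) - 3)
        assert between / within > 4

    def test_type_means_ordered_by_activation(self):
        with pytest.raises(ValueError, match="increasing"):
            tq.PlantedMatrixTruth(
                surface_ids=["a", "b"],
                true_type=np.array([1, 2]),
                type_mean_vectors=pd.DataFrame(
                    [[5.0, 5.0], [1.0, 1.0], [3.0, 3.0]], index=[1, 2, 3]
                ),
                noise_sd=np.array([1.0, 1.0]),
                n_replicates=2,
                seed=0,
            )


class TestReceptorDesign:
    def test_zero_beta_constant_response(self):
        truth = tq.PlantedReceptorTruth(
            assignment_rows=None,
            beta_true=np.array([2.0] + [0.0] * 9),
            noise_sd=0.0,
            seed=1,
        )
        d = tq.gen_receptor_design(truth, 20)
        assert np.all(d.response == 2.0)

    def test_identity_design_recovers_beta_differences(self):
        A = pd.DataFrame(np.eye(9, dtype=int), columns=list(tq.RECEPTORS))
        beta = np.array([2.0, 0.3, 0.2, 0.4, 0.1, -0.1, 0.35, 0.25, -0.05, 0.05])
        truth = tq.PlantedReceptorTruth(assignment_rows=A, beta_true=beta, noise_sd=0.0, seed=1)
        d = tq.gen_receptor_design(truth)
        assert np.allclose(d.response - beta[0], beta[1:])

    def test_response_reconstructible_from_stored_pieces(self):
        truth = tq.planted_receptor_truth(seed=9, noise_sd=0.1)
        d = tq.gen_receptor_design(truth, 52)
        rebuilt = np.clip(
            truth.beta_true[0] + d.assignment.to_numpy() @ truth.beta_true[1:] + d.noise,
            1.0,
            3.0,
        )
        assert np.array_equal(rebuilt, d.response)

    def test_every_surface_engages_a_receptor(self):
        d = tq.gen_receptor_design(tq.planted_receptor_truth(seed=2), 52)
        assert (d.assignment.sum(axis=1) >= 1).all()
        bad = pd.DataFrame(np.zeros((3, 9), dtype=int), columns=list(tq.RECEPTORS))
        with pytest.raises(ValueError, match="at least one receptor"):
            tq.PlantedReceptorTruth(
                assignment_rows=bad,
                beta_true=np.zeros(10),
                noise_sd=0.0,
                seed=0,
            )


class TestCohort:
    def test_degenerate_cohort_patient_equals_controls(self):
        truth = tq.cohort_truth(seed=1, inter_sd=0.0, intra_sd=0.0)
        controls, patient, _ = tq.gen_cohort(truth)
        pgrid = patient.pivot(index="surface", columns="parameter", values="value")
        for _, sub in controls.groupby(["subject", "day"]):
            grid = sub.pivot(index="surface", columns="parameter", values="value")
            assert np.allclose(grid.reindex_like(pgrid), pgrid)

    def test_planted_shift_is_exact_in_inter_sd_units(self):
        truth = tq.cohort_truth(seed=1)
        shift = truth.patient_shift.copy()
        shift.iloc[2, 3] = 3.0
        truth.patient_shift = shift
        _, patient, _ = tq.gen_cohort(truth)
        grid = patient.pivot(index="surface", columns="parameter", values="value")
        grid = grid.reindex(index=truth.cell_means.index, columns=truth.cell_means.columns)
        delta = (grid - truth.cell_means) / truth.inter_sd
        assert delta.iloc[2, 3] == pytest.approx(3.0)
        assert np.allclose(delta.to_numpy().ravel()[np.arange(delta.size) != 2 * delta.shape[1] + 3], 0.0)

    def test_variance_components_recoverable_by_moments(self):
        """Method-of-moments decomposition converges to the generating sds."""
        truth = tq.cohort_truth(seed=12, n_controls=50, n_surfaces=4)
        controls, _, _ = tq.gen_cohort(truth)
        param = controls["parameter"].iloc[0]
        intra_vars, between_vars = [], []
        for _s, piv in controls[controls["parameter"] == param].groupby("surface"):
            by_subj = piv.groupby("subject")["value"]
            iv = by_subj.var(ddof=1).mean()
            intra_vars.append(iv)
            between_vars.append(by_subj.mean().var(ddof=1) - iv / truth.n_days)
        assert np.sqrt(np.mean(intra_vars)) == pytest.approx(truth.intra_sd, rel=0.10)
        assert np.sqrt(np.mean(between_vars)) == pytest.approx(truth.inter_sd, rel=0.10)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            tq.cohort_truth(seed=1, inter_sd=-1.0)
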