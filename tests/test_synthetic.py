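"""Synthetic cohort generator: masks, label maps, rendering, survival."""

import numpy as np
import pytest

from tumorshape import (
    NON_MALIGNANT,
    TUMOR,
    WHITE,
    CohortSpec,
    ShapeSpec,
    connected_components,
    extract_tumor_regions,
    find_holes,
    gen_label_map,
    gen_survival,
    gen_tumor_mask,
    is_white_patch,
    logrank,
    region_geometry,
    render_patch_set,
    render_slide,
    segment_tissue_regions,
    simulate_cohort,
)
from tumorshape.synthetic import DegenerateShapeError


class TestGenTumorMask:
    def test_smooth_disk_is_simply_connected(self):
        mask = gen_tumor_mask(ShapeSpec(base_radius=6, roughness=0.0))
        assert connected_components(mask, 8)[1] == 1
        assert find_holes(mask).n_holes == 0

    def test_same_seed_reproduces_identical_mask(self):
        spec = ShapeSpec(base_radius=7, roughness=0.5, n_holes=2,
                         n_satellites=2, seed=11)
        assert np.array_equal(gen_tumor_mask(spec), gen_tumor_mask(spec))

    def test_different_seeds_differ(self):
        a = gen_tumor_mask(ShapeSpec(base_radius=7, roughness=0.5, seed=1))
        b = gen_tumor_mask(ShapeSpec(base_radius=7, roughness=0.5, seed=2))
        assert a.shape != b.shape or not np.array_equal(a, b)

    def test_requested_holes_are_punched(self):
        mask = gen_tumor_mask(ShapeSpec(base_radius=8, n_holes=3, seed=4))
        assert find_holes(mask).n_holes == 3

    def test_satellites_are_disjoint_single_cells(self):
        spec = ShapeSpec(base_radius=6, n_satellites=3, seed=5)
        mask = gen_tumor_mask(spec)
        _, n = connected_components(mask, 8)
        assert n == 4
        sizes = sorted(
            np.bincount(connected_components(mask, 8)[0].ravel())[1:]
        )
        assert sizes[:3] == [1, 1, 1]

    def test_too_small_for_holes_raises(self):
        with pytest.raises(DegenerateShapeError):
            gen_tumor_mask(ShapeSpec(base_radius=2, n_holes=30))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ShapeSpec(base_radius=1)
        with pytest.raises(ValueError):
            ShapeSpec(base_radius=5, roughness=-0.1)
        with pytest.raises(ValueError):
            ShapeSpec(base_radius=5, aspect=0.5)

    def test_roughness_raises_boundary_irregularity(self):
        """Mean crack perimeter^2/area grows with the perturbation
        amplitude (20 seeds per level)."""
        def mean_pa(rough):
            vals = []
            for seed in range(20):
                mask = gen_tumor_mask(
                    ShapeSpec(base_radius=8, roughness=rough, seed=seed)
                )
                vals.append(region_geometry(mask).pa_ratio)
            return np.mean(vals)

        assert mean_pa(0.0) < mean_pa(0.5)


class TestGenLabelMap:
    def test_single_disk_yields_one_tissue_one_tumor_region(self):
        lm, truth = gen_label_map([ShapeSpec(base_radius=6, seed=1)])
        tissues = segment_tissue_regions(lm)
        assert len(tissues) == 1
        regions = extract_tumor_regions(tissues[0], lm)
        assert len(regions) == 1
        assert truth.n_tumor_regions == [1]

    def test_satellites_recovered_downstream(self):
        lm, truth = gen_label_map(
            [ShapeSpec(base_radius=7, n_satellites=3, seed=2)]
        )
        tissues = segment_tissue_regions(lm)
        regions = extract_tumor_regions(tissues[0], lm)
        assert len(regions) == 4 == truth.n_tumor_regions[0]

    def test_empty_spec_list_gives_all_white(self):
        lm, truth = gen_label_map([], canvas=(6, 9))
        assert lm.shape == (6, 9) and (lm == WHITE).all()
        assert truth.n_samples == 0

    def test_two_samples_stay_disjoint(self):
        lm, truth = gen_label_map(
            [ShapeSpec(base_radius=5, seed=3), ShapeSpec(base_radius=5, seed=4)]
        )
        assert len(segment_tissue_regions(lm)) == 2

    def test_overlapping_positions_rejected(self):
        specs = [ShapeSpec(base_radius=5, seed=3), ShapeSpec(base_radius=5, seed=4)]
        with pytest.raises(ValueError, match="overlap"):
            gen_label_map(specs, canvas=(40, 40),
                          positions=[(2, 2), (3, 3)])

    def test_canvas_too_small_rejected(self):
        with pytest.raises(ValueError, match="margin|fit"):
            gen_label_map([ShapeSpec(base_radius=8)], canvas=(10, 10))

    def test_holes_are_non_malignant_tissue(self):
        lm, _ = gen_label_map([ShapeSpec(base_radius=8, n_holes=2, seed=7)])
        tissues = segment_tissue_regions(lm)
        region = extract_tumor_regions(tissues[0], lm)[0]
        holes = find_holes(region.mask)
        assert holes.n_holes == 2
        assert (lm[holes.mask] == NON_MALIGNANT).all()


class TestRenderSlide:
    def test_white_cells_exceed_white_threshold(self):
        lm = np.full((2, 2), WHITE, dtype=np.int8)
        img = render_slide(lm, patch_size=16, seed=0)
        assert is_white_patch(img[:16, :16], threshold=200)

    def test_tumor_cells_are_dark(self):
        lm = np.full((1, 1), TUMOR, dtype=np.int8)
        img = render_slide(lm, patch_size=16, seed=0)
        assert not is_white_patch(img, threshold=200)

    def test_bit_identical_for_same_seed(self):
        lm, _ = gen_label_map([ShapeSpec(base_radius=4, seed=1)])
        assert np.array_equal(render_slide(lm, 8, seed=3),
                              render_slide(lm, 8, seed=3))
        assert not np.array_equal(render_slide(lm, 8, seed=3),
                                  render_slide(lm, 8, seed=4))

    def test_tumor_and_non_malignant_are_separable(self):
        """Nearest-centroid on (mean intensity, blue-red balance) separates
        the two tissue textures with accuracy > 0.9 (100 patches each)."""
        patches, labels = render_patch_set(100, patch_size=16, seed=2)
        keep = labels != WHITE
        patches, labels = patches[keep], labels[keep]
        feats = np.column_stack([
            patches.mean(axis=(1, 2, 3)),
            patches[..., 2].mean(axis=(1, 2)) - patches[..., 0].mean(axis=(1, 2)),
        ])
        centroids = {c: feats[labels == c].mean(axis=0) for c in (0, 1)}
        pred = np.array([
            min(centroids, key=lambda c: np.sum((f - centroids[c]) ** 2))
            for f in feats
        ])
        assert (pred == labels).mean() > 0.9

    def test_patch_size_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            render_slide(np.zeros((2, 2), dtype=np.int8), patch_size=4)


class TestGenSurvival:
    def test_zero_censoring_means_all_events(self):
        spec = CohortSpec(n_patients=50, censor_rate=0.0, seed=1,
                          beta={"f": 0.5})
        x = np.random.default_rng(0).normal(size=(50, 1))
        time, event = gen_survival(x, spec)
        assert (event == 1).all() and (time > 0).all()

    def test_censor_rate_is_hit_in_expectation(self):
        spec = CohortSpec(n_patients=4000, censor_rate=0.4, seed=2,
                          beta={"f": 0.5})
        x = np.random.default_rng(1).normal(size=(4000, 1))
        _, event = gen_survival(x, spec)
        assert abs((event == 0).mean() - 0.4) < 0.04

    def test_feature_beta_mismatch_raises(self):
        spec = CohortSpec(n_patients=10, beta={"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError, match="columns"):
            gen_survival(np.zeros((10, 3)), spec)

    def test_reproducible_by_seed(self):
        spec = CohortSpec(n_patients=30, censor_rate=0.3, seed=9,
                          beta={"f": 0.3})
        x = np.random.default_rng(2).normal(size=(30, 1))
        t1, e1 = gen_survival(x, spec)
        t2, e2 = gen_survival(x, spec)
        assert np.array_equal(t1, t2) and np.array_equal(e1, e2)

    def test_null_beta_gives_uniform_logrank_type_I(self):
        """With beta = 0 a median split of the feature is pure noise: the
        log-rank test should reject at ~ the nominal 5% level (200 reps)."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            x = rng.normal(size=(60, 1))
            spec = CohortSpec(n_patients=60, censor_rate=0.2,
                              seed=20_000 + seed, beta={"f": 0.0},
                              baseline_hazard=1e-3)
            time, event = gen_survival(x, spec)
            groups = np.where(x[:, 0] > np.median(x[:, 0]), "hi", "lo")
            if event[groups == "hi"].sum() and event[groups == "lo"].sum():
                _, _, p = logrank(groups, time, event)
                rejections += p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_true_hazard_ratio_recovered_between_risk_halves(self):
        """Empirical event-rate ratio between high and low true-risk halves
        approaches exp(beta * delta-x) at n=1000 (within 20%)."""
        n = 1000
        rng = np.random.default_rng(3)
        x = rng.choice([0.0, 1.0], size=(n, 1))  # two risk groups
        beta = 0.8
        spec = CohortSpec(n_patients=n, censor_rate=0.0, seed=4,
                          beta={"f": beta}, baseline_hazard=1e-3)
        time, event = gen_survival(x, spec)
        hi = x[:, 0] == 1
        # with exponential times and no censoring, hazard ratio = ratio of
        # mean survival times inverted
        hr_emp = time[~hi].mean() / time[hi].mean()
        assert abs(hr_emp - np.exp(beta)) / np.exp(beta) < 0.2


class TestSimulateCohort:
    def test_shapes_and_columns(self):
        feats, clin, lms, specs = simulate_cohort(
            CohortSpec(n_patients=12, seed=5)
        )
        assert len(feats) == 12 and len(clin) == 12 and len(lms) == 12
        assert list(clin.columns[:3]) == ["patient_id", "time_days", "event"]
        assert {"age", "sex", "smoking", "stage"} <= set(clin.columns)
        assert (clin["time_days"] > 0).all()

    def test_deterministic_in_seed(self):
        a_f, a_c, _, _ = simulate_cohort(CohortSpec(n_patients=8, seed=6))
        b_f, b_c, _, _ = simulate_cohort(CohortSpec(n_patients=8, seed=6))
        assert a_f.equals(b_f) and a_c.equals(b_c)
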