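"""Gray/white classification, deformation fields, atlas labels."""

import numpy as np
import pytest
from scipy import stats

from electrolocate import (
    AtlasVolume,
    Electrode,
    LabelConfig,
    Volume,
    assign_atlas_labels,
    classify_gray_white,
    rank_sum_p,
    sphere_voxels,
    warp_atlas_to_patient,
    warp_points,
)
from electrolocate.labeling import matching_labels
from electrolocate.phantom import make_affine_fields

from .oracles import exact_ranksum_pvalue


def _grid(n=40, voxel=0.5):
    affine = np.eye(4) * voxel
    affine[3, 3] = 1.0
    affine[:3, 3] = -voxel * (n - 1) / 2.0
    return Volume(np.zeros((n, n, n)), affine)


def _identity_field(shape=(20, 20, 20), voxel=1.0):
    affine = np.eye(4) * voxel
    affine[3, 3] = 1.0
    fwd, _ = make_affine_fields(shape, affine, np.eye(4))
    return fwd


class TestSphereVoxels:
    def test_matches_exhaustive_scan(self, rng):
        grid = _grid(voxel=0.4)
        center = rng.uniform(-2, 2, size=3)
        got = sphere_voxels(center, 1.3, grid)
        # brute force over the whole grid
        idx = np.argwhere(np.ones(grid.shape, dtype=bool))
        world = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
        want = idx[np.linalg.norm(world - center, axis=1) <= 1.3]
        assert np.array_equal(np.sort(got, axis=0), np.sort(want, axis=0))

    def test_tiny_radius_on_voxel_center_gives_one_voxel(self):
        grid = _grid(n=21, voxel=1.0)
        center = grid.index_to_world([10, 10, 10])
        got = sphere_voxels(center, 0.1, grid)
        assert len(got) == 1
        assert np.array_equal(got[0], [10, 10, 10])

    def test_volume_approximates_analytic_sphere(self):
        grid = _grid(voxel=0.4)
        got = sphere_voxels(np.zeros(3), 1.3, grid)
        vol = len(got) * grid.voxel_volume_mm3
        analytic = 4 / 3 * np.pi * 1.3**3
        assert abs(vol - analytic) / analytic < 0.15

    def test_sphere_outside_grid_is_empty(self):
        grid = _grid(n=10, voxel=1.0)
        assert len(sphere_voxels([100.0, 0, 0], 1.3, grid)) == 0


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        assert rank_sum_p(x, x.copy()) == 1.0

    def test_complete_separation_is_significant(self):
        assert rank_sum_p([0.9] * 20, [0.1] * 20) < 0.001

    def test_symmetry(self, rng):
        x, y = rng.uniform(size=8), rng.uniform(size=6)
        assert rank_sum_p(x, y) == rank_sum_p(y, x)

    def test_exact_path_matches_scipy_exact(self, rng):
        """Tie-free small samples: compare with scipy's exact
        Mann-Whitney distribution (an independent implementation)."""
        for _ in range(5):
            x = rng.normal(size=7)
            y = rng.normal(size=8)
            ours = rank_sum_p(x, y)
            scipy_p = stats.mannwhitneyu(x, y, method="exact").pvalue
            assert abs(ours - scipy_p) < 1e-12

    def test_exact_path_matches_enumeration_with_ties(self, rng):
        x = np.array([0.1, 0.2, 0.2, 0.5])
        y = np.array([0.2, 0.6, 0.6, 0.9])
        assert abs(rank_sum_p(x, y) - exact_ranksum_pvalue(x, y)) < 1e-12

    def test_approximation_close_to_exact_beyond_cutoff(self, rng):
        """The tie-corrected normal approximation (n > 10 path) stays
        near the exact enumeration at moderate sizes."""
        x = rng.normal(size=11)
        y = rng.normal(size=7)
        approx = rank_sum_p(x, y)
        scipy_exact = stats.mannwhitneyu(x, y, method="exact").pvalue
        assert abs(approx - scipy_exact) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_p([], [1.0])


class TestClassifyGrayWhite:
    def _maps(self, gm_val, wm_val, n=24, voxel=0.5):
        grid = _grid(n=n, voxel=voxel)
        gm = Volume(np.full(grid.shape, gm_val), grid.affine)
        wm = Volume(np.full(grid.shape, wm_val), grid.affine)
        return gm, wm

    def test_low_probability_everywhere_is_unknown(self):
        gm, wm = self._maps(0.05, 0.05)
        e = Electrode(id=0, centroid_mm=np.zeros(3))
        assert classify_gray_white(e, gm, wm) == "unknown"

    def test_nonsignificant_defaults_to_gray(self, rng):
        grid = _grid(n=24, voxel=0.5)
        # overlapping noisy maps with equal medians
        gm = Volume(rng.uniform(0.3, 0.7, grid.shape), grid.affine)
        wm = Volume(rng.uniform(0.3, 0.7, grid.shape), grid.affine)
        e = Electrode(id=0, centroid_mm=np.zeros(3))
        assert classify_gray_white(e, gm, wm) == "gray"

    def test_separated_maps_classify_accordingly(self):
        gm, wm = self._maps(0.02, 0.95)
        e = Electrode(id=0, centroid_mm=np.zeros(3))
        assert classify_gray_white(e, gm, wm) == "white"
        gm2, wm2 = self._maps(0.95, 0.02)
        assert classify_gray_white(e, gm2, wm2) == "gray"

    def test_sphere_outside_maps_warns_unknown(self):
        gm, wm = self._maps(0.9, 0.1, n=10, voxel=0.5)
        e = Electrode(id=0, centroid_mm=np.array([500.0, 0, 0]))
        with pytest.warns(UserWarning):
            assert classify_gray_white(e, gm, wm) == "unknown"

    def test_phantom_interior_contacts_recovered(self, bundle, rng):
        """Random placements >= 2 mm inside a tissue shell classify to
        the planted class."""
        from electrolocate.phantom import _tissue_class_of

        spec = bundle.spec
        radii = np.asarray(spec.brain_radii_mm)
        n_checked = 0
        while n_checked < 60:
            p = rng.uniform(-1, 1, size=3) * radii
            rho = float(np.sqrt(((p / radii) ** 2).sum()))
            planted = _tissue_class_of(rho, spec)
            if planted in ("boundary",) or rho > 1.3:
                continue
            e = Electrode(id=0, centroid_mm=p)
            got = classify_gray_white(e, bundle.gm, bundle.wm)
            assert got == planted, (p, rho)
            n_checked += 1


class TestWarpPoints:
    def test_identity_field(self, rng):
        field = _identity_field()
        pts = rng.uniform(2, 15, size=(20, 3))
        assert np.allclose(warp_points(pts, field), pts, atol=1e-12)

    def test_constant_translation_field(self, rng):
        affine = np.eye(4)
        shift = np.eye(4)
        shift[:3, 3] = [5.0, 0, 0]
        fwd, _ = make_affine_fields((15, 15, 15), affine, shift)
        pts = rng.uniform(2, 12, size=(10, 3))
        assert np.allclose(warp_points(pts, fwd), pts + [5, 0, 0], atol=1e-9)

    def test_affine_field_closed_form_and_inverse(self, bundle, rng):
        A = bundle.truth.mni_affine
        radii = np.asarray(bundle.spec.brain_radii_mm)
        pts = rng.uniform(-0.7, 0.7, size=(100, 3)) * radii
        mni = warp_points(pts, bundle.forward)
        want = pts @ A[:3, :3].T + A[:3, 3]
        assert np.abs(mni - want).max() < 1e-6
        back = warp_points(mni, bundle.inverse)
        assert np.abs(back - pts).max() < 1e-5

    def test_outside_domain_rejected(self):
        field = _identity_field(shape=(10, 10, 10))
        with pytest.raises(ValueError, match="outside"):
            warp_points([[50.0, 0, 0]], field)


def _single_label_atlas(n=30, voxel=1.0, label=3):
    affine = np.eye(4) * voxel
    affine[3, 3] = 1.0
    affine[:3, 3] = -voxel * (n - 1) / 2.0
    data = np.full((n, n, n), label, dtype=np.int32)
    return AtlasVolume(Volume(data, affine, "mni"), {label: "everything"}, name="uni")


def _centered_identity_field(n=30, voxel=1.0):
    affine = np.eye(4) * voxel
    affine[3, 3] = 1.0
    affine[:3, 3] = -voxel * (n - 1) / 2.0
    fwd, _ = make_affine_fields((n, n, n), affine, np.eye(4))
    return fwd


class TestAssignAtlasLabels:
    def test_single_label_atlas(self):
        atlas = _single_label_atlas()
        field = _centered_identity_field()
        e = Electrode(id=0, centroid_mm=np.zeros(3))
        modal, probs = assign_atlas_labels(e, atlas, field)
        assert modal == "everything"
        assert probs == [("everything", 1.0)]

    def test_planar_boundary_split_counts_voxels(self):
        """A contact sphere straddling a plane picks the majority side
        and reports both fractions."""
        n = 40
        affine = np.eye(4) * 0.5
        affine[3, 3] = 1.0
        affine[:3, 3] = -0.5 * (n - 1) / 2.0
        data = np.where(
            np.arange(n)[:, None, None] * 0.5 + affine[0, 3] > 0.0, 2, 1
        ).astype(np.int32) * np.ones((n, n, n), dtype=np.int32)
        atlas = AtlasVolume(Volume(data, affine, "mni"), {1: "left", 2: "right"})
        fwd, _ = make_affine_fields((n, n, n), affine, np.eye(4))
        e = Electrode(id=0, centroid_mm=np.array([0.3, 0.0, 0.0]))
        modal, probs = assign_atlas_labels(e, atlas, fwd)
        frac = dict(probs)
        # center 0.3 mm right of the boundary: right-side majority both
        # for the modal (1.3-mm sphere) and the probabilistic (10-mm
        # sphere) labels; fractions checked against a voxel-count oracle
        grid = Volume(np.zeros((n, n, n)), affine)
        vox = sphere_voxels(e.centroid_mm, 10.0, grid)
        world = vox @ affine[:3, :3].T + affine[:3, 3]
        want_right = (world[:, 0] > 0.0).mean()
        assert want_right > 0.5
        assert modal == "right"
        assert np.isclose(frac["right"], want_right)
        assert np.isclose(frac["left"] + frac["right"], 1.0)

    def test_small_region_stored_but_excluded_from_matching(self):
        """A region holding ~4% of the 1-cm sphere stays in the stored
        list but is dropped by the 5% matching filter."""
        n = 60
        affine = np.eye(4) * 0.8
        affine[3, 3] = 1.0
        affine[:3, 3] = -0.8 * (n - 1) / 2.0
        data = np.ones((n, n, n), dtype=np.int32)
        # small slab: fraction of the 10-mm sphere below 5%
        i0 = int(round((9.0 - affine[0, 3]) / 0.8))
        data[i0:, :, :] = 2
        atlas = AtlasVolume(Volume(data, affine, "mni"), {1: "big", 2: "sliver"})
        fwd, _ = make_affine_fields((n, n, n), affine, np.eye(4))
        e = Electrode(id=0, centroid_mm=np.zeros(3))
        modal, probs = assign_atlas_labels(e, atlas, fwd)
        frac = dict(probs)
        assert "sliver" in frac and 0.0 < frac["sliver"] < 0.05
        kept = [name for name, _ in matching_labels(probs)]
        assert kept == ["big"]

    def test_even_split_tie_breaks_to_lower_index(self):
        n = 21
        affine = np.eye(4)
        affine[:3, 3] = -(n - 1) / 2.0
        data = np.where(np.arange(n)[:, None, None] + affine[0, 3] > 0, 5, 2).astype(
            np.int32
        ) * np.ones((n, n, n), dtype=np.int32)
        atlas = AtlasVolume(Volume(data, affine, "mni"), {2: "low", 5: "high"})
        fwd, _ = make_affine_fields((n, n, n), affine, np.eye(4))
        # center exactly on a voxel plane: sphere splits evenly
        e = Electrode(id=0, centroid_mm=np.array([0.5, 0.0, 0.0]))
        modal, _ = assign_atlas_labels(e, atlas, fwd)
        assert modal == "low"

    def test_identity_field_conserves_pointwise_label(self, bundle, rng):
        """With the phantom's affine field, interior contacts reproduce
        the octant planted in the truth record."""
        for c in bundle.truth.contacts:
            if not c["atlas_interior"]:
                continue
            e = Electrode(id=0, centroid_mm=np.array(c["position_mm"]))
            modal, _ = assign_atlas_labels(e, bundle.atlas, bundle.forward)
            assert modal == c["atlas_label"]


class TestWarpAtlas:
    def test_identity_field_reproduces_atlas(self):
        atlas = _single_label_atlas(n=16)
        fwd = _centered_identity_field(n=16)
        grid = Volume(np.zeros((16, 16, 16)), atlas.labels.affine)
        out = warp_atlas_to_patient(atlas, fwd, grid)
        assert np.array_equal(out.data, atlas.labels.data)

    def test_translation_field_shifts_labels(self):
        n = 20
        affine = np.eye(4)
        data = np.zeros((n, n, n), dtype=np.int32)
        data[10:, :, :] = 7
        atlas = AtlasVolume(Volume(data, affine, "mni"), {7: "block"})
        shift = np.eye(4)
        shift[:3, 3] = [3.0, 0, 0]
        fwd, _ = make_affine_fields((n, n, n), affine, shift)
        grid = Volume(np.zeros((n, n, n)), affine)
        out = warp_atlas_to_patient(atlas, fwd, grid)
        # patient voxel i samples atlas at i+3: boundary moves to index 7
        assert out.data[7, 0, 0] == 7
        assert out.data[6, 0, 0] == 0

    def test_dual_path_modal_consistency_on_phantom(self, bundle):
        """Per-contact modal labels agree between direct warping of the
        sphere voxels and lookup in the atlas pre-warped to patient
        space, for >= 95% of contacts."""
        grid = Volume(np.zeros(bundle.ct.shape), bundle.ct.affine)
        lw = warp_atlas_to_patient(bundle.atlas, bundle.forward, grid)
        agree = 0
        contacts = bundle.truth.contacts
        for c in contacts:
            e = Electrode(id=0, centroid_mm=np.array(c["position_mm"]))
            modal, _ = assign_atlas_labels(e, bundle.atlas, bundle.forward, grid=grid)
            vox = sphere_voxels(e.centroid_mm, 1.3, lw)
            labels = np.asarray(lw.data)[vox[:, 0], vox[:, 1], vox[:, 2]]
            vals, counts = np.unique(labels, return_counts=True)
            lw_modal = bundle.atlas.label_name(int(vals[counts == counts.max()].min()))
            agree += modal == lw_modal
        assert agree / len(contacts) >= 0.95


class TestProbLabelInvariants:
    def test_fractions_sum_to_one(self, bundle):
        e = Electrode(id=0, centroid_mm=np.array(bundle.truth.contacts[0]["position_mm"]))
        _, probs = assign_atlas_labels(e, bundle.atlas, bundle.forward)
        fracs = [f for _, f in probs]
        assert np.isclose(sum(fracs), 1.0)
        assert all(0 <= f <= 1 for f in fracs)
        assert fracs == sorted(fracs, reverse=True)


class TestConfigValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            LabelConfig(sphere_radius_mm=-1.0)
        with pytest.raises(ValueError):
            LabelConfig(prob_exclude_frac=1.5)

    def test_atlas_requires_table_entries(self):
        data = np.array([[[1, 4]]], dtype=np.int32)
        with pytest.raises(ValueError, match="table"):
            AtlasVolume(Volume(data, np.eye(4), "mni"), {1: "a"})
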