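import numpy as np
import pytest

from planqa.core import sample_trilinear
from planqa.fiducials import fiducial_qa
from planqa.gamma import compute_gamma
from planqa.synthetic import (
    BeamSpec,
    PerturbationSpec,
    PhantomSpec,
    apply_rigid,
    hu_to_density,
    jitter_fiducials,
    make_case,
    make_dose_pair,
    make_phantom,
    make_pseudo_ct,
    random_rigid_transform,
    smooth_random_dose_pair,
    toy_dose_engine,
)

from conftest import small_beams, small_phantom_spec


def water_phantom(radius=80.0, length=120.0, spacing=2.0, seed=0):
    """All-water body: every structure HU forced to 0."""
    spec = PhantomSpec(
        body_semi_axes_mm=(radius, radius),
        body_length_mm=length,
        femoral_hu=0.0,
        ring_hu=0.0,
        prostate_hu=0.0,
        spacing_mm=spacing,
        seed=seed,
    )
    return make_phantom(spec)


class TestMakePhantom:
    def test_body_volume_matches_analytic(self):
        ph = make_phantom(PhantomSpec(seed=3))
        a, b = ph.geometry["semi_axes_mm"]
        length = ph.geometry["length_mm"]
        voxel_vol = float(np.prod(ph.ct.spacing))
        got = ph.masks["body"].count * voxel_vol
        want = np.pi * a * b * length
        assert got == pytest.approx(want, rel=0.02)

    def test_determinism(self):
        spec = small_phantom_spec(seed=9)
        p1 = make_phantom(spec)
        p2 = make_phantom(spec)
        assert np.array_equal(p1.ct.values, p2.ct.values)
        assert np.array_equal(p1.fiducials_ct.points, p2.fiducials_ct.points)

    def test_seeds_differ(self):
        p1 = make_phantom(small_phantom_spec(seed=1))
        p2 = make_phantom(small_phantom_spec(seed=2))
        assert not np.array_equal(p1.ct.values, p2.ct.values)

    def test_fiducials_well_separated(self):
        for seed in range(5):
            ph = make_phantom(small_phantom_spec(seed=seed))
            pts = ph.fiducials_ct.points
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 5.0

    def test_structures_inside_body(self, phantom):
        body = phantom.masks["body"].values
        assert not np.any(phantom.masks["bone"].values & ~body)
        assert not np.any(phantom.masks["prostate"].values & ~body)

    def test_isocenter_in_prostate(self, phantom):
        assert sample_trilinear(phantom.ct, phantom.isocenter) == pytest.approx(
            30.0, abs=1.0
        )

    def test_rectal_cavity_option(self):
        ph = make_phantom(small_phantom_spec(seed=1, rectal_air_cavity=True))
        body = ph.masks["body"].values
        assert np.any((ph.ct.values < -500) & body)


class TestMakePseudoCT:
    def test_zero_perturbation_identity(self, phantom):
        p = make_pseudo_ct(phantom.ct, phantom.masks, PerturbationSpec())
        assert np.array_equal(p.values, phantom.ct.values)

    def test_tissue_bias_exact(self, phantom):
        p = make_pseudo_ct(
            phantom.ct, phantom.masks, PerturbationSpec(tissue_hu_bias=40.0)
        )
        soft = (
            phantom.masks["body"].values
            & ~phantom.masks["bone"].values
            & (phantom.ct.values > -500)
        )
        diff = p.values - phantom.ct.values
        assert np.all(diff[soft] == 40.0)
        assert np.all(diff[~soft] == 0.0)

    def test_bone_bias_exact(self, phantom):
        p = make_pseudo_ct(
            phantom.ct, phantom.masks, PerturbationSpec(bone_hu_bias=-100.0)
        )
        bone = phantom.masks["bone"].values
        diff = p.values - phantom.ct.values
        assert np.all(diff[bone] == -100.0)
        assert np.all(diff[~bone] == 0.0)

    def test_skin_layer_area_growth(self):
        # 1 mm pixels: a 1 mm shell adds ~ perimeter x 1 mm of area per slice
        ph = make_phantom(
            PhantomSpec(
                body_semi_axes_mm=(40.0, 30.0),
                body_length_mm=20.0,
                spacing_mm=1.0,
                seed=0,
            )
        )
        p = make_pseudo_ct(ph.ct, ph.masks, PerturbationSpec(skin_layer_mm=1.0))
        body = ph.masks["body"].values
        k = body.shape[2] // 2
        # the shell is partial-volume weighted; its area is the sum of
        # covered fractions, (HU - air) / (tissue - air), over added pixels
        sl = p.values[:, :, k]
        added = np.sum(((sl + 1000.0) / 1000.0)[~body[:, :, k]])
        a, b = ph.geometry["semi_axes_mm"]
        # Ramanujan approximation of the ellipse perimeter
        h = ((a - b) / (a + b)) ** 2
        perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert added == pytest.approx(perim, rel=0.25)

    def test_contour_jitter_changes_boundary_only(self, phantom):
        p = make_pseudo_ct(
            phantom.ct, phantom.masks, PerturbationSpec(contour_jitter_mm=3.0, seed=5)
        )
        changed = p.values != phantom.ct.values
        body = phantom.masks["body"].values
        from scipy import ndimage

        deep_inside = ndimage.binary_erosion(body, iterations=5)
        assert changed.any()
        assert not np.any(changed & deep_inside)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(skin_layer_mm=-1.0)


class TestToyDoseEngine:
    def test_hu_density_map(self):
        assert hu_to_density(np.array([0.0])) == pytest.approx(1.0)
        assert hu_to_density(np.array([-1000.0])) == pytest.approx(0.0)
        assert hu_to_density(np.array([5000.0])) == pytest.approx(2.0)  # clipped

    def test_single_beam_slope_recovers_mu(self):
        ph = water_phantom()
        beams = BeamSpec(n_beams=1, half_width_mm=30.0, mu_eff_per_mm=0.005)
        d = toy_dose_engine(ph.ct, beams, ph.isocenter)
        iso = ph.isocenter
        xs = np.linspace(iso[0] - 50, iso[0] + 50, 41)
        pts = np.stack([xs, np.full_like(xs, iso[1]), np.full_like(xs, iso[2])], 1)
        vals = sample_trilinear(d.grid, pts)
        slope = np.polyfit(xs, np.log(vals), 1)[0]
        assert slope == pytest.approx(-0.005, rel=0.01)

    def test_slab_attenuation_closed_form(self):
        ph = water_phantom()
        beams = BeamSpec(n_beams=1, half_width_mm=30.0, mu_eff_per_mm=0.005)
        scale = 1.0
        d0 = toy_dose_engine(ph.ct, beams, ph.isocenter, scale=scale)
        # double density (HU 0 -> 1000) in a slab upstream of the isocenter
        t = 20.0
        ct2 = ph.ct.copy()
        iso = ph.isocenter
        x = ct2.origin[0] + ct2.spacing[0] * np.arange(ct2.dims[0])
        slab = (x >= iso[0] - 60) & (x < iso[0] - 60 + t)
        body = ph.masks["body"].values
        ct2.values[slab, :, :] = np.where(body[slab, :, :], 1000.0, ct2.values[slab, :, :])
        d1 = toy_dose_engine(ct2, beams, iso, scale=scale)
        v0 = sample_trilinear(d0.grid, iso)
        v1 = sample_trilinear(d1.grid, iso)
        assert v1 / v0 == pytest.approx(np.exp(-0.005 * t), rel=0.02)

    def test_all_zero_hu_equivalence(self):
        # a phantom whose every structure is water equals a manually-built
        # body-of-zeros image: identical doses
        ph = water_phantom(spacing=2.5)
        manual = ph.ct.copy()
        manual.values[:] = np.where(ph.masks["body"].values, 0.0, -1000.0)
        beams = small_beams(n_beams=3)
        d1 = toy_dose_engine(ph.ct, beams, ph.isocenter)
        d2 = toy_dose_engine(manual, beams, ph.isocenter)
        assert np.array_equal(d1.grid.values, d2.grid.values)

    def test_isocenter_outside_body_rejected(self, phantom):
        with pytest.raises(ValueError, match="body"):
            toy_dose_engine(
                phantom.ct, small_beams(), phantom.ct.origin + 1.0
            )

    def test_normalized_to_prescription(self, phantom):
        d = toy_dose_engine(phantom.ct, small_beams(), phantom.isocenter)
        assert sample_trilinear(d.grid, phantom.isocenter) == pytest.approx(60.0)


class TestMakeCase:
    def test_zero_perturbation_doses_identical(self, zero_case):
        assert np.array_equal(
            zero_case.ref_dose.grid.values, zero_case.eval_dose.grid.values
        )

    def test_dose_monotonic_in_tissue_bias(self):
        spec = small_phantom_spec(seed=2)
        beams = small_beams()
        ph = make_phantom(spec)
        diffs = []
        for bias in (0.0, 40.0, 160.0):
            pseudo = make_pseudo_ct(ph.ct, ph.masks, PerturbationSpec(tissue_hu_bias=bias))
            ev, ref = make_dose_pair(pseudo, ph.ct, beams, ph.isocenter)
            r = sample_trilinear(ref.grid, ph.isocenter)
            e = sample_trilinear(ev.grid, ph.isocenter)
            diffs.append(100.0 * (e - r) / r)
        assert diffs[0] == pytest.approx(0.0, abs=1e-9)
        assert diffs[0] > diffs[1] > diffs[2]

    def test_first_order_attenuation_prediction(self):
        # mean density error eps over tissue depth d shifts the isocenter dose
        # by ~ -100 * mu * d * eps percent
        spec = small_phantom_spec(seed=4)
        beams = small_beams()
        ph = make_phantom(spec)
        bias = 40.0
        eps = bias / 1000.0
        pseudo = make_pseudo_ct(ph.ct, ph.masks, PerturbationSpec(tissue_hu_bias=bias))
        ev, ref = make_dose_pair(pseudo, ph.ct, beams, ph.isocenter)
        r = sample_trilinear(ref.grid, ph.isocenter)
        e = sample_trilinear(ev.grid, ph.isocenter)
        measured = 100.0 * (e - r) / r
        # independent depth oracle: soft-tissue path length to the isocenter
        # along each beam axis, by direct ray marching of the tissue mask
        soft = (
            ph.masks["body"].values
            & ~ph.masks["bone"].values
            & (ph.ct.values > -500)
        )
        depths = []
        step = 0.5
        for i in range(beams.n_beams):
            ang = 2 * np.pi * i / beams.n_beams
            d = np.array([np.cos(ang), np.sin(ang), 0.0])
            depth = 0.0
            for t in np.arange(step / 2, 400.0, step):
                q = ph.isocenter - t * d
                ci = np.round((q - ph.ct.origin) / ph.ct.spacing).astype(int)
                if np.any(ci < 0) or np.any(ci >= np.array(ph.ct.dims)):
                    break
                if soft[tuple(ci)]:
                    depth += step
            depths.append(depth)
        predicted = -100.0 * beams.mu_eff_per_mm * np.mean(depths) * eps
        assert measured == pytest.approx(predicted, rel=0.3)

    def test_fiducial_jitter_failure_rate(self, phantom):
        failures = 0
        n = 100
        for seed in range(n):
            rng = np.random.default_rng(seed)
            rot, t = random_rigid_transform(rng, 5.0, 8.0)
            mri = jitter_fiducials(
                apply_rigid(phantom.fiducials_ct, rot, t, modality="MRI"), 2.0, rng
            )
            if not fiducial_qa(mri, phantom.fiducials_ct, 1.0).passed:
                failures += 1
        assert failures > n / 2

    def test_gamma_pass_rate_trend_with_bias(self):
        from planqa import GammaCriteria
        from planqa.report import run_case_qa

        spec = small_phantom_spec(seed=6)
        beams = small_beams()
        rates = []
        for bias in (0.0, 40.0, 160.0):
            bundle = make_case(spec, PerturbationSpec(tissue_hu_bias=bias), beams)
            rep = run_case_qa(bundle, criteria_list=[GammaCriteria(2, 2)])
            rates.append(rep.gamma_results[0].pass_rate_pct)
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] == 100.0

    def test_ground_truth_attached(self, zero_case):
        assert zero_case.ground_truth["perturbation"]["tissue_hu_bias"] == 0.0


class TestSmoothPair:
    def test_deterministic(self):
        a = smooth_random_dose_pair(3)
        b = smooth_random_dose_pair(3)
        assert np.array_equal(a[0].grid.values, b[0].grid.values)

    def test_mask_is_threshold(self):
        ref, _, mask = smooth_random_dose_pair(5)
        want = ref.grid.values >= 0.2 * ref.grid.values.max()
        assert np.array_equal(mask.values, want)
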