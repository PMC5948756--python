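import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfcount import (
    ChamberSpec,
    OpticsSpec,
    StainingCondition,
    StainingModelParams,
    render_brightfield,
    render_fluorescence,
    sample_scene,
    settle,
    settled,
    staining_signal,
)
from csfcount.errors import ValidationError
from csfcount.hough import find_circles
from csfcount.image import load_frame
from csfcount.simulate import (
    GroundTruthSample,
    SceneObject,
    frame_volume_ul,
    write_scene,
)


class TestSampleScene:
    def test_zero_rates_give_empty_scene(self):
        s = sample_scene(0, 0, debris_rate=0, clump_rate=0, seed=1)
        assert s.objects == ()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            sample_scene(-1, 0)

    def test_frame_volume(self):
        v = frame_volume_ul(OpticsSpec(), ChamberSpec())
        assert v == pytest.approx(0.14928, rel=1e-3)

    def test_poisson_loading_mean_and_dispersion(self):
        """Counts are Poisson at concentration x control volume.

        At 1000 RBC/μL the per-frame mean is ~149.3; at 5.2 WBC/μL, ~0.78.
        Variance/mean stays near 1 (the in-plane exclusion at ~5% area
        occupancy barely perturbs the loading statistics).
        """
        n_seeds = 200
        rbc = np.empty(n_seeds)
        wbc = np.empty(n_seeds)
        for i in range(n_seeds):
            s = sample_scene(1000.0, 5.2, debris_rate=0, clump_rate=0, seed=10_000 + i)
            rbc[i] = s.count("RBC")
            wbc[i] = s.count("WBC")
        mu_rbc = 1000.0 * frame_volume_ul(OpticsSpec(), ChamberSpec())
        mu_wbc = 5.2 * frame_volume_ul(OpticsSpec(), ChamberSpec())
        assert abs(rbc.mean() - mu_rbc) < 3 * math.sqrt(mu_rbc / n_seeds)
        assert abs(wbc.mean() - mu_wbc) < 3 * math.sqrt(mu_wbc / n_seeds)
        assert 0.7 < rbc.var() / rbc.mean() < 1.3
        assert 0.7 < wbc.var() / max(wbc.mean(), 1e-9) < 1.3

    def test_objects_respect_geometry_and_size_bands(self):
        s = sample_scene(300, 100, seed=3)
        for o in s.objects:
            assert 0 <= o.x <= 610 and 0 <= o.y <= 460
            assert 0 <= o.z0 <= 532
            if o.cls in ("RBC", "WBC"):
                assert 8.6 <= o.diameter <= 14.2
            elif o.cls == "debris":
                assert o.diameter < 8.6
            else:
                assert o.diameter > 14.2

    def test_settled_objects_do_not_interpenetrate(self):
        s = sample_scene(1000, 0, debris_rate=0, clump_rate=0, seed=5)
        pts = s.positions(("RBC",))
        radii = np.array([o.diameter / 2 for o in s.objects])
        d = np.hypot(pts[:, 0:1] - pts[None, :, 0], pts[:, 1:2] - pts[None, :, 1])
        np.fill_diagonal(d, np.inf)
        lim = radii[:, None] + radii[None, :]
        assert (d >= lim - 1e-9).all()


class TestSettle:
    def _scene(self):
        objs = tuple(
            SceneObject(x=10.0 * i, y=10.0, z0=z, z=z, cls="RBC", diameter=10.0)
            for i, z in enumerate((0.0, 124.0, 400.0, 532.0))
        )
        return GroundTruthSample(objs, 0, 0, 0, OpticsSpec(), ChamberSpec())

    def test_zero_time_is_identity(self):
        s = self._scene()
        assert settle(s, 0.0, 0.92) == s

    def test_full_sedimentation(self):
        s = settle(self._scene(), 532 / 0.92 + 1, 0.92)
        assert all(o.z == 0.0 for o in s.objects)

    def test_linear_descent(self):
        s = settle(self._scene(), 300.0, 0.92)
        assert s.objects[2].z == pytest.approx(400 - 276, abs=1e-9)

    def test_order_and_classes_unchanged(self):
        s0 = self._scene()
        s1 = settle(s0, 100.0, 0.92)
        assert [o.cls for o in s1.objects] == [o.cls for o in s0.objects]
        assert [o.x for o in s1.objects] == [o.x for o in s0.objects]


class TestStainingSignal:
    def test_saturation_limit(self):
        m = StainingModelParams()
        assert staining_signal(1e9, 1e9, m) == pytest.approx(m.s_max, rel=1e-3)

    def test_hill_half_point(self):
        m = StainingModelParams()
        assert staining_signal(m.k_half, 1e9, m) == pytest.approx(m.s_max / 2, rel=1e-3)

    def test_optimum_condition_amplitude(self):
        """At (750 μM, 10 min): Hill(750) x (1 - e^(-10/3.33)) = 0.4751 s_max."""
        m = StainingModelParams()
        assert staining_signal(750.0, 10.0, m) == pytest.approx(0.4751 * m.s_max, rel=1e-3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c1=st.floats(0, 2000), c2=st.floats(0, 2000),
        t1=st.floats(0, 60), t2=st.floats(0, 60),
    )
    def test_monotone_in_both_arguments(self, c1, c2, t1, t2):
        m = StainingModelParams()
        lo = staining_signal(min(c1, c2), min(t1, t2), m)
        hi = staining_signal(max(c1, c2), max(t1, t2), m)
        assert hi >= lo - 1e-9


class TestRendering:
    def test_bit_identical_determinism(self):
        s = settled(sample_scene(80, 40, seed=11))
        bf1 = render_brightfield(s)
        bf2 = render_brightfield(s)
        fl1 = render_fluorescence(s)
        fl2 = render_fluorescence(s)
        assert np.array_equal(bf1.pixels, bf2.pixels)
        assert np.array_equal(fl1.pixels, fl2.pixels)
        assert not np.array_equal(bf1.pixels, fl1.pixels)

    def test_empty_scene_brightfield_is_background_only(self, config):
        s = sample_scene(0, 0, debris_rate=0, clump_rate=0, seed=2)
        bf = render_brightfield(s)
        base = 0.55 * 65535
        assert bf.pixels.mean() == pytest.approx(base, rel=0.02)
        assert find_circles(bf, config.detection) == []

    def test_membrane_ring_profile(self):
        """A settled 11-μm cell leaves a dark annulus with its intensity
        minimum at radius 5.5 μm (within one pixel)."""
        obj = SceneObject(x=305, y=230, z0=0, z=0, cls="RBC", diameter=11.0)
        s = GroundTruthSample((obj,), 0, 0, 42, OpticsSpec(), ChamberSpec())
        bf = render_brightfield(s, noise_sd=0.0)
        px = bf.pixel_size
        arr = bf.to_float()
        yy, xx = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1]]
        rho = np.hypot(xx - obj.x / px, yy - obj.y / px) * px
        bins = np.arange(0, 12, 0.25)
        prof = [arr[(rho >= a) & (rho < a + 0.25)].mean() for a in bins]
        r_min = bins[int(np.argmin(prof))] + 0.125
        assert abs(r_min - 5.5) <= px

    def test_fluorescence_channel_selectivity(self, config):
        """RBC-only scenes are indistinguishable from pure background in the
        fluorescence channel: nucleic-acid staining marks only WBCs."""
        s = settled(sample_scene(300, 0, seed=9))
        model = StainingModelParams()
        cond = StainingCondition()
        fl = render_fluorescence(s, staining=cond, model=model, noise_sd=150.0)
        bg = model.bg_floor + model.bg_slope * cond.c_d
        assert abs(fl.pixels.mean() - bg) < 2 * 150.0
        assert find_circles(fl, config.detection) == []

    def test_zero_dye_gives_floor_background(self):
        s = settled(sample_scene(0, 50, seed=4))
        m = StainingModelParams()
        fl = render_fluorescence(s, staining=StainingCondition(c_d=0.0, t_i=10), model=m,
                                 noise_sd=0.0)
        assert float(fl.pixels.max()) <= m.bg_floor + 1

    def test_blur_monotone_in_height(self):
        """Edge gradient magnitude decreases as a cell sits higher above
        the focal plane at the chamber floor."""
        grads = []
        for z in (0.0, 100.0, 250.0, 450.0):
            obj = SceneObject(x=305, y=230, z0=z, z=z, cls="RBC", diameter=11.0)
            s = GroundTruthSample((obj,), 0, 0, 3, OpticsSpec(), ChamberSpec())
            bf = render_brightfield(s, noise_sd=0.0)
            gy, gx = np.gradient(bf.to_float())
            grads.append(np.hypot(gx, gy).max())
        assert all(a > b for a, b in zip(grads, grads[1:]))


def test_write_scene_round_trip(tmp_path):
    s = settled(sample_scene(50, 20, seed=6))
    bf = render_brightfield(s)
    fl = render_fluorescence(s)
    paths = write_scene(tmp_path, "s6", s, bf, fl)
    assert paths["bf"].name == "s6_bf.tif"
    reloaded = load_frame(paths["bf"], 0.476, "bright_field")
    assert np.array_equal(reloaded.pixels, bf.pixels)
    lines = paths["truth"].read_text().strip().splitlines()
    assert lines[0] == "x_um,y_um,z_um,class,diameter_um"
    assert len(lines) == 1 + len(s.objects)
    assert (tmp_path / "s6_manifest.json").exists()
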