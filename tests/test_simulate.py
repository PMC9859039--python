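"""Track spawning, growth geometry, and movie rendering."""

import numpy as np
import pytest

from mtnuc import (
    MovieStack,
    NucleationKinetics,
    RenderSettings,
    SimulationConfig,
    grow_tracks,
    render_movie,
    simulate_tracks,
)
from mtnuc.simulate import MicrotubuleTrack, _clip_segment


class TestTrackSpawning:
    def test_zero_rate_spawns_nothing(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(0.0, 10.0),
                               duration=60.0)
        tracks, truth = simulate_tracks(cfg)
        assert tracks == []
        assert truth.counts_at([10.0, 60.0]).tolist() == [0, 0]

    def test_linear_regime_one_birth_per_second(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 1e9),
                               duration=10.0)
        tracks, _ = simulate_tracks(cfg)
        assert [t.birth_time for t in tracks] == list(np.arange(1.0, 11.0))

    def test_saturating_births_hand_recursion(self):
        # recursion counts 2, 3, 3.5, 3.75, ...; floor-with-carry spawns at
        # 1 s (x2) and 2 s; the 4th track appears once the count comes
        # within numerical tolerance of the capacity (t = 22 s)
        cfg = SimulationConfig(kinetics=NucleationKinetics(2.0, 4.0),
                               duration=50.0)
        tracks, _ = simulate_tracks(cfg)
        assert [t.birth_time for t in tracks] == [1.0, 1.0, 2.0, 22.0]

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(0.5, 30.0),
                               duration=100.0, seed=42)
        a, _ = simulate_tracks(cfg)
        b, _ = simulate_tracks(cfg)
        assert [t.origin for t in a] == [t.origin for t in b]
        assert [t.orientation_deg for t in a] == [t.orientation_deg for t in b]

    def test_count_fidelity_against_recursion(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(3.0, 40.0),
                               duration=120.0)
        _, truth = simulate_tracks(cfg)
        at_frames = truth.counts_at(truth.trajectory.times)
        assert np.all(np.abs(at_frames - np.floor(truth.trajectory.counts + 1e-6))
                      <= 1)

    def test_orientations_cover_eight_discrete_angles(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(10.0, 4000.0),
                               duration=300.0, seed=5)
        tracks, _ = simulate_tracks(cfg)
        angles = np.array([t.orientation_deg for t in tracks])
        expected = set(np.arange(8) * 45.0)
        assert set(angles.tolist()) == expected
        freqs = np.array([(angles == a).mean() for a in sorted(expected)])
        # binomial tolerance: 4 sigma around 1/8 with n > 2000 draws
        sigma = np.sqrt((1 / 8) * (7 / 8) / angles.size)
        assert np.all(np.abs(freqs - 1 / 8) < 4 * sigma)

    def test_templated_fraction_controls_anchoring(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(5.0, 500.0),
                               duration=120.0, templated_fraction=0.0, seed=2)
        tracks, _ = simulate_tracks(cfg)
        assert tracks and all(not t.anchored for t in tracks)


class TestGrowthGeometry:
    def test_zero_length_at_birth(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 10.0))
        trk = MicrotubuleTrack(0, 5.0, (20.0, 20.0), 0.0, True)
        segs = grow_tracks([trk], 5.0, cfg)
        assert segs[0].true_length_um == 0.0
        assert segs[0].p0 == segs[0].p1

    def test_length_is_speed_times_elapsed(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 10.0),
                               growth_speed=1.5)
        trk = MicrotubuleTrack(0, 0.0, (20.0, 20.0), 0.0, True)
        assert trk.length_um(120.0, cfg) == pytest.approx(3.0)

    def test_unborn_tracks_omitted(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 10.0))
        trk = MicrotubuleTrack(0, 50.0, (20.0, 20.0), 0.0, True)
        assert grow_tracks([trk], 10.0, cfg) == []

    def test_clipping_preserves_true_length(self):
        # 45-degree track nucleated near the corner grows out of plane
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 10.0),
                               plane_size=(40, 40), pixel_size=0.16,
                               growth_speed=6.0)
        trk = MicrotubuleTrack(0, 0.0, (35.0, 35.0), 45.0, True)
        t = 120.0
        seg = grow_tracks([trk], t, cfg)[0]
        assert seg.clipped
        true_len = trk.length_um(t, cfg)
        assert seg.true_length_um == pytest.approx(true_len)
        rendered_px = np.hypot(seg.p1[0] - seg.p0[0], seg.p1[1] - seg.p0[1])
        assert rendered_px * cfg.pixel_size < true_len
        # clipped endpoint sits on the plane boundary (line-box intersection)
        assert max(seg.p1) == pytest.approx(39.0)

    def test_clip_segment_against_box(self):
        # independent check of the Liang-Barsky helper on a hand case:
        # segment (−5,5) -> (15,5) through a 10x10 box clips to x in [0,9]
        q0, q1, clipped = _clip_segment((-5.0, 5.0), (15.0, 5.0), 10, 10)
        assert clipped
        assert q0 == pytest.approx((0.0, 5.0))
        assert q1 == pytest.approx((9.0, 5.0))
        assert _clip_segment((-5.0, -5.0), (-1.0, -1.0), 10, 10) is None


class TestRendering:
    def test_blank_movie_is_constant(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(0.0, 10.0),
                               duration=20.0)
        movie = render_movie([], cfg, RenderSettings(noise_model="none"))
        assert np.all(movie.data == 200.0)  # background + offset

    def test_intensity_proportional_to_length(self, noise_free_render):
        cfg = SimulationConfig(kinetics=NucleationKinetics(0.2, 20.0),
                               duration=120.0, plane_size=(80, 80),
                               pixel_size=0.16, growth_speed=6.0, seed=2)
        tracks, truth = simulate_tracks(cfg)
        movie = render_movie(tracks, cfg, noise_free_render)
        base = noise_free_render.background + noise_free_render.camera_offset
        total = movie.data.reshape(movie.n_frames, -1).sum(axis=1) \
            - base * np.prod(cfg.plane_size)
        lengths = np.array(
            [truth.total_length_um(t, in_plane_only=True)
             for t in movie.frame_times]
        )
        live = lengths > 0
        r2 = np.corrcoef(total[live], lengths[live])[0, 1] ** 2
        assert r2 > 0.999

    def test_rendered_extent_matches_track_length(self, noise_free_render):
        # a single straight track's above-background footprint spans its
        # length plus at most a couple of PSF widths
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 1.0),
                               duration=100.0, plane_size=(80, 40),
                               pixel_size=0.1, growth_speed=3.0)
        trk = MicrotubuleTrack(0, 0.0, (10.0, 20.0), 0.0, True)
        movie = render_movie([trk], cfg, RenderSettings(noise_model="none",
                                                        psf_sigma=0.2))
        frame = movie.data[-1]
        base = 200.0
        cols = np.flatnonzero((frame > base + 1.0).any(axis=0))
        extent_um = (cols[-1] - cols[0]) * cfg.pixel_size
        true_um = trk.length_um(100.0, cfg)
        assert extent_um == pytest.approx(true_um, abs=4 * 0.2)

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 50.0),
                               duration=60.0, seed=9)
        render = RenderSettings(eb1_channel=True)
        for name in ("a", "b"):
            tracks, _ = simulate_tracks(cfg)
            movie, eb1 = render_movie(tracks, cfg, render)
            movie.save(tmp_path / f"{name}.tif")
            eb1.save(tmp_path / f"{name}_eb1.tif")
        assert (tmp_path / "a.tif").read_bytes() == (tmp_path / "b.tif").read_bytes()
        assert (tmp_path / "a_eb1.tif").read_bytes() == \
            (tmp_path / "b_eb1.tif").read_bytes()

    def test_noise_models_differ_from_clean(self):
        cfg = SimulationConfig(kinetics=NucleationKinetics(1.0, 20.0),
                               duration=20.0, seed=1)
        tracks, _ = simulate_tracks(cfg)
        clean = render_movie(tracks, cfg, RenderSettings(noise_model="none"))
        noisy = render_movie(tracks, cfg, RenderSettings())
        assert not np.array_equal(clean.data, noisy.data)
        resid = noisy.data[0].astype(float) - clean.data[0].astype(float)
        assert 5.0 < resid.std() < 20.0  # shot noise at background ~ sqrt(100)


class TestMovieStackIO:
    def test_tiff_round_trip_preserves_data_and_calibration(self, tmp_path):
        stack = MovieStack(np.random.default_rng(0).random((4, 16, 16)),
                           pixel_size_um=0.16, frame_interval_s=2.0)
        path = tmp_path / "m.tif"
        stack.save(path)
        back = MovieStack.load(path)
        assert back.pixel_size_um == 0.16
        assert back.frame_interval_s == 2.0
        assert np.allclose(back.data, stack.data.astype(np.float32))

    def test_missing_calibration_requires_explicit_values(self, tmp_path):
        import tifffile

        path = tmp_path / "bare.tif"
        tifffile.imwrite(path, np.zeros((2, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="calibration"):
            MovieStack.load(path)
        back = MovieStack.load(path, pixel_size_um=0.1, frame_interval_s=1.0)
        assert back.n_frames == 2
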