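import numpy as np
import pytest

from ecg2img.errors import (
    DimensionError,
    EmptyInputError,
    PartitionError,
    ShapeError,
)
from ecg2img.imaging import (
    RenderConfig,
    compose_panel,
    encode_patient,
    load_image_png,
    render_strip,
    resize_lanczos,
    save_panel_png,
    split_segments,
)
from ecg2img.leads import LeadPanel

from _oracles import lanczos_direct


class TestSplitSegments:
    @pytest.mark.parametrize("n_samples, n, lengths", [
        (5000, 3, (1667, 1667, 1666)),
        (5, 2, (3, 2)),
        (9, 3, (3, 3, 3)),
        (10, 4, (3, 3, 2, 2)),
    ])
    def test_lengths(self, n_samples, n, lengths):
        parts = split_segments(np.arange(n_samples), n)
        assert tuple(len(p) for p in parts) == lengths

    def test_single_segment_identity(self, rng):
        x = rng.normal(0, 1, 37)
        (seg,) = split_segments(x, 1)
        np.testing.assert_array_equal(seg, x)

    def test_concatenation_recovers_input(self, rng):
        x = rng.normal(0, 1, 5000)
        parts = split_segments(x, 3)
        np.testing.assert_array_equal(np.concatenate(parts), x)

    def test_explicit_example(self):
        parts = split_segments(np.array([1, 2, 3, 4, 5]), 2)
        np.testing.assert_array_equal(parts[0], [1, 2, 3])
        np.testing.assert_array_equal(parts[1], [4, 5])

    def test_too_many_segments(self):
        with pytest.raises(PartitionError):
            split_segments(np.arange(3), 4)


class TestRenderStrip:
    def test_all_zero_gives_single_midline_row(self, render_config):
        grid = render_strip(np.zeros(100), 100, 256, render_config)
        trace_rows = np.unique(np.where(grid == 0)[0])
        assert len(trace_rows) == 1
        assert trace_rows[0] in (127, 128)  # midline of 256 rows
        assert (grid[grid != 0] == 255).all()

    def test_positive_clip_confined_to_top_row(self, render_config):
        r = render_config.amp_range_mv
        grid = render_strip(np.array([r, r]), 50, 64, render_config)
        assert (grid[0] == 0).all()
        assert (grid[1:] == 255).all()

    def test_out_of_range_clipped(self, render_config):
        grid = render_strip(np.array([99.0, 99.0]), 50, 64, render_config)
        assert (grid[0] == 0).all()

    def test_negation_mirrors_strip(self, render_config, rng):
        # avoid amplitudes mapping exactly onto half-integer rows
        v = rng.uniform(-1.9, 1.9, 200)
        a = render_strip(v, 200, 256, render_config)
        b = render_strip(-v, 200, 256, render_config)
        np.testing.assert_array_equal(b, a[::-1, :])

    def test_trace_connected_between_columns(self, render_config):
        # steep jump: every row between the two sample rows must be inked
        grid = render_strip(np.array([-1.5, 1.5]), 2, 256, render_config)
        inked_rows = np.where((grid == 0).any(axis=1))[0]
        assert np.array_equal(inked_rows,
                              np.arange(inked_rows.min(), inked_rows.max() + 1))

    def test_monotone_geometry(self, render_config):
        # raising one sample's amplitude never moves its trace row down
        base = np.zeros(10)
        rows = []
        for amp in (-1.0, 0.0, 1.0):
            v = base.copy()
            v[5] = amp
            grid = render_strip(v, 10, 128, render_config)
            rows.append(np.where(grid[:, 5] == 0)[0].min())
        assert rows[0] >= rows[1] >= rows[2]

    def test_empty_input(self, render_config):
        with pytest.raises(EmptyInputError):
            render_strip(np.array([]), 10, 10, render_config)


class TestResizeLanczos:
    def test_identity_resize(self, rng):
        g = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        out = resize_lanczos(g, 32, 32, 3)
        np.testing.assert_array_equal(out, g)

    def test_constant_preserved(self):
        g = np.full((40, 60), 137, dtype=np.uint8)
        out = resize_lanczos(g, 17, 11, 3)
        assert (out == 137).all()

    @pytest.mark.parametrize("out_w, out_h", [(26, 26), (16, 48), (96, 20)])
    def test_matches_direct_convolution_oracle(self, rng, out_w, out_h):
        g = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        mine = resize_lanczos(g, out_w, out_h, 3).astype(int)
        ref = lanczos_direct(g, out_w, out_h, 3).astype(int)
        assert np.abs(mine - ref).max() <= 1

    def test_bad_dims(self):
        with pytest.raises(DimensionError):
            resize_lanczos(np.zeros((4, 4)), 0, 4, 3)


class TestRenderConfigFile:
    def test_yaml_and_json_round_trip(self, tmp_path):
        from ecg2img.imaging import render_config_from_file
        y = tmp_path / "cfg.yaml"
        y.write_text("amp_range_mv: 1.5\nlanczos_taps: 2\n")
        cfg = render_config_from_file(y)
        assert cfg.amp_range_mv == 1.5 and cfg.lanczos_taps == 2
        j = tmp_path / "cfg.json"
        j.write_text('{"strip_height_px": 26}')
        assert render_config_from_file(j) == RenderConfig()

    def test_unknown_field_rejected(self, tmp_path):
        from ecg2img.imaging import render_config_from_file
        f = tmp_path / "cfg.yaml"
        f.write_text("no_such_field: 1\n")
        with pytest.raises(ShapeError):
            render_config_from_file(f)


class TestComposePanel:
    def test_background_strips_give_background_image(self, render_config):
        s = np.full((26, 224), 255, dtype=np.uint8)
        img = compose_panel([s] * 4, render_config)
        assert img.shape == (224, 224)
        assert (img == 255).all()

    def test_band_placement(self, render_config, rng):
        strips = [rng.integers(0, 255, (26, 224)).astype(np.uint8)
                  for _ in range(4)]
        img = compose_panel(strips, render_config)
        for k in range(4):
            np.testing.assert_array_equal(img[k * 66:k * 66 + 26], strips[k])
        # gaps are untouched background
        for k in range(3):
            assert (img[k * 66 + 26:(k + 1) * 66] == 255).all()

    def test_permuting_strips_permutes_bands_only(self, render_config, rng):
        strips = [rng.integers(0, 255, (26, 224)).astype(np.uint8)
                  for _ in range(4)]
        a = compose_panel(strips, render_config)
        b = compose_panel(strips[::-1], render_config)
        for k in range(4):
            np.testing.assert_array_equal(b[k * 66:k * 66 + 26],
                                          a[(3 - k) * 66:(3 - k) * 66 + 26])

    def test_wrong_strip_dims(self, render_config):
        bad = [np.zeros((25, 224), dtype=np.uint8)] * 4
        with pytest.raises(ShapeError):
            compose_panel(bad, render_config)


class TestEncodePatient:
    def test_shapes_and_dtype(self, survivor_panel, render_config):
        panel = encode_patient(survivor_panel, render_config)
        assert len(panel.images) == 3
        for img in panel.images:
            assert img.shape == (224, 224)
            assert img.dtype == np.uint8

    def test_all_zero_panel_midline_traces(self, render_config):
        zeros = tuple(np.zeros(5000) for _ in range(4))
        panel = LeadPanel("z", zeros, 500.0)
        encoded = encode_patient(panel, render_config)
        for img in encoded.images:
            inked_cols = (img < 255).sum(axis=1)
            inked_rows = set(np.where(inked_cols > 0)[0])
            bands = render_config.strip_row_bands()
            # trace rows fall inside the four strip bands only
            allowed = {r for lo, hi in bands for r in range(lo, hi)}
            assert inked_rows <= allowed
            for lo, hi in bands:
                band = img[lo:hi].astype(int)
                darkest = band.min(axis=1).argmin()
                # midline of a 26-row strip
                assert abs(darkest - 12.5) <= 1.0
                assert (band < 255).any()

    def test_deterministic_png_bytes(self, survivor_panel, render_config,
                                      tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = save_panel_png(encode_patient(survivor_panel, render_config), d1)
        p2 = save_panel_png(encode_patient(survivor_panel, render_config), d2)
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_png_round_trip_preserves_pixels(self, survivor_panel,
                                             render_config, tmp_path):
        panel = encode_patient(survivor_panel, render_config)
        paths = save_panel_png(panel, tmp_path)
        for img, p in zip(panel.images, paths):
            np.testing.assert_array_equal(load_image_png(p), img)

    def test_mirror_property(self, render_config, rng):
        # encode(-signal) is the per-strip vertical mirror of encode(signal)
        leads = tuple(rng.uniform(-1.5, 1.5, 600) for _ in range(4))
        pos = encode_patient(LeadPanel("m", leads, 500.0), render_config)
        neg = encode_patient(
            LeadPanel("m", tuple(-x for x in leads), 500.0), render_config)
        for a, b in zip(pos.images, neg.images):
            for lo, hi in render_config.strip_row_bands():
                diff = b[lo:hi].astype(int) - a[lo:hi][::-1, :].astype(int)
                # float summation order may flip a value at a rounding
                # boundary by one intensity level
                assert np.abs(diff).max() <= 1
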