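"""Record reading, segmentation, detrending, and resampling."""

import numpy as np
import pytest

from scalodx import (
    EcgRecord,
    Segment,
    detrend,
    read_csv_signal,
    read_wfdb,
    resample,
    segment_record,
    write_csv_signal,
)


# ---------------------------------------------------------------------------
# WFDB fixtures written on the fly
# ---------------------------------------------------------------------------

def _write_wfdb16(tmp_path, name, channels, fs=250, gain=200, baseline=0):
    """channels: list of integer arrays, one per signal, format 16."""
    n_sig = len(channels)
    n = len(channels[0])
    hea = tmp_path / f"{name}.hea"
    lines = [f"{name} {n_sig} {fs} {n}"]
    for i in range(n_sig):
        lines.append(f"{name}.dat 16 {gain}({baseline})/mV 12 {baseline} 0 0 0 ch{i}")
    hea.write_text("\n".join(lines) + "\n")
    inter = np.column_stack(channels).astype("<i2").ravel()
    (tmp_path / f"{name}.dat").write_bytes(inter.tobytes())
    return str(tmp_path / name)


def _write_wfdb212(tmp_path, name, channels, fs=360, gain=200):
    n_sig = len(channels)
    n = len(channels[0])
    hea = tmp_path / f"{name}.hea"
    lines = [f"{name} {n_sig} {fs} {n}"]
    for i in range(n_sig):
        lines.append(f"{name}.dat 212 {gain} 12 0 0 0 0 ch{i}")
    hea.write_text("\n".join(lines) + "\n")
    flat = np.column_stack(channels).ravel().astype(int)
    if flat.size % 2:
        flat = np.append(flat, 0)
    out = bytearray()
    for a, b in flat.reshape(-1, 2):
        a &= 0xFFF
        b &= 0xFFF
        out += bytes([a & 0xFF, ((b >> 8) << 4) | (a >> 8), b & 0xFF])
    (tmp_path / f"{name}.dat").write_bytes(bytes(out))
    return str(tmp_path / name)


class TestReadWfdb:
    def test_format16_roundtrip_physical_units(self, tmp_path):
        digital = np.arange(1250, dtype=int) % 400 - 200
        path = _write_wfdb16(tmp_path, "rec16", [digital], fs=250, gain=200)
        rec = read_wfdb(path)
        assert rec.fs == 250
        assert rec.samples.size == 1250
        np.testing.assert_allclose(rec.samples, digital / 200.0)

    def test_gain_and_baseline_conversion(self, tmp_path):
        # stored 400 with gain 200, baseline 0 -> 2.0 mV
        path = _write_wfdb16(tmp_path, "g", [np.array([400, 0, -400])])
        rec = read_wfdb(path)
        np.testing.assert_allclose(rec.samples, [2.0, 0.0, -2.0])

    def test_format212_two_channels(self, tmp_path):
        ch0 = np.array([0, 100, -100, 2047, -2048, 7])
        ch1 = np.array([5, -5, 1234, -1234, 0, 42])
        path = _write_wfdb212(tmp_path, "rec212", [ch0, ch1])
        np.testing.assert_allclose(read_wfdb(path, 0).samples, ch0 / 200.0)
        np.testing.assert_allclose(read_wfdb(path, 1).samples, ch1 / 200.0)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope"):
            read_wfdb(str(tmp_path / "nope"))

    def test_channel_out_of_range(self, tmp_path):
        path = _write_wfdb16(tmp_path, "one", [np.zeros(10, int) + 1])
        with pytest.raises(IndexError):
            read_wfdb(path, channel_index=3)


class TestCsv:
    def test_two_column_infers_fs(self, tmp_path):
        t = np.arange(250) * 0.004
        x = np.sin(t)
        p = tmp_path / "sig.csv"
        np.savetxt(p, np.column_stack([t, x]), delimiter=",")
        rec = read_csv_signal(str(p))
        assert rec.fs == pytest.approx(250.0, rel=1e-6)
        np.testing.assert_allclose(rec.samples, x)

    def test_single_column_needs_fs(self, tmp_path):
        p = tmp_path / "one.csv"
        np.savetxt(p, np.arange(10.0), delimiter=",")
        rec = read_csv_signal(str(p), fs=360)
        assert rec.fs == 360
        with pytest.raises(ValueError):
            read_csv_signal(str(p))

    def test_gap_in_time_column_rejected(self, tmp_path):
        t = np.arange(100) * 0.004
        t[50:] += 0.0004 * 10  # 10% gap
        p = tmp_path / "gap.csv"
        np.savetxt(p, np.column_stack([t, np.zeros(100)]), delimiter=",")
        with pytest.raises(ValueError, match="non-uniform"):
            read_csv_signal(str(p))

    def test_write_read_roundtrip(self, tmp_path, rng):
        rec = EcgRecord(samples=rng.normal(size=500), fs=250, record_id="rt")
        p = tmp_path / "rt.csv"
        write_csv_signal(rec, str(p))
        back = read_csv_signal(str(p))
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-9)
        assert back.fs == pytest.approx(250.0, rel=1e-4)


class TestSegmentation:
    @pytest.mark.parametrize(
        "n_seconds,expected", [(20, 4), (4.9, 0), (12, 2), (5, 1)]
    )
    def test_tiling_and_remainder(self, n_seconds, expected):
        fs = 250
        rec = EcgRecord(samples=np.ones(int(n_seconds * fs)), fs=fs)
        segs = segment_record(rec, duration=5)
        assert len(segs) == expected
        for i, s in enumerate(segs):
            assert s.samples.size == 1250
            assert s.start_index == i * 1250

    def test_overlap_windows(self):
        rec = EcgRecord(samples=np.arange(2500.0), fs=250)
        segs = segment_record(rec, duration=5, overlap=2.5)
        assert [s.start_index for s in segs] == [0, 625, 1250]

    def test_length_conservation(self, rng):
        rec = EcgRecord(samples=rng.normal(size=3333), fs=100)
        segs = segment_record(rec, duration=5)
        assert sum(s.samples.size for s in segs) == (3333 // 500) * 500


class TestDetrend:
    def test_removes_exact_line(self, make_seg):
        t = np.arange(1250) / 250.0
        seg = make_seg(0.5 + 0.1 * t)
        out = detrend(seg)
        np.testing.assert_allclose(out.samples, 0, atol=1e-12)

    def test_idempotent(self, make_seg, rng):
        seg = make_seg(rng.normal(size=1250))
        once = detrend(seg)
        twice = detrend(once)
        np.testing.assert_allclose(twice.samples, once.samples, atol=1e-12)

    def test_linear_operator(self, make_seg, rng):
        f = rng.normal(size=500)
        g = rng.normal(size=500)
        a, b = 2.5, -1.2
        lhs = detrend(make_seg(a * f + b * g)).samples
        rhs = a * detrend(make_seg(f)).samples + b * detrend(make_seg(g)).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_recovers_sine_on_line(self, make_seg):
        # explicit normal-equation oracle for the linear fit
        t = np.arange(1250) / 250.0
        sine = np.sin(2 * np.pi * 3 * t)
        seg = make_seg(sine + 2.0 + 0.3 * t)
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, seg.samples, rcond=None)
        expected = seg.samples - A @ coef
        np.testing.assert_allclose(detrend(seg).samples, expected, atol=1e-9)

    def test_mean_near_zero(self, make_seg, rng):
        out = detrend(make_seg(rng.normal(size=1250) * 3 + 7))
        rng_amp = out.samples.max() - out.samples.min()
        assert abs(out.samples.mean()) < 1e-9 * rng_amp


class TestDetrendProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(
            np.float64,
            st.integers(10, 200),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_residual_orthogonal_to_line(self, samples):
        seg = Segment(samples=samples, fs=100.0)
        out = detrend(seg).samples
        t = seg.times
        # least-squares residual is orthogonal to both basis functions
        scale = max(1.0, np.abs(samples).max())
        assert abs(out.sum()) < 1e-7 * scale * samples.size
        assert abs(out @ t) < 1e-7 * scale * samples.size * t.max()


class TestResample:
    def test_noop_same_rate(self, make_seg, rng):
        seg = make_seg(rng.normal(size=1250))
        out = resample(seg, 250.0)
        assert out is seg

    def test_length_scaling(self, make_seg, rng):
        seg = make_seg(rng.normal(size=1250), fs=250)
        out = resample(seg, 360.0)
        assert out.samples.size == 1800
        assert out.fs == 360.0

    def test_sine_preserved(self, make_seg):
        fs = 360.0
        t = np.arange(int(5 * fs)) / fs
        seg = make_seg(np.sin(2 * np.pi * 5 * t), fs=fs)
        out = resample(seg, 250.0)
        t2 = np.arange(out.samples.size) / 250.0
        ref = np.sin(2 * np.pi * 5 * t2)
        # exclude filter edge effects
        sl = slice(50, -50)
        r = np.corrcoef(out.samples[sl], ref[sl])[0, 1]
        assert r > 0.999

    def test_bad_rate(self, make_seg):
        with pytest.raises(ValueError):
            resample(make_seg(np.ones(10)), -1.0)
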