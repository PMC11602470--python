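"""Loading, band-pass filtering and amplitude artifact masking."""

import numpy as np
import pytest
from scipy.signal import periodogram

from mwnetdyn import (
    BANDS,
    Recording,
    ValidationError,
    bandpass_filter,
    load_recording,
    reject_by_amplitude,
)
from mwnetdyn.preprocess import DEFAULT_CHANNELS

from conftest import make_recording


def band_power(x, rate, lo, hi):
    f, p = periodogram(x, fs=rate)
    return p[(f >= lo) & (f <= hi)].sum()


def write_minimal_edf(path, data: np.ndarray, rate: int, channels) -> None:
    """Hand-rolled 16-bit EDF writer for a synthetic test fixture.

    One data record per second; physical range chosen so one digital unit is
    one microvolt (physical -32768..32767 uV over the full int16 range).
    """
    n_ch, n_samp = data.shape
    n_records = n_samp // rate
    hdr = bytearray()
    hdr += f"{'0':<8}".encode()                    # version
    hdr += b" " * 80 + b" " * 80                   # patient + recording id
    hdr += b"01.01.20" + b"00.00.00"               # start date/time
    hdr += f"{256 + 256 * n_ch:<8}".encode()       # header length
    hdr += b" " * 44
    hdr += f"{n_records:<8}".encode()
    hdr += f"{1:<8}".encode()                      # record duration, s
    hdr += f"{n_ch:<4}".encode()
    for ch in channels:
        hdr += f"{ch:<16}".encode()
    hdr += b" " * 80 * n_ch                        # transducer
    for _ in channels:
        hdr += f"{'uV':<8}".encode()
    for field in ("-32768", "32767", "-32768", "32767"):
        for _ in channels:                         # phys min/max, digital min/max
            hdr += f"{field:<8}".encode()
    hdr += b" " * 80 * n_ch                        # prefiltering
    for _ in channels:
        hdr += f"{rate:<8}".encode()               # samples per record
    hdr += b" " * 32 * n_ch                        # reserved
    body = bytearray()
    for r in range(n_records):
        for c in range(n_ch):
            body += data[c, r * rate : (r + 1) * rate].astype("<i2").tobytes()
    path.write_bytes(bytes(hdr) + bytes(body))


class TestRecordingValidation:
    def test_shape_and_names(self):
        data = np.zeros((8, 512))
        rec = Recording("p", "FL-1", 256.0, list(DEFAULT_CHANNELS), data)
        assert rec.n_channels == 8 and rec.duration == 2.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(data=np.zeros((1, 512))),  # too few channels
            dict(data=np.zeros((2, 100))),  # shorter than 1 s
            dict(data=np.full((2, 512), np.nan)),  # non-finite
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        data = kwargs["data"]
        names = [f"c{i}" for i in range(data.shape[0])]
        with pytest.raises(ValidationError):
            Recording("p", "FL-1", 256.0, names, data)

    def test_duplicate_channel_names_rejected(self):
        with pytest.raises(ValidationError):
            Recording("p", "FL-1", 256.0, ["a", "a"], np.zeros((2, 512)))


class TestLoadRecording:
    def test_delimited_roundtrip(self, tmp_path, rng):
        data = rng.standard_normal((2560, 8))
        path = tmp_path / "trial.csv"
        header = ",".join(DEFAULT_CHANNELS)
        np.savetxt(path, data, delimiter=",", header=header, comments="")
        rec = load_recording(path, "delimited", sampling_rate=256)
        assert rec.data.shape == (8, 2560)
        assert rec.channel_names == list(DEFAULT_CHANNELS)
        np.testing.assert_allclose(rec.data, data.T, rtol=1e-6)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1.0,2.0\n1.0,oops\n" + "1.0,2.0\n" * 300)
        with pytest.raises((ValidationError, IOError)):
            load_recording(path, "delimited", sampling_rate=256)

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError, match="nope"):
            load_recording(tmp_path / "nope.csv", "delimited", sampling_rate=256)

    def test_array_with_sidecar(self, tmp_path, rng):
        data = rng.standard_normal((4, 512))
        np.save(tmp_path / "rec.npy", data)
        (tmp_path / "rec.json").write_text(
            '{"sampling_rate": 256, "channel_names": ["a", "b", "c", "d"]}'
        )
        rec = load_recording(tmp_path / "rec.npy", "array")
        assert rec.sampling_rate == 256 and rec.channel_names == ["a", "b", "c", "d"]

    def test_channel_count_mismatch(self, tmp_path, rng):
        data = rng.standard_normal((2560, 8))
        path = tmp_path / "t.csv"
        np.savetxt(path, data, delimiter=",", header=",".join(DEFAULT_CHANNELS), comments="")
        with pytest.raises(ValidationError):
            load_recording(path, "delimited", sampling_rate=256, channel_names=["x"] * 4)

    def test_edf_roundtrip(self, tmp_path, rng):
        data_uv = rng.integers(-500, 500, size=(8, 2560)).astype(np.int16)
        path = tmp_path / "trial.edf"
        write_minimal_edf(path, data_uv, rate=256, channels=DEFAULT_CHANNELS)
        rec = load_recording(path, "edf")
        assert rec.data.shape == (8, 2560)
        assert rec.sampling_rate == 256.0
        # digital values map 1:1 to microvolts in the synthetic header
        np.testing.assert_allclose(rec.data, data_uv, atol=0.5)


class TestBandpassFilter:
    def test_alpha_tone_passes_alpha_band(self, rng):
        t = np.arange(2048) / 256.0
        tone = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(np.vstack([tone, tone]), 256.0)
        out = bandpass_filter(rec, "alpha")
        assert out.data.shape == rec.data.shape
        p_in = band_power(tone, 256, 9, 11)
        p_out = band_power(out.data[0], 256, 9, 11)
        assert abs(p_out - p_in) / p_in < 0.01

    def test_alpha_tone_blocked_by_delta_band(self):
        t = np.arange(8192) / 256.0
        tone = np.sin(2 * np.pi * 10 * t)
        rec = make_recording(np.vstack([tone, tone]), 256.0)
        out = bandpass_filter(rec, "delta")
        rms_in = np.sqrt(np.mean(tone**2))
        rms_out = np.sqrt(np.mean(out.data[0] ** 2))
        assert rms_out < 0.05 * rms_in

    def test_zero_signal_stays_zero(self):
        rec = make_recording(np.zeros((2, 1024)), 256.0)
        out = bandpass_filter(rec, "beta")
        assert np.allclose(out.data, 0)

    def test_band_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((2, 300)), 100.0)
        with pytest.raises(ValidationError):
            bandpass_filter(rec, "gamma")  # 80 Hz edge vs 50 Hz Nyquist

    def test_filtering_near_idempotent_in_passband(self, rng):
        # multi-tone signal inside the flat part of the alpha passband;
        # a second pass may only touch it through passband ripple
        t = np.arange(8192) / 256.0
        data = sum(np.sin(2 * np.pi * f * t + p)
                   for f, p in zip((9.0, 10.0, 11.5), (0.0, 1.0, 2.0)))
        data = np.vstack([data, data])
        once = bandpass_filter(make_recording(data, 256.0), "alpha")
        twice = bandpass_filter(once, "alpha")
        rms1 = np.sqrt(np.mean(once.data**2))
        rms2 = np.sqrt(np.mean(twice.data**2))
        assert abs(rms2 - rms1) / rms1 < 0.01


class TestRejectByAmplitude:
    def test_all_below_threshold_keeps_everything(self, noise_banded):
        out = reject_by_amplitude(noise_banded, threshold=1e6)
        assert out.valid_mask.all()

    def test_spike_masks_padded_interval(self):
        rate = 256.0
        data = np.zeros((2, int(10 * rate)))
        spike_idx = int(5 * rate)
        data[0, spike_idx] = 500.0
        rec = make_recording(data, rate, band="alpha")
        out = reject_by_amplitude(rec, threshold=100.0, pad=0.5)
        lo, hi = int(4.5 * rate), int(5.5 * rate)
        assert not out.valid_mask[lo : hi + 1].any()
        assert out.valid_mask[: lo].all() and out.valid_mask[hi + 1 :].all()

    def test_zero_threshold_rejected(self, noise_banded):
        with pytest.raises(ValidationError):
            reject_by_amplitude(noise_banded, threshold=0.0)

    def test_mask_monotone_in_threshold(self, noise_banded):
        kept = [
            reject_by_amplitude(noise_banded, threshold=thr).valid_mask.sum()
            for thr in (50.0, 20.0, 10.0, 5.0)
        ]
        assert all(a >= b for a, b in zip(kept, kept[1:]))
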