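"""Loading, band-pass filtering and amplitude-based artifact masking.

Recordings are multichannel EEG matrices (channels x samples, microvolts).
Inputs are assumed already resampled/notch-filtered; this module restricts a
recording to one of the five canonical frequency bands with a zero-phase
windowed-Hamming FIR filter (MNE defaults) and marks amplitude-contaminated
stretches in a boolean validity mask rather than cutting them out, so that
downstream segmentation never spans a discontinuity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BANDS",
    "BAND_ORDER",
    "Recording",
    "BandedRecording",
    "load_recording",
    "bandpass_filter",
    "reject_by_amplitude",
]

#: Canonical EEG band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}

#: Bands ordered from low to high frequency (used for deterministic tie-breaks).
BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: The 8-channel montage of the study system.
DEFAULT_CHANNELS: tuple[str, ...] = ("F3", "F4", "T3", "C3", "C4", "T4", "O1", "O2")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Recording:
    """One participant-trial multichannel signal.

    ``data`` is channel-major (``n_channels x n_samples``) in microvolts.
    """

    participant_id: str
    trial_label: str
    sampling_rate: float
    channel_names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples matrix")
        n_ch, n_samp = self.data.shape
        if n_ch < 2:
            raise ValidationError("at least 2 channels required")
        if len(self.channel_names) != n_ch:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for {n_ch} channels"
            )
        if len(set(self.channel_names)) != n_ch:
            raise ValidationError("channel names must be unique")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if n_samp < self.sampling_rate:
            raise ValidationError("recording must be at least 1 s long")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class BandedRecording(Recording):
    """A recording restricted to one frequency band, with a validity mask."""

    band: str = "alpha"
    band_edges: tuple[float, float] = BANDS["alpha"]
    valid_mask: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.band not in BANDS:
            raise ValidationError(f"unknown band {self.band!r}")
        if tuple(self.band_edges) != BANDS[self.band]:
            raise ValidationError(
                f"band_edges {self.band_edges} do not match {self.band} {BANDS[self.band]}"
            )
        if self.valid_mask.size == 0:
            self.valid_mask = np.ones(self.n_samples, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.n_samples,):
            raise ValidationError("valid_mask length must equal sample count")


def _load_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts; the package works in uV
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


def _load_delimited(path: Path) -> tuple[np.ndarray, list[str]]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - reported as I/O error with path
        raise IOError(f"could not read delimited file {path}: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValidationError(f"non-numeric values in {path}")
    return df.to_numpy().T, [str(c) for c in df.columns]


def _load_array(path: Path) -> tuple[np.ndarray, float | None, list[str] | None]:
    sidecar = path.with_suffix(".json")
    arr = np.load(path)
    rate = None
    names = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rate = meta.get("sampling_rate")
        names = meta.get("channel_names")
    return np.asarray(arr, dtype=np.float64), rate, names


def load_recording(
    path: str | Path,
    format: str = "delimited",
    *,
    sampling_rate: float | None = None,
    channel_names: Sequence[str] | None = None,
    participant_id: str = "unknown",
    trial_label: str = "unknown",
) -> Recording:
    """Read a recording from EDF, delimited text, or a raw array container.

    Delimited files carry one column per channel with a header row of channel
    names and require ``sampling_rate``. Array containers (``.npy``) may carry
    a ``.json`` sidecar with ``sampling_rate`` and ``channel_names``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"input file not found: {path}")
    if format == "edf":
        data, rate, names = _load_edf(path)
    elif format == "delimited":
        if sampling_rate is None:
            raise ValidationError("sampling_rate is required for delimited input")
        data, names = _load_delimited(path)
        rate = float(sampling_rate)
    elif format == "array":
        data, rate, names = _load_array(path)
        rate = float(sampling_rate if sampling_rate is not None else rate or 0)
        if rate <= 0:
            raise ValidationError("sampling_rate missing for array input")
    else:
        raise ValidationError(f"unknown format {format!r}")

    if channel_names is not None:
        if names is not None and len(channel_names) != len(names):
            raise ValidationError(
                f"config names {len(channel_names)} channels, file has {len(names)}"
            )
        names = list(channel_names)
    if names is None:
        raise ValidationError("channel names absent from file and config")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"non-finite values in {path}")
    return Recording(
        participant_id=participant_id,
        trial_label=trial_label,
        sampling_rate=float(rate),
        channel_names=list(names),
        data=data,
    )


def bandpass_filter(rec: Recording, band: str) -> BandedRecording:
    """Zero-phase windowed-Hamming FIR band-pass into one canonical band.

    Delegates to MNE's default FIR design (``firwin``, Hamming window,
    automatic order from the transition-bandwidth heuristic, forward-backward
    compensated for zero phase). Signal length is unchanged.
    """
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}")
    low, high = BANDS[band]
    if rec.sampling_rate <= 2 * high:
        raise ValidationError(
            f"band {band} upper edge {high} Hz >= Nyquist "
            f"({rec.sampling_rate / 2} Hz)"
        )
    import mne

    filtered = mne.filter.filter_data(
        rec.data,
        sfreq=rec.sampling_rate,
        l_freq=low,
        h_freq=high,
        fir_design="firwin",
        fir_window="hamming",
        phase="zero",
        verbose="error",
    )
    mask = rec.valid_mask.copy() if isinstance(rec, BandedRecording) else None
    return BandedRecording(
        participant_id=rec.participant_id,
        trial_label=rec.trial_label,
        sampling_rate=rec.sampling_rate,
        channel_names=list(rec.channel_names),
        data=filtered,
        band=band,
        band_edges=BANDS[band],
        valid_mask=mask if mask is not None else np.empty(0, dtype=bool),
    )


def reject_by_amplitude(
    rec: BandedRecording, threshold: float = 100.0, pad: float = 0.25
) -> BandedRecording:
    """Mask samples where any channel exceeds ``threshold`` uV, padded.

    The data are left untouched; ``valid_mask`` is cleared on the offending
    samples extended by ``pad`` seconds on each side. Lowering the threshold
    can only remove additional samples (mask monotonicity).
    """
    if threshold <= 0:
        raise ValidationError("amplitude threshold must be positive")
    bad = np.any(np.abs(rec.data) > threshold, axis=0)
    pad_n = int(round(pad * rec.sampling_rate))
    if pad_n > 0 and bad.any():
        idx = np.flatnonzero(bad)
        for i in idx:
            bad[max(0, i - pad_n) : i + pad_n + 1] = True
    new_mask = rec.valid_mask & ~bad
    return replace(rec, valid_mask=new_mask)
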