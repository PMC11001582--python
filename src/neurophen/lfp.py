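"""LFP preprocessing and Welch band power.

Raw multichannel LFP sampled at 2.5 kHz is low-pass filtered and decimated
to 500 Hz with an eighth-order Chebyshev Type 1 IIR filter (0.05 dB passband
ripple, cutoff at 0.8x the output Nyquist, applied forward-backward for zero
phase), common-average referenced, and averaged across cortical channels.
Band power is then estimated with Welch's method (40-s Hann windows, 50%
overlap) and averaged within the slow (0.1-1 Hz), mid-gamma (40-90 Hz) and
high-gamma (90-120 Hz) bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger("neurophen.lfp")

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "slow": (0.1, 1.0),
    "mid_gamma": (40.0, 90.0),
    "high_gamma": (90.0, 120.0),
}


@dataclass
class LfpRecording:
    """Multichannel LFP: ``samples`` is channels x time at ``fs_raw`` Hz."""

    samples: np.ndarray
    fs_raw: float = 2500.0
    channel_depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.fs_raw > 0:
            raise ValueError("fs_raw must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs_raw


@dataclass
class BandPower:
    """Band-averaged PSD (signal^2/Hz) in the three standard bands.

    ``integrated`` additionally carries the integrated power (signal^2) per
    band, since "mean power" can denote either convention.
    """

    slow: float
    mid_gamma: float
    high_gamma: float
    extra: dict[str, float] = field(default_factory=dict)
    integrated: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {"slow": self.slow, "mid_gamma": self.mid_gamma, "high_gamma": self.high_gamma}
        d.update(self.extra)
        return d


def common_average_reference(
    samples: np.ndarray, reference_channels: np.ndarray | None = None
) -> np.ndarray:
    """Subtract the per-sample mean across channels. Idempotent; with a single
    channel the input is returned unchanged with a warning.

    ``reference_channels`` restricts the subtracted mean to those rows (the
    usual trick for keeping a signal of interest out of its own reference);
    default is the mean over all channels.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 1:
        logger.warning("single channel: common average reference skipped")
        return samples
    ref = samples if reference_channels is None else samples[reference_channels]
    return samples - ref.mean(axis=0, keepdims=True)


def decimate_lfp(samples: np.ndarray, fs_raw: float, fs_out: float = 500.0) -> np.ndarray:
    """Low-pass + decimate each channel from fs_raw to fs_out.

    The decimation factor must be an integer. The anti-alias filter is the
    conventional Chebyshev Type 1, order 8, 0.05 dB ripple at 0.8x the output
    Nyquist, run forward-backward (zero phase).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    factor = fs_raw / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs_raw/fs_out must be a positive integer, got {factor}")
    q = int(round(factor))
    if q == 1:
        return samples.copy()
    # scipy's IIR decimator is exactly cheby1(8, 0.05, 0.8/q) + filtfilt
    return signal.decimate(samples, q, ftype="iir", zero_phase=True, axis=1)


CORTICAL_DEPTH_MAX_UM = 800.0


def preprocess_lfp(
    rec: LfpRecording,
    fs_out: float = 500.0,
    cortical_channels: np.ndarray | None = None,
) -> np.ndarray:
    """Filter/decimate each channel, common-average reference, then average
    the cortical channels into a single LFP trace.

    The reference mean is taken over the channels *not* being averaged
    (probe sites below cortex), so the cortical signal does not subtract
    itself: averaging mean-subtracted channels over the same set used for
    the mean is identically zero. Cortical channels default to those with
    ``channel_depths`` within ``CORTICAL_DEPTH_MAX_UM`` of the surface;
    without depth information (or with every channel cortical) the
    common-mode subtraction is skipped with a warning.
    """
    dec = decimate_lfp(rec.samples, rec.fs_raw, fs_out)
    n = dec.shape[0]
    if cortical_channels is None:
        if rec.channel_depths is not None:
            cortical_channels = np.flatnonzero(
                np.asarray(rec.channel_depths) <= CORTICAL_DEPTH_MAX_UM
            )
        else:
            cortical_channels = np.arange(n)
    cortical_channels = np.asarray(cortical_channels, dtype=int)
    if cortical_channels.size == 0:
        raise ValueError("no cortical channels to average")
    reference = np.setdiff1d(np.arange(n), cortical_channels)
    if reference.size:
        ref_mean = dec[reference].mean(axis=0, keepdims=True)
        return (dec[cortical_channels] - ref_mean).mean(axis=0)
    if n > 1:
        logger.warning(
            "all channels are averaged; common-mode subtraction skipped "
            "(it would null the averaged trace)"
        )
    return dec[cortical_channels].mean(axis=0)


def band_power_welch(
    trace: np.ndarray,
    fs: float,
    window_s: float = 40.0,
    overlap: float = 0.5,
    bands: dict[str, tuple[float, float]] | None = None,
    detrend: str = "linear",
) -> BandPower:
    """Welch band power of a single trace.

    PSD segments are ``window_s`` long (Hann taper, linear detrend per
    segment) with fractional ``overlap``; a band's value is the mean of PSD
    bins whose center frequency lies in the closed interval [lo, hi]. The
    40-s default window gives 0.025 Hz resolution, enough to resolve the
    0.1 Hz lower edge of the slow band.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be 1-D")
    all_bands = dict(DEFAULT_BANDS)
    if bands:
        all_bands.update(bands)
    nyq = fs / 2.0
    for name, (lo, hi) in all_bands.items():
        if hi > nyq:
            raise ValueError(f"band {name} upper edge {hi} Hz above Nyquist {nyq} Hz")
        if not 0 <= lo < hi:
            raise ValueError(f"band {name} edges must satisfy 0 <= lo < hi")
    nperseg = int(round(window_s * fs))
    if trace.size < 2 * nperseg:
        raise ValueError(
            f"trace too short: {trace.size} samples < 2 windows of {nperseg}"
        )
    freqs, psd = signal.welch(
        trace,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=detrend,
        scaling="density",
    )
    df = freqs[1] - freqs[0]
    means: dict[str, float] = {}
    integrated: dict[str, float] = {}
    for name, (lo, hi) in all_bands.items():
        mask = (freqs >= lo) & (freqs <= hi)
        if not np.any(mask):
            logger.warning("band %s contains no PSD bins at df=%.4g Hz", name, df)
            means[name] = 0.0
            integrated[name] = 0.0
            continue
        means[name] = float(psd[mask].mean())
        integrated[name] = float(psd[mask].sum() * df)
    extra = {k: v for k, v in means.items() if k not in DEFAULT_BANDS}
    return BandPower(
        slow=means["slow"],
        mid_gamma=means["mid_gamma"],
        high_gamma=means["high_gamma"],
        extra=extra,
        integrated=integrated,
    )


def analyze_lfp(
    rec: LfpRecording,
    fs_out: float = 500.0,
    window_s: float = 40.0,
    overlap: float = 0.5,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandPower:
    """Full chain: preprocess to a single averaged trace, then Welch band power."""
    trace = preprocess_lfp(rec, fs_out=fs_out)
    return band_power_welch(trace, fs_out, window_s=window_s, overlap=overlap, bands=bands)
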