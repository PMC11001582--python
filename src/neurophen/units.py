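"""Spike-sorted unit quality control and depth-binned firing rates.

Units surviving manual curation are admitted to analysis only if fewer than
1% of their inter-spike intervals violate the 2-ms physiological refractory
period. Mean firing rates are computed over 1-s bins across the recording
and summarised on a log10(Hz) scale for the superficial (0–400 µm) and
layer-5 (550–800 µm) depth bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("neurophen.units")

SUPERFICIAL = "superficial"
LAYER5 = "layer5"
UNASSIGNED = "unassigned"

# depth bins in µm below the cortical surface, inclusive on both ends
DEPTH_BINS: dict[str, tuple[float, float]] = {
    SUPERFICIAL: (0.0, 400.0),
    LAYER5: (550.0, 800.0),
}


class TooFewSpikesError(ValueError):
    """Unit has fewer than two spikes, so no ISI-based QC is possible."""


@dataclass
class SpikeUnit:
    """One sorted unit: spike times (s, ascending) and depth (µm below surface)."""

    unit_id: str
    spike_times: np.ndarray
    depth_um: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be non-decreasing")
        if self.depth_um < 0:
            raise ValueError("depth must be non-negative")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class UnitQC:
    unit_id: str
    n_spikes: int
    n_violations: int
    violation_fraction: float
    passes: bool


@dataclass
class FiringRateResult:
    unit_id: str
    mean_rate_hz: float
    log10_rate: float  # NaN when mean_rate_hz == 0
    depth_bin: str


def refractory_qc(
    unit: SpikeUnit, refractory_ms: float = 2.0, max_fraction: float = 0.01
) -> UnitQC:
    """Count ISIs strictly below the refractory period.

    The violation fraction uses the ISI count (``n_spikes - 1``) as its
    denominator; a unit passes only if the fraction is strictly below
    ``max_fraction`` (strict "< 1%"). Ties at exactly the refractory period
    are non-violations.
    """
    if unit.n_spikes < 2:
        raise TooFewSpikesError(f"unit {unit.unit_id}: {unit.n_spikes} spikes, QC unassessable")
    isis = np.diff(unit.spike_times)
    n_viol = int(np.sum(isis < refractory_ms / 1000.0))
    fraction = n_viol / isis.size
    return UnitQC(
        unit_id=unit.unit_id,
        n_spikes=unit.n_spikes,
        n_violations=n_viol,
        violation_fraction=fraction,
        passes=fraction < max_fraction,
    )


def assign_depth_bin(depth_um: float) -> str:
    """Map a depth to its cortical bin; the 400–550 µm gap and anything below
    800 µm is unassigned and excluded from binned summaries."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    for name, (lo, hi) in DEPTH_BINS.items():
        if lo <= depth_um <= hi:
            return name
    return UNASSIGNED


def mean_firing_rate(
    unit: SpikeUnit, recording_duration_s: float, bin_s: float = 1.0
) -> FiringRateResult:
    """Mean of spike counts over fixed bins, as Hz, and its log10.

    A trailing partial bin (when the duration is not an integer multiple of
    ``bin_s``) is dropped with a log message. With ``bin_s`` dividing the
    duration this is identical to n_spikes / duration.
    """
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be positive")
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(math.floor(recording_duration_s / bin_s))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    covered = n_bins * bin_s
    if covered < recording_duration_s:
        logger.debug(
            "unit %s: trailing %.3f s partial bin dropped", unit.unit_id,
            recording_duration_s - covered,
        )
    counts, _ = np.histogram(unit.spike_times, bins=n_bins, range=(0.0, covered))
    mean_rate = float(counts.mean() / bin_s)
    log10_rate = float(np.log10(mean_rate)) if mean_rate > 0 else float("nan")
    return FiringRateResult(
        unit_id=unit.unit_id,
        mean_rate_hz=mean_rate,
        log10_rate=log10_rate,
        depth_bin=assign_depth_bin(unit.depth_um),
    )


def unit_table(
    units: list[SpikeUnit],
    recording_duration_s: float,
    bin_s: float = 1.0,
    refractory_ms: float = 2.0,
    max_fraction: float = 0.01,
) -> pd.DataFrame:
    """QC + firing-rate table over a list of units.

    Units with fewer than two spikes are excluded (logged). Columns:
    unit_id, n_spikes, violation_fraction, passes, depth_bin, mean_rate_hz,
    log10_rate.
    """
    rows = []
    n_unassessable = 0
    for u in units:
        try:
            qc = refractory_qc(u, refractory_ms=refractory_ms, max_fraction=max_fraction)
        except TooFewSpikesError:
            n_unassessable += 1
            continue
        fr = mean_firing_rate(u, recording_duration_s, bin_s=bin_s)
        rows.append(
            {
                "unit_id": u.unit_id,
                "n_spikes": qc.n_spikes,
                "n_violations": qc.n_violations,
                "violation_fraction": qc.violation_fraction,
                "passes": qc.passes,
                "depth_um": u.depth_um,
                "depth_bin": fr.depth_bin,
                "mean_rate_hz": fr.mean_rate_hz,
                "log10_rate": fr.log10_rate,
            }
        )
    if n_unassessable:
        logger.warning("%d unit(s) with < 2 spikes excluded from QC", n_unassessable)
    return pd.DataFrame(rows)


def depth_bin_summary(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Median and quartiles of log10 rates per depth bin, QC-passing units only.

    Zero-rate units (log10 undefined) are excluded from the distributions and
    counted, not floored.
    """
    out: dict[str, dict[str, float]] = {}
    passing = table[table["passes"]]
    for name in (SUPERFICIAL, LAYER5):
        sub = passing[passing["depth_bin"] == name]
        n_zero = int((sub["mean_rate_hz"] == 0).sum())
        rates = sub.loc[sub["mean_rate_hz"] > 0, "log10_rate"].to_numpy()
        if rates.size == 0:
            out[name] = {"n_units": int(len(sub)), "n_zero_rate": n_zero}
            continue
        q1, med, q3 = np.percentile(rates, [25, 50, 75])
        out[name] = {
            "n_units": int(len(sub)),
            "n_zero_rate": n_zero,
            "log10_rate_median": float(med),
            "log10_rate_q1": float(q1),
            "log10_rate_q3": float(q3),
        }
    return out
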