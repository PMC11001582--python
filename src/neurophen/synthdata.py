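"""Synthetic neural and proteomic data with known ground truth.

Every downstream stage of the pipeline can be exercised without any
experimental download: this module generates

* ROI/neuropil fluorescence recordings with known transient onsets, rates
  and activity classes,
* spike tables with known rates, depths and contamination flags,
* multichannel LFP with exact per-band power targets and a channel-common
  offset, and
* group-structured log2 protein abundance tables with known differential
  flags, effect sizes and ECM labels.

Randomness: every generator is a pure function of its arguments including
``seed``. Internally a single :class:`numpy.random.SeedSequence` is built
from the seed and spawned into named child streams in a fixed order, so
adding draws to one sub-stream never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.ndimage import gaussian_filter1d

from .calcium import FluorescenceRecording, classify_activity
from .lfp import DEFAULT_BANDS, LfpRecording
from .units import SpikeUnit


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

@dataclass
class CalciumTruth:
    """Ground truth for a synthetic fluorescence recording.

    ``rate_per_roi`` is the realized event rate (events/min) and
    ``class_per_roi`` is the activity classifier applied to that rate, so
    truth classes are consistent with the >3/min rule by construction.
    """

    event_times_per_roi: list[np.ndarray]
    rate_per_roi: np.ndarray
    class_per_roi: list[str]
    kernel_params: tuple[float, float]
    neuropil_coupling: float
    noise_sd: float
    seed: int
    amplitudes_per_roi: list[np.ndarray] | None = None  # event dF/F amplitudes


def _double_exp_kernel(rise_s: float, decay_s: float, fs: float) -> np.ndarray:
    """Unit-peak double-exponential transient kernel sampled at fs."""
    if not (decay_s > rise_s > 0):
        raise ValueError("kernel requires decay > rise > 0")
    t = np.arange(0, int(math.ceil(6 * decay_s * fs)) + 1) / fs
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _conditional_poisson_count(
    rng: np.random.Generator, lam: float, threshold: float, above: bool, max_tries: int = 10000
) -> int:
    """Poisson draw conditioned on count > threshold (above) or <= threshold."""
    for _ in range(max_tries):
        c = int(rng.poisson(lam))
        if (c > threshold) == above:
            return c
    return int(math.floor(threshold)) + 1 if above else int(math.floor(threshold))


def gen_calcium(
    n_rois: int = 100,
    duration_s: float = 300.0,
    fs: float = 30.0,
    frac_hyper: float = 0.1,
    rate_hyper: float = 4.0,
    rate_base: float = 0.5,
    kernel_params: tuple[float, float] = (0.1, 1.0),
    neuropil_coupling: float = 0.7,
    noise_sd: float = 2.0,
    snr: float = 8.0,
    baseline: float = 100.0,
    background_sd: float = 1.0,
    animal_id: str = "sim",
    genotype: str = "synthetic",
    layer: str = "superficial",
    seed: int = 0,
) -> tuple[FluorescenceRecording, CalciumTruth]:
    """Simulate ROI + neuropil fluorescence with known transients.

    A quota of ``round(frac_hyper * n_rois)`` ROIs is hyperactive: their
    Poisson event counts (mean ``rate_hyper`` per min) are conditioned on a
    realized rate strictly above 3/min, and the remaining ROIs (mean
    ``rate_base``) on a rate at or below 3/min, so the truth fraction is
    exact and truth classes match the classifier applied to realized rates.

    Each ROI trace is ``baseline * (1 + sum of events convolved with a
    unit-peak double-exponential kernel) + neuropil_coupling * B(t) +
    Gaussian noise``; the neuropil channel is ``B(t)`` plus independent noise
    of the same SD, where ``B`` is a shared 1-s-smoothed background. Event
    amplitudes (in dF/F units) are lognormal with median ``snr`` times the
    per-frame noise SD expressed in dF/F units.
    """
    if not duration_s > 0 or not fs > 0:
        raise ValueError("duration_s and fs must be positive")
    if not 0 <= frac_hyper <= 1:
        raise ValueError("frac_hyper must lie in [0, 1]")
    if frac_hyper > 0 and not rate_hyper > 3.0:
        raise ValueError("rate_hyper must exceed 3/min when frac_hyper > 0")
    if not 0 <= neuropil_coupling < 1:
        raise ValueError("neuropil_coupling must lie in [0, 1)")
    if noise_sd < 0 or baseline <= 0:
        raise ValueError("noise_sd must be >= 0 and baseline > 0")

    rng_class, rng_events, rng_bg, rng_noise = _streams(seed, 4)
    n_frames = int(round(duration_s * fs))
    duration_min = duration_s / 60.0
    count_threshold = 3.0 * duration_min  # rate > 3/min  <=>  count > threshold

    n_hyper = int(round(frac_hyper * n_rois))
    is_hyper = np.zeros(n_rois, dtype=bool)
    is_hyper[rng_class.permutation(n_rois)[:n_hyper]] = True

    kernel = _double_exp_kernel(*kernel_params, fs=fs)
    sigma_dff = noise_sd / baseline if noise_sd > 0 else 0.01
    amp_median = snr * sigma_dff

    background = rng_bg.standard_normal(n_frames)
    background = gaussian_filter1d(background, sigma=max(fs, 1.0))
    bstd = background.std()
    if bstd > 0:
        background *= background_sd / bstd

    F = np.empty((n_rois, n_frames))
    Fn = np.empty((n_rois, n_frames))
    event_times: list[np.ndarray] = []
    amplitudes: list[np.ndarray] = []
    rates = np.empty(n_rois)
    classes: list[str] = []
    for i in range(n_rois):
        rate = rate_hyper if is_hyper[i] else rate_base
        count = _conditional_poisson_count(
            rng_events, rate * duration_min, count_threshold, above=bool(is_hyper[i])
        )
        times = np.sort(rng_events.uniform(0, duration_s, size=count))
        amps = amp_median * np.exp(0.25 * rng_events.standard_normal(count))
        dff_sig = np.zeros(n_frames)
        for tau, a in zip(times, amps):
            onset = int(math.floor(tau * fs))
            span = min(kernel.size, n_frames - onset)
            if span > 0:
                dff_sig[onset : onset + span] += a * kernel[:span]
        F[i] = (
            baseline * (1.0 + dff_sig)
            + neuropil_coupling * background
            + noise_sd * rng_noise.standard_normal(n_frames)
        )
        Fn[i] = background + noise_sd * rng_noise.standard_normal(n_frames)
        event_times.append(times)
        amplitudes.append(amps)
        rates[i] = count * 60.0 / duration_s
        classes.append(classify_activity(rates[i]))

    rec = FluorescenceRecording(
        F=F, Fn=Fn, fs=fs, animal_id=animal_id, genotype=genotype, layer=layer
    )
    truth = CalciumTruth(
        event_times_per_roi=event_times,
        rate_per_roi=rates,
        class_per_roi=classes,
        kernel_params=kernel_params,
        neuropil_coupling=neuropil_coupling,
        noise_sd=noise_sd,
        seed=seed,
        amplitudes_per_roi=amplitudes,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

@dataclass
class SpikeTruth:
    rate_per_unit: np.ndarray  # Hz
    depth_per_unit: np.ndarray  # um
    contaminated_flags: np.ndarray
    seed: int


def gen_spikes(
    n_units: int = 50,
    duration_s: float = 600.0,
    rate_log_mean: float = 0.0,
    rate_log_sd: float = 0.4,
    depth_range: tuple[float, float] = (0.0, 800.0),
    frac_contaminated: float = 0.0,
    contamination_fraction: float = 0.05,
    dead_time_ms: float = 2.5,
    seed: int = 0,
) -> tuple[list[SpikeUnit], SpikeTruth]:
    """Simulate spike-sorted units.

    Clean units are stationary renewal processes with exponential ISIs plus a
    2.5-ms dead time (zero refractory violations by construction); the
    exponential rate is adjusted so the mean ISI equals 1/rate. A quota of
    ``round(frac_contaminated * n_units)`` units receives injected doublet
    spikes at 0.5-1.5 ms after randomly chosen anchors so that the final
    violation fraction is about ``contamination_fraction``. Unit rates are
    log-normal: log10(rate in Hz) ~ N(rate_log_mean, rate_log_sd). Depths are
    uniform over ``depth_range``.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    if not depth_range or depth_range[1] <= depth_range[0]:
        raise ValueError("depth_range must be a non-empty (lo, hi) span")
    if not 0 <= frac_contaminated <= 1:
        raise ValueError("frac_contaminated must lie in [0, 1]")

    rng_rates, rng_isi, rng_contam, rng_depth = _streams(seed, 4)
    dead = dead_time_ms / 1000.0
    rates = 10.0 ** rng_rates.normal(rate_log_mean, rate_log_sd, size=n_units)
    if np.any(rates * dead >= 1):
        raise ValueError("a unit rate is too high for the dead time")
    depths = rng_depth.uniform(depth_range[0], depth_range[1], size=n_units)

    n_contam = int(round(frac_contaminated * n_units))
    contam = np.zeros(n_units, dtype=bool)
    contam[rng_contam.permutation(n_units)[:n_contam]] = True

    units: list[SpikeUnit] = []
    for i in range(n_units):
        r = rates[i]
        lam = r / (1.0 - r * dead)  # mean ISI = dead + 1/lam = 1/r
        n_draw = int(r * duration_s + 10 * math.sqrt(r * duration_s) + 50)
        isis = dead + rng_isi.exponential(1.0 / lam, size=n_draw)
        times = np.cumsum(isis)
        while times[-1] < duration_s:  # pragma: no cover - rare top-up
            extra = dead + rng_isi.exponential(1.0 / lam, size=n_draw)
            times = np.concatenate([times, times[-1] + np.cumsum(extra)])
        times = times[times < duration_s]
        if contam[i] and times.size >= 2:
            f = contamination_fraction
            n_inj = max(1, int(math.ceil(f * times.size / (1.0 - f))))
            anchors = rng_contam.choice(times.size, size=min(n_inj, times.size), replace=False)
            partners = times[anchors] + rng_contam.uniform(0.0005, 0.0015, size=anchors.size)
            partners = partners[partners < duration_s]
            times = np.sort(np.concatenate([times, partners]))
        units.append(SpikeUnit(unit_id=f"unit{i:04d}", spike_times=times, depth_um=depths[i]))

    truth = SpikeTruth(
        rate_per_unit=rates, depth_per_unit=depths, contaminated_flags=contam, seed=seed
    )
    return units, truth


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

@dataclass
class LfpTruth:
    band_power_targets: dict[str, float]  # integrated power (signal^2) per band
    n_channels: int
    common_offset_amplitude: float
    seed: int


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, power: float
) -> np.ndarray:
    """Gaussian noise with support exactly in [lo, hi] Hz and exact variance
    ``power``, synthesised in the frequency domain."""
    if power < 0:
        raise ValueError("band power targets must be >= 0")
    if power == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"band [{lo}, {hi}] Hz contains no FFT bins")
    spec = np.zeros(freqs.size, dtype=complex)
    m = int(mask.sum())
    spec[mask] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.irfft(spec, n=n)
    return x * math.sqrt(power / x.var())


def gen_lfp(
    duration_s: float = 600.0,
    fs_raw: float = 2500.0,
    n_channels: int = 4,
    band_power_targets: dict[str, float] | None = None,
    common_offset_amplitude: float = 0.0,
    n_reference_channels: int = 2,
    sensor_noise_sd: float = 0.0,
    bands: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[LfpRecording, LfpTruth]:
    """Simulate a probe-like multichannel LFP with exact per-band power.

    ``n_channels`` cortical channels each carry one shared band-limited
    Gaussian field (one component per entry of ``band_power_targets``: band
    name -> integrated power in signal-units squared, scaled exactly; band
    edges from ``bands``, default the slow / mid-gamma / high-gamma set) —
    the field is volume-conducted, hence coherent across nearby cortical
    sites. ``n_reference_channels`` further channels sit below cortex
    (depths > 800 um) and carry only the channel-common offset signal (RMS
    ``common_offset_amplitude``, 1-30 Hz) plus optional independent sensor
    noise, giving the preprocessing a reference set for common-mode removal.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_reference_channels < 0:
        raise ValueError("n_reference_channels must be >= 0")
    if duration_s < 80:
        raise ValueError("duration_s must be >= 80 s (two 40-s Welch windows)")
    band_edges = dict(DEFAULT_BANDS)
    if bands:
        band_edges.update(bands)
    if band_power_targets is None:
        band_power_targets = {name: 0.0 for name in band_edges}
    unknown = set(band_power_targets) - set(band_edges)
    if unknown:
        raise ValueError(f"targets for unknown bands: {sorted(unknown)}")
    nyq = fs_raw / 2.0
    for name in band_power_targets:
        if band_edges[name][1] > nyq:
            raise ValueError(f"band {name} above Nyquist {nyq} Hz")

    n = int(round(duration_s * fs_raw))
    rng_common, rng_field, rng_sensor = _streams(seed, 3)
    common = np.zeros(n)
    if common_offset_amplitude > 0:
        common = _band_limited_noise(rng_common, n, fs_raw, 1.0, min(30.0, nyq * 0.9), 1.0)
        common *= common_offset_amplitude
    field = np.zeros(n)
    for name, power in band_power_targets.items():
        lo, hi = band_edges[name]
        field = field + _band_limited_noise(rng_field, n, fs_raw, lo, hi, power)

    n_total = n_channels + n_reference_channels
    samples = np.empty((n_total, n))
    for c in range(n_total):
        x = common.copy()
        if c < n_channels:
            x = x + field
        if sensor_noise_sd > 0:
            x = x + sensor_noise_sd * rng_sensor.standard_normal(n)
        samples[c] = x
    depths = np.concatenate([
        np.linspace(100.0, 800.0, n_channels),
        np.linspace(900.0, 900.0 + 100.0 * max(n_reference_channels - 1, 0),
                    n_reference_channels),
    ])
    rec = LfpRecording(samples=samples, fs_raw=fs_raw, channel_depths=depths)
    truth = LfpTruth(
        band_power_targets=dict(band_power_targets),
        n_channels=n_channels,
        common_offset_amplitude=common_offset_amplitude,
        seed=seed,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

@dataclass
class ProteomeTruth:
    de_flags: np.ndarray
    true_log2fc: np.ndarray
    group_sizes: dict[str, int]
    variance_per_protein: np.ndarray
    ecm_labels: np.ndarray
    seed: int


def _ecm_probabilities(frac_de: float, frac_ecm: float, odds: float) -> tuple[float, float]:
    """P(ECM | DE) and P(ECM | not DE) with the requested odds ratio and
    marginal ECM fraction."""
    if frac_ecm <= 0:
        return 0.0, 0.0
    if odds == 1.0 or frac_de in (0.0, 1.0):
        return frac_ecm, frac_ecm

    def marginal(p0: float) -> float:
        o0 = p0 / (1 - p0)
        p1 = odds * o0 / (1 + odds * o0)
        return frac_de * p1 + (1 - frac_de) * p0 - frac_ecm

    # marginal(p0) is increasing with marginal(0) < 0 and marginal(1) > 0
    p0 = optimize.brentq(marginal, 1e-12, 1 - 1e-9)
    o0 = p0 / (1 - p0)
    p1 = odds * o0 / (1 + odds * o0)
    return p1, p0


def gen_proteome(
    n_proteins: int = 2000,
    group_sizes: dict[str, int] | None = None,
    frac_de: float = 0.1,
    lfc_location: float = 1.5,
    lfc_scale: float = 0.0,
    up_fraction: float = 0.7,
    var_mean: float = 0.04,
    var_shape: float = 4.0,
    var_heterogeneity: float = 0.0,
    frac_ecm: float = 0.1,
    ecm_de_odds: float = 5.0,
    seed: int = 0,
):
    """Simulate a log2 protein abundance table with group structure.

    The first key of ``group_sizes`` (default ``{"WT": 4, "GR400": 5}``) is
    the reference group. A deterministic quota of ``round(frac_de *
    n_proteins)`` proteins is differentially abundant: the non-reference
    groups are shifted by ``true_log2fc``, whose magnitude is
    ``lfc_location + lfc_scale * |N(0,1)|`` and whose sign is up with
    probability ``up_fraction``. Per-protein variances are inverse-gamma
    (shape ``var_shape``, mean ``var_mean``); when ``var_heterogeneity > 0``
    each non-reference group's variance is multiplied by
    ``exp(var_heterogeneity * N(0,1))`` so group variances are unequal. ECM
    labels are Bernoulli with odds ``ecm_de_odds`` higher among DE proteins
    at marginal fraction ``frac_ecm``.

    Returns ``(AbundanceTable, ProteomeTruth)``.
    """
    from .proteomics import AbundanceTable
    import pandas as pd

    if group_sizes is None:
        group_sizes = {"WT": 4, "GR400": 5}
    if any(sz < 2 for sz in group_sizes.values()):
        raise ValueError("every group size must be >= 2 (Welch test undefined otherwise)")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")

    rng_flags, rng_lfc, rng_var, rng_data, rng_ecm = _streams(seed, 5)
    n_de = int(round(frac_de * n_proteins))
    de = np.zeros(n_proteins, dtype=bool)
    de[rng_flags.permutation(n_proteins)[:n_de]] = True

    lfc = np.zeros(n_proteins)
    if n_de:
        mag = lfc_location + lfc_scale * np.abs(rng_lfc.standard_normal(n_de))
        sign = np.where(rng_lfc.random(n_de) < up_fraction, 1.0, -1.0)
        lfc[de] = sign * mag

    # inverse-gamma variances: mean = scale / (shape - 1)
    base_var = (var_mean * (var_shape - 1.0)) / rng_var.gamma(var_shape, 1.0, size=n_proteins)
    mu = rng_var.normal(20.0, 2.0, size=n_proteins)

    groups = list(group_sizes)
    sample_ids: list[str] = []
    group_labels: list[str] = []
    cols = []
    for gi, g in enumerate(groups):
        shift = 0.0 if gi == 0 else lfc
        gvar = base_var
        if gi > 0 and var_heterogeneity > 0:
            gvar = base_var * np.exp(var_heterogeneity * rng_var.standard_normal(n_proteins))
        sd = np.sqrt(gvar)
        for j in range(group_sizes[g]):
            sample = f"{g}_{j + 1}"
            sample_ids.append(sample)
            group_labels.append(g)
            cols.append(mu + shift + sd * rng_data.standard_normal(n_proteins))

    p_ecm_de, p_ecm_null = _ecm_probabilities(frac_de, frac_ecm, ecm_de_odds)
    ecm = np.where(de, rng_ecm.random(n_proteins) < p_ecm_de,
                   rng_ecm.random(n_proteins) < p_ecm_null)

    ids = [f"P{i:05d}" for i in range(n_proteins)]
    data = pd.DataFrame(np.column_stack(cols), index=ids, columns=sample_ids)
    table = AbundanceTable(
        data=data, groups=pd.Series(group_labels, index=sample_ids), min_valid_per_group=3
    )
    truth = ProteomeTruth(
        de_flags=de,
        true_log2fc=lfc,
        group_sizes=dict(group_sizes),
        variance_per_protein=base_var,
        ecm_labels=ecm,
        seed=seed,
    )
    return table, truth


def make_gene_sets(
    truth: ProteomeTruth, n_random_sets: int = 9, random_set_size: int | None = None, seed: int = 0
):
    """Gene sets with known truth for enrichment tests: one set of the
    ECM-labelled proteins plus random sets of comparable size."""
    from .proteomics import GeneSetCollection

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = truth.de_flags.size
    ids = np.array([f"P{i:05d}" for i in range(n)])
    ecm_ids = ids[truth.ecm_labels]
    if random_set_size is None:
        random_set_size = max(5, ecm_ids.size)
    sets = {"ECM": frozenset(ecm_ids)}
    for k in range(n_random_sets):
        members = rng.choice(ids, size=min(random_set_size, n), replace=False)
        sets[f"RANDOM_{k:02d}"] = frozenset(members)
    return GeneSetCollection(sets=sets, universe=frozenset(ids))


def make_regulator_network(truth: ProteomeTruth, n_decoys: int = 5, targets_per_decoy: int = 30,
                           seed: int = 0):
    """A regulator network with one true driver whose targets are the
    up-shifted ECM-labelled DE proteins (expected sign +1) plus random-decoy
    regulators."""
    from .proteomics import RegulatorNetwork

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = truth.de_flags.size
    ids = np.array([f"P{i:05d}" for i in range(n)])
    driver_targets = ids[truth.ecm_labels & truth.de_flags & (truth.true_log2fc > 0)]
    targets = {"DRIVER": [(t, 1) for t in driver_targets]}
    for k in range(n_decoys):
        members = rng.choice(ids, size=min(targets_per_decoy, n), replace=False)
        signs = rng.choice([-1, 1], size=members.size)
        targets[f"DECOY_{k:02d}"] = list(zip(members.tolist(), signs.tolist()))
    return RegulatorNetwork(targets=targets)
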