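"""Synthetic extracellular recording generator with known ground truth.

Emulates the experimental design the analysis modules assume: dorsal-striatal
medium spiny neurons (MSNs) of two molecular subtypes (D1 and D2), recorded as

* a wideband extracellular trace at 30 kHz containing spike waveforms plus
  Gaussian noise at a configurable signal-to-noise ratio,
* a local field potential (LFP) trace at 2 kHz consisting of a ``1/f``
  background plus a band-limited beta (12-30 Hz) oscillation whose amplitude
  is an experimental-group parameter,
* a 473 nm optogenetic stimulation protocol (10 Hz pulse trains, 20 ms
  pulses) during which ChR2-tagged (D2) units fire a short-latency evoked
  spike per pulse and/or modulate their Poisson rate, while D1 units are
  rate-suppressed.

Spiking is a homogeneous Poisson process thinned to a piecewise-constant rate
and pruned to an absolute refractory dead time.  All randomness flows from a
single master seed through named child streams, so a session is a pure
function of its configuration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GroundTruthUnit",
    "StimProtocol",
    "LFPSpec",
    "RecordingSession",
    "biphasic_template",
    "generate_spike_train",
    "render_wideband",
    "render_lfp",
    "make_session",
    "make_tagged_population",
    "sample_group_rates",
    "child_seed",
    "D2_RATE_PARAMS",
]

#: Group-level D2-MSN baseline firing statistics (mean_hz, sd_hz) used when
#: drawing per-unit rates for the four experimental groups: healthy controls
#: (C), exercised controls (CE), hemiparkinsonian (PD) and hemiparkinsonian
#: with aerobic training (PE).  The lesioned striatum shows elevated D2-MSN
#: firing that training partially normalises; CE is taken equal to C since
#: exercise alone does not change baseline MSN rates.
D2_RATE_PARAMS: Mapping[str, tuple[float, float]] = {
    "C": (1.72, 0.52),
    "CE": (1.72, 0.52),
    "PD": (6.40, 2.34),
    "PE": (4.28, 1.28),
}


def child_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic per-component seed (< 2**31) from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def biphasic_template(
    fs: float = 30_000.0,
    trough_to_peak_us: float = 400.0,
    pre_peak_us: float = 300.0,
    amplitude: float = 1.0,
    post_peak_frac: float = 0.5,
    pre_peak_frac: float = 0.25,
    trough_sigma_us: float = 80.0,
    peak_sigma_us: float = 120.0,
    window_us: tuple[float, float] = (-600.0, 1000.0),
) -> np.ndarray:
    """Analytic spike waveform: a sum of three Gaussians (pre-peak, trough,
    post-peak), trough-negative, with a known trough-to-peak interval.

    The lobe widths are small relative to the inter-lobe intervals so the
    extrema sit at the Gaussian centres to well under one sample at 30 kHz,
    which makes the ground-truth waveform metrics analytic:
    ``peak_trough_us == trough_to_peak_us`` and
    ``peak_peak_us == pre_peak_us + trough_to_peak_us``.
    ``amplitude`` is the absolute trough depth, in the same units as the
    wideband noise standard deviation (so amplitude / noise_sd is the SNR).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.arange(round(window_us[0] * fs * 1e-6), round(window_us[1] * fs * 1e-6) + 1)
    t_us = t / fs * 1e6
    w = -amplitude * np.exp(-0.5 * (t_us / trough_sigma_us) ** 2)
    w += amplitude * post_peak_frac * np.exp(
        -0.5 * ((t_us - trough_to_peak_us) / peak_sigma_us) ** 2
    )
    w += amplitude * pre_peak_frac * np.exp(
        -0.5 * ((t_us + pre_peak_us) / peak_sigma_us) ** 2
    )
    # renormalise so the trough depth is exactly `amplitude` despite the
    # (small) overlap of the positive lobes
    depth = -w.min()
    if depth > 0 and amplitude > 0:
        w *= amplitude / depth
    return w


@dataclass(frozen=True)
class GroundTruthUnit:
    """A simulated neuron: subtype, baseline rate, waveform and opto response.

    ``opto_modulation`` is the fractional rate change during stimulation
    pulses (stim rate = base_rate * (1 + opto_modulation), applied from
    ``opto_latency_ms`` after each pulse onset).  For positively modulated
    (tagged D2) units, each pulse additionally evokes a precisely timed spike
    at the opto latency with probability ``opto_response_prob``, emulating
    direct ChR2 drive.
    """

    unit_id: str
    subtype: str = "other"  # {"D1", "D2", "other"}
    base_rate: float = 2.0
    waveform_template: np.ndarray = field(default_factory=biphasic_template)
    refractory_ms: float = 2.0
    opto_latency_ms: float = 3.0
    opto_modulation: float = 0.0
    opto_response_prob: float = 1.0
    opto_latency_jitter_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.subtype not in ("D1", "D2", "other"):
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be > 0")
        if self.opto_latency_ms < 0:
            raise ValueError("opto_latency_ms must be >= 0")
        if self.opto_modulation < -1:
            raise ValueError("opto_modulation must be >= -1 (rate cannot go negative)")
        w = np.asarray(self.waveform_template, dtype=float)
        if w.ndim != 1 or w.size < 3:
            raise ValueError("waveform_template must be a 1-D array")


@dataclass(frozen=True)
class StimProtocol:
    """Optogenetic pulse-train protocol: pulse trains delivered in epochs.

    Defaults follow the in vivo tagging protocol: 10 Hz trains of 20 ms
    pulses of 473 nm blue light.
    """

    pulse_rate_hz: float = 10.0
    pulse_width_ms: float = 20.0
    epoch_onsets: tuple[float, ...] = (60.0,)
    epoch_durations: tuple[float, ...] = (60.0,)
    wavelength_nm: float = 473.0  # metadata only

    def __post_init__(self) -> None:
        if self.pulse_rate_hz <= 0 or self.pulse_width_ms <= 0:
            raise ValueError("pulse_rate_hz and pulse_width_ms must be > 0")
        if self.pulse_width_ms * self.pulse_rate_hz / 1000.0 >= 1.0:
            raise ValueError("duty cycle must be < 1")
        if len(self.epoch_onsets) != len(self.epoch_durations):
            raise ValueError("epoch_onsets and epoch_durations must align")
        onsets = np.asarray(self.epoch_onsets, dtype=float)
        durs = np.asarray(self.epoch_durations, dtype=float)
        if np.any(durs <= 0) or np.any(onsets < 0):
            raise ValueError("epochs must have positive duration and onset >= 0")
        ends = onsets + durs
        order = np.argsort(onsets)
        if np.any(ends[order][:-1] > onsets[order][1:]):
            raise ValueError("stimulation epochs must not overlap")

    @property
    def pulse_width_s(self) -> float:
        return self.pulse_width_ms / 1000.0

    def pulse_onsets(self, duration: float | None = None) -> np.ndarray:
        """Onset times (s) of every light pulse, optionally clipped to
        ``duration``."""
        onsets = []
        for t0, d in zip(self.epoch_onsets, self.epoch_durations):
            n = int(np.floor(d * self.pulse_rate_hz))
            onsets.append(t0 + np.arange(n) / self.pulse_rate_hz)
        out = np.sort(np.concatenate(onsets)) if onsets else np.empty(0)
        if duration is not None:
            out = out[out + self.pulse_width_s <= duration]
        return out

    def total_on_time(self, duration: float | None = None) -> float:
        return self.pulse_onsets(duration).size * self.pulse_width_s

    def first_epoch_onset(self) -> float:
        return float(min(self.epoch_onsets))


@dataclass(frozen=True)
class LFPSpec:
    """Parametric LFP model: 1/f background plus a band-limited beta bump."""

    one_over_f_exponent: float = 1.0
    beta_center_hz: float = 20.0
    beta_bandwidth_hz: float = 8.0
    beta_amplitude: float = 0.0
    broadband_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_amplitude < 0 or self.broadband_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.beta_bandwidth_hz <= 0:
            raise ValueError("beta_bandwidth_hz must be > 0")


@dataclass
class RecordingSession:
    """One simulated recording: wideband + LFP traces, pulse times and the
    ground-truth sidecar (per-unit spike times and subtype labels)."""

    wideband: np.ndarray
    lfp: np.ndarray
    pulse_times: np.ndarray
    duration: float
    fs_wideband: float = 30_000.0
    fs_lfp: float = 2_000.0
    ground_truth: dict[str, dict] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for trace, fs, name in (
            (self.wideband, self.fs_wideband, "wideband"),
            (self.lfp, self.fs_lfp, "lfp"),
        ):
            expected = self.duration * fs
            if abs(len(trace) - expected) > 1:
                raise ValueError(
                    f"{name} length {len(trace)} inconsistent with "
                    f"duration {self.duration} s at {fs} Hz"
                )
        pt = np.asarray(self.pulse_times, dtype=float)
        if pt.size and (np.any(np.diff(pt) <= 0) or pt[0] < 0 or pt[-1] > self.duration):
            raise ValueError("pulse_times must be strictly increasing within [0, duration]")


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy left-to-right pruning so consecutive gaps are >= refractory_s."""
    if times.size == 0:
        return times
    keep = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory_s:
            keep.append(t)
            last = t
    return np.asarray(keep)


def generate_spike_train(
    unit: GroundTruthUnit,
    duration: float,
    protocol: StimProtocol | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate one unit's spike times (s) over ``[0, duration)``.

    Baseline firing is Poisson at ``unit.base_rate``; within each stimulation
    pulse the rate becomes ``base_rate * (1 + opto_modulation)`` starting
    ``opto_latency_ms`` after pulse onset (thinning of a homogeneous process
    at the maximum rate).  Positively modulated units additionally receive
    one evoked spike per pulse at the opto latency with probability
    ``opto_response_prob``.  An absolute refractory dead time is then imposed
    greedily; this trims the realised rate by roughly ``base_rate *
    refractory`` (about 1% at typical MSN rates).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if unit.base_rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    r_max = unit.base_rate * (1.0 + max(unit.opto_modulation, 0.0))

    n_cand = rng.poisson(r_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))

    if protocol is not None and unit.opto_modulation != 0.0:
        onsets = protocol.pulse_onsets(duration)
        lat = unit.opto_latency_ms / 1000.0
        starts = onsets + np.minimum(lat, protocol.pulse_width_s)
        ends = onsets + protocol.pulse_width_s
        # index of the modulated window each candidate falls into, if any
        idx = np.searchsorted(starts, cand, side="right") - 1
        in_win = (idx >= 0) & (cand < ends[np.clip(idx, 0, None)])
        rate = np.where(in_win, unit.base_rate * (1.0 + unit.opto_modulation), unit.base_rate)
    else:
        rate = np.full(cand.shape, unit.base_rate)
    spikes = cand[rng.uniform(0.0, r_max, cand.shape) < rate]

    if (
        protocol is not None
        and unit.opto_modulation > 0.0
        and unit.opto_response_prob > 0.0
    ):
        onsets = protocol.pulse_onsets(duration)
        fire = rng.uniform(size=onsets.shape) < unit.opto_response_prob
        evoked = onsets[fire] + unit.opto_latency_ms / 1000.0
        if unit.opto_latency_jitter_ms > 0:
            evoked = evoked + rng.normal(
                0.0, unit.opto_latency_jitter_ms / 1000.0, evoked.shape
            )
        evoked = evoked[(evoked >= 0) & (evoked < duration)]
        spikes = np.sort(np.concatenate([spikes, evoked]))

    return _enforce_refractory(np.sort(spikes), unit.refractory_ms / 1000.0)


def render_wideband(
    trains: Mapping[str, np.ndarray],
    templates: Mapping[str, np.ndarray],
    noise_sd: float,
    fs: float,
    duration: float,
    seed: int = 0,
    trough_index: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Superimpose spike templates on i.i.d. Gaussian noise.

    Each template is inserted so that its trough (global minimum, unless
    ``trough_index`` overrides it) lands on the sample nearest the spike
    time.  The achieved SNR of a unit is ``max(|template|) / noise_sd``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    trace = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    for uid, times in trains.items():
        tpl = np.asarray(templates[uid], dtype=float)
        t_idx = int(np.argmin(tpl)) if trough_index is None else trough_index[uid]
        centers = np.round(np.asarray(times) * fs).astype(int)
        for c in centers:
            a = c - t_idx
            b = a + tpl.size
            lo, hi = max(a, 0), min(b, n)
            if lo < hi:
                trace[lo:hi] += tpl[lo - a : hi - a]
    return trace


def achieved_snr(template: np.ndarray, noise_sd: float) -> float:
    """SNR as defined for unit inclusion: template peak absolute amplitude
    over noise standard deviation."""
    if noise_sd <= 0:
        return np.inf
    return float(np.max(np.abs(template)) / noise_sd)


def render_lfp(spec: LFPSpec, duration: float, fs: float, seed: int = 0) -> np.ndarray:
    """Synthesize an LFP trace: spectrally shaped 1/f^a background plus a
    band-limited Gaussian beta component scaled to SD ``beta_amplitude``."""
    from scipy import signal

    if fs < 2.0 * (spec.beta_center_hz + spec.beta_bandwidth_hz):
        raise ValueError(
            "sampling rate violates the Nyquist requirement for the beta band"
        )
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    white = rng.standard_normal(n)
    spec_w = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    if spec.one_over_f_exponent != 0.0:
        with np.errstate(divide="ignore"):
            shape = np.where(freqs > 0, freqs ** (-spec.one_over_f_exponent / 2.0), 0.0)
    spec_w[0] = 0.0
    background = np.fft.irfft(spec_w * shape, n)
    sd = background.std()
    if sd > 0 and spec.broadband_sd > 0:
        background *= spec.broadband_sd / sd
    else:
        background = np.zeros(n)

    trace = background
    if spec.beta_amplitude > 0:
        lo = spec.beta_center_hz - spec.beta_bandwidth_hz / 2.0
        hi = spec.beta_center_hz + spec.beta_bandwidth_hz / 2.0
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        beta = signal.sosfiltfilt(sos, rng.standard_normal(n))
        beta *= spec.beta_amplitude / beta.std()
        trace = trace + beta
    return trace


def make_session(
    units: Sequence[GroundTruthUnit],
    protocol: StimProtocol | None = None,
    lfp_spec: LFPSpec | None = None,
    duration: float = 120.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    fs_wideband: float = 30_000.0,
    fs_lfp: float = 2_000.0,
) -> RecordingSession:
    """Assemble a full annotated recording session.

    Deterministic: the same units, protocol and seed reproduce the session
    bit for bit.  The ground-truth sidecar carries each unit's spike times,
    subtype and generating parameters.
    """
    lfp_spec = lfp_spec or LFPSpec()
    trains: dict[str, np.ndarray] = {}
    templates: dict[str, np.ndarray] = {}
    ground_truth: dict[str, dict] = {}
    for unit in units:
        s = child_seed(seed, f"train:{unit.unit_id}")
        times = generate_spike_train(unit, duration, protocol, seed=s)
        trains[unit.unit_id] = times
        templates[unit.unit_id] = np.asarray(unit.waveform_template, dtype=float)
        ground_truth[unit.unit_id] = {
            "spike_times": times,
            "subtype": unit.subtype,
            "base_rate": unit.base_rate,
            "opto_modulation": unit.opto_modulation,
            "opto_latency_ms": unit.opto_latency_ms,
        }
    wideband = render_wideband(
        trains,
        templates,
        noise_sd=noise_sd,
        fs=fs_wideband,
        duration=duration,
        seed=child_seed(seed, "wideband-noise"),
    )
    lfp = render_lfp(lfp_spec, duration, fs_lfp, seed=child_seed(seed, "lfp"))
    pulse_times = (
        protocol.pulse_onsets(duration) if protocol is not None else np.empty(0)
    )
    return RecordingSession(
        wideband=wideband,
        lfp=lfp,
        pulse_times=pulse_times,
        duration=duration,
        fs_wideband=fs_wideband,
        fs_lfp=fs_lfp,
        ground_truth=ground_truth,
        seed=seed,
    )


def sample_group_rates(
    group: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-unit D2-MSN baseline rates for an experimental group from a
    gamma distribution matched to the group's mean and SD (see
    :data:`D2_RATE_PARAMS`)."""
    try:
        mean, sd = D2_RATE_PARAMS[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected one of {list(D2_RATE_PARAMS)}")
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, n)


def make_tagged_population(
    n_d1: int = 12,
    n_d2: int = 20,
    n_other: int = 3,
    d1_modulation: float = -0.5,
    d2_modulation: float = 0.5,
    opto_latency_ms: float = 3.0,
    rate_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
    fs: float = 30_000.0,
) -> list[GroundTruthUnit]:
    """Build a mixed MSN population with the identified-unit composition of
    a tagging experiment (default 12 D1, 20 D2, 3 unresponsive of 35).

    D2 units are light-activated (positive modulation plus an evoked spike
    per pulse at the opto latency); D1 units are light-suppressed with no
    evoked response; 'other' units ignore the light.
    """
    rng = np.random.default_rng(seed)
    units = []
    specs = [("D1", n_d1, d1_modulation), ("D2", n_d2, d2_modulation), ("other", n_other, 0.0)]
    for subtype, count, mod in specs:
        for i in range(count):
            rate = float(rng.uniform(*rate_range))
            ttp = float(rng.uniform(350.0, 600.0))
            units.append(
                GroundTruthUnit(
                    unit_id=f"{subtype}_{i:02d}",
                    subtype=subtype,
                    base_rate=rate,
                    waveform_template=biphasic_template(
                        fs=fs, trough_to_peak_us=ttp, amplitude=6.0
                    ),
                    opto_modulation=mod,
                    opto_latency_ms=opto_latency_ms,
                    opto_response_prob=1.0 if mod > 0 else 0.0,
                )
            )
    return units
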