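"""Synthetic multi-subject EEG for the isochronous-tone paradigm.

Each subject's recording is a sum of three components on every channel,
scaled by a fronto-central spatial gain profile:

* a tone-locked biphasic evoked kernel (an N100-like deflection peaking
  ``evoked_latency`` after each tone onset, with per-tone Gaussian
  latency jitter),
* entrained sinusoids at the stimulation frequency Sf (and a weaker
  companion in the theta range) whose per-sequence starting phase is
  von Mises distributed and whose within-sequence phase-jitter SD
  decreases linearly in time — this linear decrease is what produces a
  positive time-resolved phase-coherence slope downstream,
* a 1/f^chi ("fractal") background, independent across channels.

All generative parameters are retained in a manifest so recovery can be
checked against ground truth.  Randomness flows from one master seed
through named ``numpy.random.SeedSequence`` substreams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import ParadigmSpec, make_paradigm

__all__ = [
    "FC_CLUSTER",
    "DEFAULT_CHANNELS",
    "SubjectParams",
    "Recording",
    "synth_noise",
    "synth_subject",
    "synth_cohort",
]

#: The 16-channel fronto-central cluster over which endpoints are averaged.
FC_CLUSTER: tuple[str, ...] = (
    "AFz", "AF3", "AF4", "F3", "F4", "F5", "F6", "FCz",
    "FC3", "FC4", "FC5", "FC6", "C1", "C2", "C3", "C4",
)

#: Default synthetic montage: the FC cluster plus posterior channels.
DEFAULT_CHANNELS: tuple[str, ...] = FC_CLUSTER + (
    "CPz", "Pz", "P3", "P4", "POz", "O1", "O2", "Oz",
)

#: Gain of the evoked/entrained signal on channels outside the FC cluster.
NON_FC_GAIN = 0.4

#: Silence between the last tone offset of a sequence and the first tone
#: of the next (response screen + inter-trial interval collapsed).
SEQUENCE_GAP_S = 2.5

#: Padding before the first and after the last sequence, seconds.
EDGE_PAD_S = 4.0


@dataclass
class SubjectParams:
    """Generative parameters for one synthetic subject.

    Amplitudes are in arbitrary EEG-like units (think microvolts).

    Attributes
    ----------
    group : str
        Group label, e.g. ``"young"`` or ``"old"``.
    evoked_amp : float
        Signed depth of the N100-like kernel at its peak (negative for
        the canonical negativity).
    evoked_latency : float
        Kernel peak time after tone onset, seconds.
    latency_jitter_sd : float
        SD of the per-tone Gaussian latency jitter, seconds.
    aperiodic_exponent : float
        chi of the 1/f^chi background (>= 0).
    aperiodic_offset : float
        log10 of the background PSD at 1 Hz (units^2/Hz).
    entrain_amp : float
        Amplitude of the entrained sinusoid at Sf.
    phase_kappa : float
        von Mises concentration of the per-sequence starting phase;
        ``inf`` means perfectly locked, 0 means uniform.
    phase_jitter_sd : float
        Initial within-sequence phase-jitter SD, radians.
    buildup_rate : float
        Linear decrease rate of the within-sequence phase-jitter SD,
        radians/second; larger values give a steeper coherence build-up.
    entrain_amp_theta : float
        Amplitude of the companion entrained sinusoid in the theta range.
    theta_freq : float
        Frequency of the theta companion, Hz (default the 4th harmonic
        of Sf, ~6.15 Hz).
    alpha_amp : float
        RMS of the endogenous (non-stimulus-locked) alpha rhythm, a
        narrow-band Gaussian process centred at ``alpha_freq``.  Real
        EEG carries such a rhythm regardless of age; because it is not
        phase-locked to the tones it floors the alpha-band coherence.
    alpha_freq : float
        Centre frequency of the endogenous rhythm, Hz.
    intercept_dev : float
        Additive participant offset applied to the evoked amplitude
        (random-intercept analogue).
    """

    group: str = "young"
    evoked_amp: float = -4.0
    evoked_latency: float = 0.100
    latency_jitter_sd: float = 0.008
    aperiodic_exponent: float = 1.2
    aperiodic_offset: float = -0.5
    entrain_amp: float = 1.0
    phase_kappa: float = 4.0
    phase_jitter_sd: float = 1.0
    buildup_rate: float = 0.15
    entrain_amp_theta: float = 0.25
    theta_freq: float = 4.0 / 0.650
    alpha_amp: float = 1.0
    alpha_freq: float = 10.0
    intercept_dev: float = 0.0

    def validate(self) -> None:
        if self.latency_jitter_sd < 0:
            raise ValueError("latency_jitter_sd must be >= 0")
        if self.phase_kappa < 0:
            raise ValueError("phase_kappa must be >= 0")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        if self.phase_jitter_sd < 0:
            raise ValueError("phase_jitter_sd must be >= 0")


@dataclass
class Recording:
    """Continuous multi-channel time series.

    ``data`` is channels x samples; ``fs`` in Hz.  Channel labels are
    unique and ordered.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = "S00"
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channel_labels),
                         self.subject_id, self.group)


def synth_noise(
    exponent: float,
    offset: float,
    n_samples: int,
    fs: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Generate power-law ("fractal") noise by spectral shaping.

    White Gaussian noise is shaped in the Fourier domain so that the
    one-sided PSD follows ``10**offset * f**(-exponent)`` in units^2/Hz.
    ``exponent = 0`` gives white noise with PSD ``10**offset``.

    Raises
    ------
    ValueError
        If ``exponent < 0`` or ``n_samples <= 16``.
    """
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")
    if n_samples <= 16:
        raise ValueError("n_samples must exceed 16")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    # white Gaussian (sigma=1) has one-sided PSD 2/fs; |H|^2 rescales it
    shape[nz] = np.sqrt(10.0 ** offset * freqs[nz] ** (-exponent) * fs / 2.0)
    return np.fft.irfft(spec * shape, n=n_samples)


def _narrowband_noise(center: float, sigma: float, rms: float, n_samples: int,
                      fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian process with a Gaussian spectral bump (endogenous rhythm)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    x = np.fft.irfft(spec * shape, n=n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _evoked_kernel(fs: float, amp: float, latency: float) -> tuple[np.ndarray, int]:
    """Biphasic N100-like kernel sampled at ``fs``.

    Main lobe: Gaussian (50 ms SD) peaking at ``latency``; a smaller
    opposite-sign lobe 100 ms later (75 ms SD).  Both lobes are
    evaluated over their full +-4 SD support so the kernel starts and
    ends smoothly — the wide, smooth lobes keep the kernel's energy
    below ~8 Hz, so tone-locked responses do not leak phase-locking
    into the alpha/beta bands.  Scaled so the extremum equals ``amp``
    exactly on the sample grid.  Returns the kernel and the sample
    offset of its first sample relative to the tone onset (negative:
    the smooth rise begins slightly before the onset).
    """
    sd1, sd2 = 0.050, 0.075
    t0 = latency - 4 * sd1

    def _shape(center: float, t: np.ndarray) -> np.ndarray:
        return (np.exp(-0.5 * ((t - center) / sd1) ** 2)
                - 0.4 * np.exp(-0.5 * ((t - center - 0.100) / sd2) ** 2))

    # the opposite-sign lobe pulls the combined extremum ~7 ms earlier
    # than the main-lobe centre; recentre so the extremum is at latency
    t_fine = np.arange(t0, latency + 0.100 + 4 * sd2, 1e-4)
    center = latency
    for _ in range(3):
        center += latency - t_fine[np.argmax(np.abs(_shape(center, t_fine)))]
    t = np.arange(t0, latency + 0.100 + 4 * sd2, 1.0 / fs)
    shape = _shape(center, t)
    peak = np.max(np.abs(shape))
    return amp * shape / peak, int(round(t0 * fs))


def _phase_jitter_track(
    tone_times: np.ndarray,
    t_grid: np.ndarray,
    sd0: float,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-linear phase-offset track with linearly shrinking SD.

    One Gaussian draw per tone time with SD ``max(0, sd0 - rate * t)``,
    linearly interpolated over ``t_grid`` (times relative to sequence
    start), constant beyond the first/last tone.
    """
    sds = np.clip(sd0 - rate * tone_times, 0.0, None)
    draws = rng.standard_normal(len(tone_times)) * sds
    return np.interp(t_grid, tone_times, draws)


def _sequence_starts(events: pd.DataFrame, spec: ParadigmSpec,
                     snap_hz: float = 250.0) -> np.ndarray:
    """Absolute start time of each sequence, snapped to the 1/snap_hz grid."""
    n_tones = events.groupby("sequence_id")["position"].max().sort_index().to_numpy()
    durations = (n_tones - 1) * spec.ioi + spec.tone_dur
    starts = EDGE_PAD_S + np.concatenate(
        ([0.0], np.cumsum(durations[:-1] + SEQUENCE_GAP_S)))
    return np.round(starts * snap_hz) / snap_hz


def synth_subject(
    spec: ParadigmSpec,
    params: SubjectParams,
    channels: list[str] | tuple[str, ...] = DEFAULT_CHANNELS,
    fs: float = 500.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "S00",
) -> tuple[Recording, pd.DataFrame]:
    """Simulate one subject's continuous recording and its event table.

    The returned events carry both the within-sequence ``onset`` and the
    absolute ``onset_abs`` in recording time.  Signal length covers all
    sequences plus 4 s padding on both sides; sequences are separated by
    2.5 s of silence (background noise only).
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if len(channels) == 0:
        raise ValueError("channels must be nonempty")
    params.validate()
    spec.validate()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_paradigm, ss_evoked, ss_phase, ss_noise = ss.spawn(4)

    events = make_paradigm(spec, np.random.default_rng(ss_paradigm))
    starts = _sequence_starts(events, spec)
    events = events.copy()
    events["onset_abs"] = starts[events["sequence_id"].to_numpy()] + events["onset"]

    seq_last_onset = events.groupby("sequence_id")["onset_abs"].max().sort_index()
    total_dur = float(seq_last_onset.iloc[-1]) + spec.tone_dur + EDGE_PAD_S
    # a few samples of slack so the final epoch's inclusive end sample
    # survives integer decimation during downsampling
    n_samples = int(round(total_dur * fs)) + 5
    t = np.arange(n_samples) / fs

    signal = np.zeros(n_samples)

    # --- tone-locked evoked responses -------------------------------------
    rng_ev = np.random.default_rng(ss_evoked)
    kernel, k_off = _evoked_kernel(fs, params.evoked_amp + params.intercept_dev,
                                   params.evoked_latency)
    onsets = events["onset_abs"].to_numpy()
    jitters = rng_ev.standard_normal(len(onsets)) * params.latency_jitter_sd
    for onset, jit in zip(onsets, jitters):
        i0 = int(round((onset + jit) * fs)) + k_off
        i1 = min(i0 + len(kernel), n_samples)
        if i0 < 0 or i0 >= n_samples:
            continue
        signal[i0:i1] += kernel[: i1 - i0]

    # --- entrained oscillations at Sf and its theta companion -------------
    # entrainment is anticipatory alignment to the stimulus: lock the
    # oscillation's phase reference to the evoked train's phase at the
    # same frequency so a concentrated starting phase (large kappa)
    # adds constructively to the tone-locked response
    k_times = (np.arange(len(kernel)) + k_off) / fs
    rng_ph = np.random.default_rng(ss_phase)
    ramp = 0.2  # raised-cosine on/off ramp, s
    for sid, grp in events.groupby("sequence_id"):
        t0 = float(starts[sid])
        t_end = float(grp["onset_abs"].max()) + spec.ioi
        i0, i1 = int(round(t0 * fs)), min(int(round(t_end * fs)), n_samples)
        tt = t[i0:i1] - t0
        tone_rel = grp["onset"].to_numpy()
        env = np.ones_like(tt)
        env[tt < ramp] = 0.5 * (1 - np.cos(np.pi * tt[tt < ramp] / ramp))
        tail = tt > (tt[-1] - ramp)
        env[tail] = 0.5 * (1 - np.cos(np.pi * (tt[-1] - tt[tail]) / ramp))
        for freq, amp in ((spec.sf, params.entrain_amp),
                          (params.theta_freq, params.entrain_amp_theta)):
            if amp == 0:
                continue
            phi_ev = np.angle(np.sum(kernel * np.exp(-2j * np.pi * freq * k_times)))
            if np.isinf(params.phase_kappa):
                phi0 = 0.0
            else:
                phi0 = rng_ph.vonmises(0.0, params.phase_kappa)
            track = _phase_jitter_track(tone_rel, tt, params.phase_jitter_sd,
                                        params.buildup_rate, rng_ph)
            signal[i0:i1] += amp * env * np.cos(
                2 * np.pi * freq * tt + phi_ev + phi0 + track)

    # --- spatial projection + per-channel 1/f background ------------------
    gains = np.array([1.0 if ch in FC_CLUSTER else NON_FC_GAIN for ch in channels])
    data = gains[:, None] * signal[None, :]
    noise_children = ss_noise.spawn(len(channels))
    for ci, child in enumerate(noise_children):
        rng_ch = np.random.default_rng(child)
        if params.aperiodic_offset > -np.inf:
            data[ci] += synth_noise(params.aperiodic_exponent,
                                    params.aperiodic_offset,
                                    n_samples, fs, rng_ch)
        if params.alpha_amp > 0:
            data[ci] += _narrowband_noise(params.alpha_freq, 1.0,
                                          params.alpha_amp, n_samples, fs,
                                          rng_ch)

    rec = Recording(data, fs, list(channels), subject_id=subject_id,
                    group=params.group)
    return rec, events


def synth_cohort(
    n_per_group: int = 18,
    group_params: dict[str, SubjectParams] | None = None,
    between_subject_sds: dict[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    spec: ParadigmSpec | None = None,
    channels: list[str] | tuple[str, ...] = DEFAULT_CHANNELS,
    fs: float = 500.0,
) -> tuple[list[tuple[Recording, pd.DataFrame]], pd.DataFrame]:
    """Simulate a two-group cohort with subject-level parameter scatter.

    Per-subject parameters are drawn around the group templates with
    Gaussian between-subject SDs (per-field, default 0), then clipped to
    validity.  Returns the recordings with their event tables and a
    manifest DataFrame of the true per-subject parameters.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (group inference undefined)")
    spec = spec or ParadigmSpec()
    if group_params is None:
        group_params = {"young": SubjectParams(group="young"),
                        "old": SubjectParams(group="old")}
    between_subject_sds = between_subject_sds or {}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_params, ss_subjects = ss.spawn(2)
    rng = np.random.default_rng(ss_params)

    nonneg = {"latency_jitter_sd", "phase_kappa", "aperiodic_exponent",
              "phase_jitter_sd", "entrain_amp", "entrain_amp_theta",
              "alpha_amp"}
    numeric = [f.name for f in dataclasses.fields(SubjectParams)
               if f.name != "group"]

    recordings: list[tuple[Recording, pd.DataFrame]] = []
    manifest_rows = []
    subject_seeds = ss_subjects.spawn(n_per_group * len(group_params))
    idx = 0
    for gname, template in group_params.items():
        for _ in range(n_per_group):
            vals = {}
            for name in numeric:
                v = getattr(template, name)
                sd = between_subject_sds.get(name, 0.0)
                if sd > 0:
                    v = v + rng.standard_normal() * sd
                if name in nonneg:
                    v = max(v, 0.0)
                vals[name] = v
            p = SubjectParams(group=gname, **vals)
            sub_id = f"S{idx:02d}"
            rec, ev = synth_subject(spec, p, channels, fs,
                                    subject_seeds[idx], subject_id=sub_id)
            recordings.append((rec, ev))
            manifest_rows.append({"subject_id": sub_id, "group": gname, **vals})
            idx += 1
    manifest = pd.DataFrame(manifest_rows)
    return recordings, manifest
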