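"""Inter-trial phase coherence and its time-resolved build-up.

ITPC at a frequency is the resultant length of the per-trial spectral
phases: each complex coefficient is divided by its magnitude (projected
onto the unit circle), the coefficients are averaged over trials, and
the magnitude of that complex mean is taken.  It is 1 when all trials
share a phase and tends to sqrt(pi)/(2 sqrt(N)) for N uniform phases.

The time-resolved variant (t-ITPC) applies the same statistic to
single-trial complex Morlet-wavelet coefficients (3 cycles, 0.2 Hz
grid), then averages the per-(channel, frequency) coherence over a
frequency band and the FC cluster.  Its least-squares linear slope from
the 3rd to the 8th tone onset quantifies the coherence build-up over
the sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .preprocess import Epochs
from .synth import FC_CLUSTER

__all__ = ["ITPCSpectrum", "TITPC", "SlopeFit", "BANDS", "itpc",
           "itpc_spectrum", "morlet_wavelet", "morlet_tf", "band_titpc",
           "t_itpc", "titpc_slope"]

#: Frequency-band edges, Hz.  Delta is centred on Sf (+-1 Hz) as the
#: band of primary interest; the others use conventional edges.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.54, 2.54),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 25.0),
}


@dataclass
class ITPCSpectrum:
    """Per-channel ITPC over a frequency grid."""

    freqs: np.ndarray
    itpc: np.ndarray          # channels x freqs, values in [0, 1] (or nan)
    channel_labels: list[str]
    n_trials: int

    def at(self, f: float, cluster: tuple[str, ...] = FC_CLUSTER) -> float:
        """Cluster-averaged ITPC at a grid frequency."""
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-6:
            raise ValueError(f"{f} Hz not on the ITPC grid")
        idx = [self.channel_labels.index(c) for c in cluster
               if c in self.channel_labels]
        return float(np.nanmean(self.itpc[idx, i]))


@dataclass
class TITPC:
    """Band- and cluster-averaged time-resolved phase coherence."""

    band: str
    band_edges: tuple[float, float]
    times: np.ndarray
    coherence: np.ndarray
    n_trials: int


@dataclass
class SlopeFit:
    """First-order polynomial fit of a t-ITPC series: p1 * t + p2."""

    p1: float     # slope, coherence / s
    p2: float     # intercept, coherence
    window: tuple[float, float]


def itpc(coeffs: np.ndarray, axis: int = 0) -> np.ndarray:
    """Resultant length of per-trial phases along ``axis``.

    Zero coefficients carry no phase; they are dropped from the mean
    with a warning.  Entries where every trial is zero come back nan.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    if coeffs.shape[axis] < 2:
        raise ValueError("need at least 2 trials for ITPC")
    mag = np.abs(coeffs)
    zero = mag == 0
    if zero.any():
        warnings.warn("zero coefficients dropped from ITPC")
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(zero, 0.0, coeffs / np.where(zero, 1.0, mag))
    n_valid = (~zero).sum(axis=axis)
    total = unit.sum(axis=axis)
    out = np.full(total.shape, np.nan)
    ok = n_valid > 0
    out[ok] = np.abs(total[ok]) / n_valid[ok]
    return out


def itpc_spectrum(spectra) -> ITPCSpectrum:
    """ITPC per channel and frequency from a SpectrumSet."""
    vals = itpc(spectra.complex_coeffs, axis=0)
    return ITPCSpectrum(freqs=spectra.freqs, itpc=vals,
                        channel_labels=list(spectra.channel_labels),
                        n_trials=spectra.n_trials)


def morlet_wavelet(freq: float, fs: float, cycles: float = 3.0,
                   zero_mean: bool = True) -> np.ndarray:
    """Complex Morlet wavelet: unit-norm Gaussian-windowed exponential.

    The temporal SD is ``cycles / (2 pi freq)``; support spans +-5 SD.
    With ``zero_mean`` the small DC leak of low-cycle wavelets is
    removed, matching the convention of standard M/EEG toolboxes.
    """
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    osc = np.exp(2j * np.pi * freq * t)
    if zero_mean:
        osc = osc - np.exp(-0.5 * (2.0 * np.pi * freq * sigma_t) ** 2)
    w = osc * np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    return w / np.linalg.norm(w)


def morlet_tf(
    epochs: Epochs,
    band: tuple[float, float] = BANDS["delta"],
    step: float = 0.2,
    cycles: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-trial complex Morlet transform on a 0.2 Hz grid in ``band``.

    Convolution ('same' mode) is done by FFT, batched over trials and
    channels.  No averaging happens before the transform, so downstream
    coherence reflects induced, single-trial phase.  Returns ``(tf,
    freqs, times)`` with ``tf`` of shape (trials, channels, freqs,
    times).

    Raises
    ------
    ValueError
        If the epochs are shorter than 3 cycles of the lowest band
        frequency (the wavelet would not fit).
    """
    if band[0] <= 0:
        raise ValueError("band low edge must be > 0 Hz")
    arr = epochs.to_array()
    n_ep, n_ch, n_t = arr.shape
    min_len = cycles / band[0]
    if n_t / epochs.fs < min_len:
        raise ValueError(
            f"epochs of {n_t / epochs.fs:.2f} s are too short for "
            f"{cycles} cycles at {band[0]} Hz (minimum {min_len:.2f} s)")
    freqs = np.arange(band[0], band[1] + step / 2, step)
    tf = np.empty((n_ep, n_ch, len(freqs), n_t), dtype=complex)
    for fi, conv in _morlet_conv_iter(arr, epochs.fs, freqs, cycles):
        tf[:, :, fi, :] = conv
    return tf, freqs, epochs.times()


def _morlet_conv_iter(arr: np.ndarray, fs: float, freqs: np.ndarray,
                      cycles: float):
    """Yield (freq index, 'same'-mode complex convolution) per frequency.

    Batched FFT convolution over (trials x channels); streaming one
    frequency at a time keeps peak memory at one (trials, channels,
    times) complex block regardless of how many band frequencies there
    are.
    """
    n_ep, n_ch, n_t = arr.shape
    wavelets = [morlet_wavelet(f, fs, cycles) for f in freqs]
    nfft = next_fast_len(n_t + max(len(w) for w in wavelets) - 1)
    data_f = fft(arr.reshape(n_ep * n_ch, n_t), nfft, axis=-1)
    for fi, w in enumerate(wavelets):
        wf = fft(w, nfft)
        conv = ifft(data_f * wf[None, :], axis=-1)
        start = (len(w) - 1) // 2
        yield fi, conv[:, start:start + n_t].reshape(n_ep, n_ch, n_t)


def band_titpc(
    epochs: Epochs,
    band: str = "delta",
    band_edges: tuple[float, float] | None = None,
    step: float = 0.2,
    cycles: float = 3.0,
    fc_cluster: tuple[str, ...] = FC_CLUSTER,
) -> TITPC:
    """Band- and cluster-averaged t-ITPC computed frequency by frequency.

    Numerically identical to ``t_itpc(*morlet_tf(...))`` but never
    materializes the full (trials, channels, freqs, times) array, so it
    is the route the pipeline takes for wide bands.
    """
    edges = band_edges or BANDS[band]
    idx = [epochs.channel_labels.index(c) for c in fc_cluster
           if c in epochs.channel_labels]
    if not idx:
        raise KeyError("no FC-cluster channels present")
    sub = epochs.pick([epochs.channel_labels[i] for i in idx])
    arr = sub.to_array()
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 trials for ITPC")
    if arr.shape[-1] / epochs.fs < cycles / edges[0]:
        raise ValueError(
            f"epochs too short for {cycles} cycles at {edges[0]} Hz "
            f"(minimum {cycles / edges[0]:.2f} s)")
    freqs = np.arange(edges[0], edges[1] + step / 2, step)
    acc = np.zeros(arr.shape[-1])
    for _, conv in _morlet_conv_iter(arr, epochs.fs, freqs, cycles):
        acc += itpc(conv, axis=0).mean(axis=0)   # coherence per ch x t -> t
    return TITPC(band=band, band_edges=edges, times=sub.times(),
                 coherence=acc / len(freqs), n_trials=arr.shape[0])


def t_itpc(
    tf: np.ndarray,
    times: np.ndarray,
    channel_labels: list[str],
    band: str = "delta",
    band_edges: tuple[float, float] | None = None,
    fc_cluster: tuple[str, ...] = FC_CLUSTER,
) -> TITPC:
    """Time-resolved ITPC, band- and FC-cluster averaged.

    Coherence is computed per (channel, frequency, time) across trials
    first — each value a well-defined quantity in [0, 1] — and only then
    averaged over band frequencies and cluster channels.
    """
    idx = [channel_labels.index(c) for c in fc_cluster if c in channel_labels]
    if not idx:
        raise KeyError("no FC-cluster channels present")
    coh = itpc(tf[:, idx, :, :], axis=0)      # ch x freq x time
    series = np.nanmean(coh, axis=(0, 1))
    return TITPC(band=band, band_edges=band_edges or BANDS.get(band, (np.nan,) * 2),
                 times=np.asarray(times), coherence=series, n_trials=tf.shape[0])


def titpc_slope(
    t: TITPC,
    ioi: float = 0.650,
    start_pos: int = 3,
    end_pos: int = 8,
) -> SlopeFit:
    """Least-squares line through the t-ITPC between two tone onsets.

    The window runs from the onset of ``start_pos`` to the onset of
    ``end_pos`` (inclusive of both boundary samples); with the default
    650 ms IOI that is [1.3, 4.55] s.
    """
    lo, hi = (start_pos - 1) * ioi, (end_pos - 1) * ioi
    sel = (t.times >= lo - 1e-9) & (t.times <= hi + 1e-9)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 t-ITPC samples in [{lo}, {hi}] s")
    p1, p2 = np.polyfit(t.times[sel], t.coherence[sel], 1)
    return SlopeFit(p1=float(p1), p2=float(p2), window=(lo, hi))
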