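"""Sequence spectra and oscillatory/fractal decomposition.

Spectra are computed on 8-s segments (first tone onset to 12th tone
offset) by direct projection of the Hann-tapered signal onto complex
sinusoids on a 0.2 Hz grid augmented with the exact stimulation
frequency Sf = 1/IOI.  An 8-s window has a native resolution of
0.125 Hz, so no FFT bin falls exactly on Sf; explicit projection
sidesteps zero-padding ambiguity and guarantees an Sf-anchored bin.
Per-trial complex coefficients are retained so the same object feeds
the phase-coherence analysis.

The aperiodic ("fractal") 1/f^chi component is fitted to the log-log
trial-averaged power spectrum by iteratively pruned least squares (the
no-knee spectral-parametrization model); subtracting it leaves the
"oscillatory" residual whose value at the Sf bin is the entrainment
endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Epochs
from .synth import FC_CLUSTER

__all__ = ["SpectrumSet", "AperiodicFit", "spectral_grid", "sequence_spectra",
           "fit_aperiodic", "oscillatory_component", "peak_at_sf",
           "subject_spectral_summary"]

SF_DEFAULT = 1.0 / 0.650


@dataclass
class SpectrumSet:
    """Per-trial complex spectra on a common frequency grid.

    ``complex_coeffs`` has shape (trials, channels, freqs); a unit-
    amplitude sinusoid at a grid frequency yields |coefficient| ~ 1.
    """

    freqs: np.ndarray
    complex_coeffs: np.ndarray
    channel_labels: list[str]
    taper: str = "hann"

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.complex_coeffs) ** 2

    @property
    def n_trials(self) -> int:
        return self.complex_coeffs.shape[0]

    def freq_index(self, f: float, tol: float = 1e-6) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > tol:
            raise ValueError(f"frequency {f} Hz not on the grid "
                             f"(nearest: {self.freqs[i]:.6f} Hz)")
        return i


@dataclass
class AperiodicFit:
    """No-knee aperiodic model: log10 P(f) = offset - exponent * log10 f."""

    offset: float
    exponent: float
    fit_range: tuple[float, float]
    residual_rms: float

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic power on a linear scale at the given frequencies."""
        return 10.0 ** (self.offset - self.exponent * np.log10(freqs))


def spectral_grid(sf: float = SF_DEFAULT, step: float = 0.2,
                  fmax: float = 40.0) -> np.ndarray:
    """The analysis grid {step, 2*step, ..., fmax} with Sf inserted."""
    base = np.arange(step, fmax + step / 2, step)
    if np.min(np.abs(base - sf)) > 1e-9:
        base = np.sort(np.append(base, sf))
    return base


def sequence_spectra(
    epochs: Epochs,
    sf: float = SF_DEFAULT,
    grid_step: float = 0.2,
    fmax: float = 40.0,
    duration: float = 8.0,
) -> SpectrumSet:
    """Hann-tapered spectra of the [0, 8] s portion of each sequence epoch.

    Coefficients are normalized so a unit-amplitude sinusoid at a grid
    frequency has magnitude ~1 (power ~1).

    Raises
    ------
    ValueError
        If any epoch does not cover [0, duration] s.
    """
    n = int(round(duration * epochs.fs))
    seg = epochs.crop(0.0, duration - 1.0 / epochs.fs)  # n samples from t=0
    arr = seg.to_array()
    if arr.shape[-1] != n:
        raise ValueError("segment length mismatch after crop")
    freqs = spectral_grid(sf, grid_step, fmax)
    t = np.arange(n) / epochs.fs
    w = np.hanning(n)
    basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, :]) * w[None, :]
    basis *= 2.0 / w.sum()
    coeffs = np.tensordot(arr, basis, axes=([2], [1]))  # trials x ch x freqs
    return SpectrumSet(freqs=freqs, complex_coeffs=coeffs,
                       channel_labels=list(epochs.channel_labels))


def fit_aperiodic(
    power: np.ndarray,
    freqs: np.ndarray,
    fit_range: tuple[float, float] = (0.5, 40.0),
    n_prune: int = 2,
    prune_percentile: float = 97.5,
) -> AperiodicFit:
    """Fit the 1/f aperiodic component by iteratively pruned least squares.

    An ordinary least-squares line is fitted to log10 power vs log10
    frequency over ``fit_range``; points whose positive residual exceeds
    the ``prune_percentile`` envelope (narrow-band peaks poking above
    the 1/f background) are dropped and the line refitted, twice.

    Parameters
    ----------
    power : 1-D array
        Trial-averaged power spectrum (non-negative; exact zeros are
        floored at machine epsilon).
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 1 or power.shape != freqs.shape:
        raise ValueError("power must be 1-D and aligned with freqs")
    if np.any(power < 0):
        raise ValueError("power values must be non-negative")
    mask = (freqs >= fit_range[0] - 1e-12) & (freqs <= fit_range[1] + 1e-12)
    if mask.sum() < 20:
        raise ValueError("need at least 20 grid points in the fit range")
    x = np.log10(freqs[mask])
    y = np.log10(np.maximum(power[mask], np.finfo(float).tiny))

    keep = np.ones_like(x, dtype=bool)
    slope, intercept = 0.0, 0.0
    for it in range(n_prune + 1):
        slope, intercept = np.polyfit(x[keep], y[keep], 1)
        resid = y - (intercept + slope * x)
        if it < n_prune:
            thr = np.percentile(resid[keep], prune_percentile)
            keep = keep & ~(resid > max(thr, 0.0) + 1e-12)
    resid = y[keep] - (intercept + slope * x[keep])
    return AperiodicFit(offset=float(intercept), exponent=float(-slope),
                        fit_range=fit_range,
                        residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def oscillatory_component(power: np.ndarray, freqs: np.ndarray,
                          fit: AperiodicFit) -> np.ndarray:
    """Residual spectrum: power minus the fitted aperiodic model."""
    return np.asarray(power, dtype=float) - fit.model(freqs)


def peak_at_sf(residual: np.ndarray, freqs: np.ndarray,
               sf: float = SF_DEFAULT) -> float:
    """Oscillatory residual at the Sf grid point (grid must be Sf-anchored)."""
    i = int(np.argmin(np.abs(freqs - sf)))
    if abs(freqs[i] - sf) > 1e-6:
        raise ValueError(f"Sf={sf} Hz is not on the frequency grid; use an "
                         "Sf-anchored grid (spectral_grid)")
    return float(residual[i])


def subject_spectral_summary(
    spectra: SpectrumSet,
    sf: float = SF_DEFAULT,
    fc_cluster: tuple[str, ...] = FC_CLUSTER,
    fit_range: tuple[float, float] = (0.5, 40.0),
    power_response: np.ndarray | None = None,
) -> dict:
    """FC-cluster endpoints for one subject.

    Averages power over trials and FC channels, fits the aperiodic
    component, and returns the Sf residual peak, the aperiodic offset
    and exponent, and the mean log10 fractal power over the fit range
    (the scalar used for the group comparison of the fractal component).

    ``power_response``, when given, is the known power transfer of the
    preprocessing filter chain on the spectral grid (see
    ``preprocess.chain_power_response``); the averaged power is divided
    by it so the attenuation near the anti-alias edge does not bias the
    1/f fit.
    """
    idx = [spectra.channel_labels.index(c) for c in fc_cluster
           if c in spectra.channel_labels]
    if not idx:
        raise KeyError("no FC-cluster channels present in the spectra")
    power = spectra.power[:, idx, :].mean(axis=(0, 1))
    if power_response is not None:
        power = power / power_response
    fit = fit_aperiodic(power, spectra.freqs, fit_range)
    resid = oscillatory_component(power, spectra.freqs, fit)
    mask = (spectra.freqs >= fit_range[0]) & (spectra.freqs <= fit_range[1])
    frac = fit.model(spectra.freqs[mask])
    return {
        "sf_peak_power": peak_at_sf(resid, spectra.freqs, sf),
        "aperiodic_offset": fit.offset,
        "aperiodic_exponent": fit.exponent,
        "mean_log_fractal_power": float(np.mean(np.log10(frac))),
        "residual_rms": fit.residual_rms,
    }
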