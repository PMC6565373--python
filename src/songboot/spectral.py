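"""Minimal spectral pitch estimator for synthetic waveforms.

Song syllables carry their pitch in the fundamental (lowest harmonic) of a
harmonic stack.  The estimator here takes a single Hann-windowed FFT of the
analysis window, finds the lowest-frequency spectral peak whose power
exceeds a fraction of the global maximum, and returns the power-weighted
mean frequency over a few bins around that peak.  It is exercised only on
synthesized tones and harmonic stacks; segmenting real song is out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile


class SpectralError(ValueError):
    pass


def extract_pitch(
    waveform: np.ndarray,
    sample_rate: float,
    window: tuple[float, float] | None = None,
    fmin: float = 200.0,
    rel_power_threshold: float = 0.1,
    n_side_bins: int = 3,
) -> float:
    """Estimate the fundamental frequency (Hz) of a windowed waveform.

    Parameters
    ----------
    waveform : mono audio samples.
    sample_rate : sampling rate in Hz.
    window : (start, stop) in seconds; ``None`` uses the whole signal.
    fmin : lowest candidate fundamental, Hz (skips DC / low-frequency noise).
    rel_power_threshold : a local maximum qualifies as the lowest harmonic
        only if its power is at least this fraction of the global maximum.
    n_side_bins : half-width, in FFT bins, of the power-weighted average
        around the selected peak.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise SpectralError("waveform must be mono (1-D)")
    if window is not None:
        i0, i1 = (int(round(t * sample_rate)) for t in window)
        if i0 < 0 or i1 > len(x) or i1 <= i0:
            raise SpectralError("analysis window outside the waveform")
        x = x[i0:i1]
    n = len(x)
    if n < 16:
        raise SpectralError("analysis window too short for spectral estimation")
    if not np.any(x):
        raise SpectralError("silent analysis window")

    spec = np.abs(np.fft.rfft(x * np.hanning(n)))
    power = spec**2
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)

    floor = rel_power_threshold * power.max()
    # local maxima above the relative-power floor, at/above fmin
    interior = np.arange(1, len(power) - 1)
    is_peak = (power[interior] >= power[interior - 1]) & (
        power[interior] > power[interior + 1]
    )
    cand = interior[is_peak & (power[interior] >= floor) & (freqs[interior] >= fmin)]
    if len(cand) == 0:
        raise SpectralError("no spectral peak above the power threshold")
    k = int(cand[0])  # lowest-frequency qualifying peak = lowest harmonic

    lo, hi = max(k - n_side_bins, 0), min(k + n_side_bins + 1, len(power))
    w = power[lo:hi]
    return float(np.sum(freqs[lo:hi] * w) / np.sum(w))


def harmonic_stack(
    f0: float,
    sample_rate: float,
    duration: float,
    harmonic_amps: tuple[float, ...] = (1.0,),
    rng: np.random.Generator | None = None,
    noise_amp: float = 0.0,
) -> np.ndarray:
    """Synthesize a harmonic stack (fundamental plus overtones) for testing."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    x = np.zeros_like(t)
    for h, amp in enumerate(harmonic_amps, start=1):
        x += amp * np.sin(2 * np.pi * f0 * h * t)
    if noise_amp > 0:
        if rng is None:
            rng = np.random.default_rng()
        x += noise_amp * rng.standard_normal(len(t))
    return x


def load_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono PCM WAV file, returning (samples scaled to [-1, 1], rate)."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise SpectralError("expected a mono WAV file")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return data.astype(float), float(rate)


def save_wav(path: str | Path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a float waveform to 16-bit PCM WAV."""
    x = np.asarray(waveform, dtype=float)
    peak = np.max(np.abs(x)) or 1.0
    pcm = np.round(x / peak * 32767).astype(np.int16)
    wavfile.write(path, int(sample_rate), pcm)
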