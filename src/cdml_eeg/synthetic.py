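"""Simulator for few-channel motor-imagery EEG sessions.

Emulates the cue-paced left/right-hand MI paradigm recorded at C3, Cz, C4:
each trial lasts ~8.5 s with the cue at t = 3 s and the imagery executed from
3 s to 7.5 s, separated by 1-2 s of rest; a session holds 160 balanced trials.

The physiology is reduced to its classification-relevant core. Every channel
carries 1/f^alpha background noise plus mu-band (8-13 Hz) and beta-band
(13-30 Hz) oscillations realised as band-limited filtered white noise (so the
spectra are realistically broad while band power stays analytically
controllable). During the imagery window, the channel contralateral to the
imagined hand expresses event-related desynchronization — its mu amplitude
drops by ``erd_depth`` — and event-related synchronization — its beta
amplitude rises by ``ers_gain`` — with smooth 0.25-s onset/offset ramps.
Left-hand imagery modulates C4, right-hand imagery modulates C3, and Cz is
deliberately left unmodulated so that single-channel ablations have a known
ordering (C3/C4 informative, Cz at chance). Volume conduction and ocular or
muscular artifacts are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import EventMarker, RawRecording

__all__ = ["SyntheticSpec", "simulate_trial", "simulate_session"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults are the paradigm's study conditions."""

    fs: float = 250.0
    n_trials: int = 160
    trial_seconds: float = 8.5
    trial_jitter: float = 0.0  # +- uniform jitter of trial length (s), e.g. 0.5
    cue_second: float = 3.0
    mi_window: tuple[float, float] = (3.0, 7.5)
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    mu_amp: float = 7.0      # uV RMS of the mu oscillation
    beta_amp: float = 3.5    # uV RMS of the beta oscillation
    erd_depth: float = 0.6   # fractional contralateral mu attenuation during MI
    ers_gain: float = 0.3    # fractional contralateral beta increase during MI
    noise_sigma: float = 20.0  # uV RMS of the 1/f^alpha background
    noise_exponent: float = 1.0
    ramp_seconds: float = 0.25
    rest_range: tuple[float, float] = (1.0, 2.0)  # inter-trial rest (s)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        for band in (self.mu_band, self.beta_band):
            if not 0 < band[0] < band[1] < self.fs / 2:
                raise ValueError(f"band {band} outside (0, Nyquist)")
        if self.n_trials % 2:
            raise ValueError("n_trials must be even (balanced classes)")


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite; it is centred out below
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order Butterworth on white noise)."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 4 * int(fs)))
    x = x[2 * int(fs):2 * int(fs) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _mi_envelope(n: int, spec: SyntheticSpec, depth: float) -> np.ndarray:
    """Multiplicative envelope: 1 outside the MI window, 1+depth inside,
    raised-cosine ramps of ``ramp_seconds`` at the window edges."""
    t = np.arange(n) / spec.fs
    lo, hi = spec.mi_window
    r = max(spec.ramp_seconds, 1.0 / spec.fs)
    shape = np.clip((t - lo) / r, 0.0, 1.0) * np.clip((hi - t) / r, 0.0, 1.0)
    smooth = 0.5 - 0.5 * np.cos(np.pi * np.clip(shape, 0.0, 1.0))
    return 1.0 + depth * smooth


def simulate_trial(spec: SyntheticSpec, label: str,
                   rng: np.random.Generator,
                   n_samples: int | None = None) -> np.ndarray:
    """One 3 x n trial (rows C3, Cz, C4, microvolts) with MI physiology.

    ``label`` is 'left' or 'right'; the contralateral channel (C4 for left,
    C3 for right) receives the ERD/ERS modulation.
    """
    if label not in ("left", "right"):
        raise ValueError("label must be 'left' or 'right'")
    n = n_samples or int(round(spec.trial_seconds * spec.fs))
    contra = {"left": 2, "right": 0}[label]  # row index: C3=0, Cz=1, C4=2

    erd_env = _mi_envelope(n, spec, -spec.erd_depth)
    ers_env = _mi_envelope(n, spec, +spec.ers_gain)

    trial = np.empty((3, n))
    for ch in range(3):
        mu = spec.mu_amp * _band_noise(n, spec.mu_band, spec.fs, rng)
        beta = spec.beta_amp * _band_noise(n, spec.beta_band, spec.fs, rng)
        if ch == contra:
            mu = mu * erd_env
            beta = beta * ers_env
        noise = spec.noise_sigma * _pink_noise(n, spec.noise_exponent, rng)
        trial[ch] = noise + mu + beta
    return trial


def simulate_session(spec: SyntheticSpec, subject_id: str = "S01",
                     rng: np.random.Generator | None = None) -> RawRecording:
    """A full session: balanced shuffled trials with cue markers and rest gaps."""
    rng = rng or np.random.default_rng(spec.seed)
    labels = ["left", "right"] * (spec.n_trials // 2)
    rng.shuffle(labels)

    chunks: list[np.ndarray] = []
    events: list[EventMarker] = []
    cursor = 0
    for label in labels:
        dur = spec.trial_seconds
        if spec.trial_jitter > 0:
            dur += rng.uniform(-spec.trial_jitter, spec.trial_jitter)
        n = int(round(dur * spec.fs))
        chunks.append(simulate_trial(spec, label, rng, n_samples=n))
        events.append(EventMarker(cursor + int(round(spec.cue_second * spec.fs)),
                                  label))
        cursor += n
        n_rest = int(round(rng.uniform(*spec.rest_range) * spec.fs))
        rest = np.stack([spec.noise_sigma
                         * _pink_noise(n_rest, spec.noise_exponent, rng)
                         for _ in range(3)])
        chunks.append(rest)
        cursor += n_rest

    return RawRecording(
        signals=np.concatenate(chunks, axis=1), fs=spec.fs,
        channel_labels=("C3", "Cz", "C4"), events=events, subject_id=subject_id)
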