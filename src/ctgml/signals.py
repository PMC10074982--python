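"""Fetal heart rate signal container, synthesis model, and text file I/O.

A trace is the last stretch of labour (by default 60 minutes at 4 Hz, the
usual cardiotocograph output rate).  The synthesis model is additive:

    fHR(t) = baseline
             + A * sin(2*pi*t / T + phase)         (slow oscillation)
             + eps(t),  eps ~ N(0, sigma^2)        (beat-scale noise)
             - sum_k depth_k * exp(-(t - c_k)^2 / (2 * w_k^2))  (decelerations)

clipped to the physiologic band [30, 240] bpm.  Deceleration onsets are a
Poisson process; depth and width are jittered per event.  The two
diagnostic groups differ in the noise level and in the deceleration
regime; the defaults in :mod:`ctgml.cohort` are calibrated so the
compression-ratio indices separate the groups as observed clinically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FhrSignal", "SignalParams", "generate_signal",
           "write_signal_file", "read_signal_file",
           "FHR_MIN_BPM", "FHR_MAX_BPM"]

FHR_MIN_BPM = 30.0
FHR_MAX_BPM = 240.0


@dataclass(frozen=True)
class FhrSignal:
    """One subject's fHR trace."""

    subject_id: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class SignalParams:
    """Per-group parameters of the additive fHR synthesis model.

    Units: bpm for amplitudes/depths, seconds for periods/widths,
    events/hour for the deceleration rate.
    """

    baseline_bpm: float = 135.0
    osc_amplitude: float = 2.0
    osc_amplitude_dispersion: float = 0.0
    osc_period_s: float = 60.0
    noise_sd: float = 0.005
    noise_sd_dispersion: float = 0.0
    alternation_amplitude: float = 0.0
    alternation_dispersion: float = 0.0
    decel_rate_per_hour: float = 2.0
    decel_depth_mean: float = 25.0
    decel_depth_sd: float = 8.0
    decel_width_s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "noise_sd_dispersion",
                     "osc_amplitude_dispersion", "alternation_amplitude",
                     "alternation_dispersion",
                     "decel_rate_per_hour", "decel_depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.osc_period_s <= 0 or self.decel_width_s <= 0:
            raise ValueError("periods and widths must be positive")


def generate_signal(params: SignalParams, sampling_rate: float,
                    duration: float, rng: np.random.Generator,
                    subject_id: str = "S0000") -> FhrSignal:
    """Synthesise one fHR trace of ``floor(sampling_rate * duration)`` samples."""
    if sampling_rate <= 0 or duration <= 0:
        raise ValueError("sampling_rate and duration must be positive")
    n = int(sampling_rate * duration)
    t = np.arange(n) / sampling_rate

    phase = rng.uniform(0.0, 2.0 * np.pi)
    # Per-subject oscillation amplitude and noise level: lognormal around
    # the group medians, so a cohort shows a spread of slow-variability and
    # of trace irregularity driven by two separate latents (as real traces
    # do) rather than one fixed regime.
    amplitude = params.osc_amplitude * float(
        np.exp(rng.normal(0.0, params.osc_amplitude_dispersion)))
    x = (params.baseline_bpm
         + amplitude * np.sin(2.0 * np.pi * t / params.osc_period_s + phase))
    noise_sd = params.noise_sd * float(np.exp(rng.normal(0.0, params.noise_sd_dispersion)))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    # Sample-to-sample alternation emulating an acquisition/sensor artifact
    # (its prevalence differs between monitor types).  It cancels exactly
    # under pairwise averaging, so it shapes scale-1 indices only.
    alt = params.alternation_amplitude * float(
        np.exp(rng.normal(0.0, params.alternation_dispersion)))
    if alt > 0:
        x = x + alt * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)

    n_decel = rng.poisson(params.decel_rate_per_hour * duration / 3600.0)
    for _ in range(n_decel):
        centre = rng.uniform(0.0, duration)
        depth = max(0.0, rng.normal(params.decel_depth_mean, params.decel_depth_sd))
        width = params.decel_width_s * rng.uniform(0.7, 1.3)
        x = x - depth * np.exp(-0.5 * ((t - centre) / width) ** 2)

    np.clip(x, FHR_MIN_BPM, FHR_MAX_BPM, out=x)
    return FhrSignal(subject_id=subject_id, samples=x, sampling_rate=sampling_rate)


def write_signal_file(signal: FhrSignal, path) -> None:
    """Write a signal as delimited text: a header line, then one sample per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"subject_id={signal.subject_id} "
                 f"sampling_rate={float(signal.sampling_rate)!r}\n")
        for v in signal.samples:
            fh.write(f"{float(v)!r}\n")


def read_signal_file(path) -> FhrSignal:
    """Read a signal written by :func:`write_signal_file`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        parts = dict(
            item.split("=", 1) for item in header.split() if "=" in item
        )
        if "subject_id" not in parts or "sampling_rate" not in parts:
            raise ValueError(
                f"{path}: missing 'subject_id=... sampling_rate=...' header"
            )
        values = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric sample {line!r}") from None
    if not values:
        raise ValueError(f"{path}: no samples")
    return FhrSignal(
        subject_id=parts["subject_id"],
        samples=np.array(values),
        sampling_rate=float(parts["sampling_rate"]),
    )
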