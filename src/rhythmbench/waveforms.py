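"""Unit waveform templates for rhythmic gene expression.

Four shapes cover the patterns seen among known cycling genes: a cosine,
an asymmetric ramp (sawtooth/triangle), a raised-cosine peak pulse, and a
rectangular box. Every template is unit-normalized: mean 0 and
peak-to-trough span 1 over one densely sampled period, so a gene's series
is ``baseline * (1 + rel_amplitude * template(t))``.

Phase conventions (hours, modulo the period):
  cosine  - peak at ``phase``
  ramp    - rise starts at ``phase``; argmax at ``phase + asymmetry*period``
  peak    - pulse centre at ``phase``; pulse width ``asymmetry*period``
  box     - high state starts at ``phase``; duty fraction ``asymmetry``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SHAPES = ("cosine", "ramp", "peak", "box")


@dataclass(frozen=True)
class WaveformSpec:
    shape: str
    period: float = 24.0
    phase: float = 0.0
    asymmetry: float = 0.5
    rel_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if not (self.period > 0):
            raise ValueError("period must be > 0")
        if not (0 < self.asymmetry < 1):
            raise ValueError("asymmetry must lie in (0, 1)")
        if self.rel_amplitude < 0:
            raise ValueError("rel_amplitude must be >= 0")


def _unit_template(shape: str, frac: np.ndarray, a: float) -> np.ndarray:
    """Template on the phase fraction ``frac`` in [0, 1); mean 0, span 1."""
    if shape == "cosine":
        return 0.5 * np.cos(2 * np.pi * frac)
    if shape == "ramp":
        # linear rise over [0, a), linear fall over [a, 1); peak at frac = a
        rise = -0.5 + frac / a
        fall = 0.5 - (frac - a) / (1 - a)
        return np.where(frac < a, rise, fall)
    if shape == "peak":
        # raised-cosine pulse of width a centred at frac = 0
        d = np.minimum(frac, 1 - frac)  # distance to the pulse centre
        raw = np.where(d <= a / 2, 0.5 * (1 + np.cos(2 * np.pi * d / a)), 0.0)
        return raw - a / 2  # analytic mean of the pulse is a/2
    if shape == "box":
        return np.where(frac < a, 1.0 - a, -a)
    raise ValueError(f"unknown shape {shape!r}")


def generate_waveform(spec: WaveformSpec, times) -> np.ndarray:
    """Evaluate the unit template at the requested times (hours).

    Deterministic; shifting ``phase`` by a full period reproduces identical
    values. The returned values have mean 0 and span 1 over a dense period.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    frac = ((t - spec.phase) / spec.period) % 1.0
    return _unit_template(spec.shape, frac, spec.asymmetry)
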