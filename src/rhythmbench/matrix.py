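"""Expression-matrix container and sample design.

The pipeline currency is a genes x timed-samples matrix together with a
per-sample design: time in hours since the first sample, a cycle label
(which 24 h day the sample belongs to) and a replicate label. Samples are
identified by column names of the form ``t<time>_c<cycle>_r<replicate>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COL_RE = re.compile(r"^t(?P<time>[0-9]*\.?[0-9]+)_c(?P<cycle>[0-9]+)_r(?P<rep>[0-9]+)$")


def sample_label(time: float, cycle: int, replicate: int) -> str:
    t = f"{float(time):g}"
    return f"t{t}_c{int(cycle)}_r{int(replicate)}"


def parse_sample_label(label: str) -> tuple[float, int, int]:
    m = _COL_RE.match(label)
    if m is None:
        raise ValueError(f"malformed sample column {label!r}; expected t<time>_c<cycle>_r<rep>")
    return float(m.group("time")), int(m.group("cycle")), int(m.group("rep"))


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample (time, cycle, replicate) description.

    ``time`` is absolute hours since the first sample of the experiment;
    ``cycle`` and ``replicate`` are 1-based integer labels.
    """

    time: tuple[float, ...]
    cycle: tuple[int, ...]
    replicate: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.cycle) != n or len(self.replicate) != n:
            raise ValueError("time, cycle, replicate must have equal length")
        if n == 0:
            raise ValueError("empty design")
        if any(t < 0 or not np.isfinite(t) for t in self.time):
            raise ValueError("times must be finite and non-negative")
        if any(c < 1 for c in self.cycle) or any(r < 1 for r in self.replicate):
            raise ValueError("cycle and replicate labels are 1-based")
        pairs = list(zip(self.time, self.replicate))
        if len(set(pairs)) != n:
            raise ValueError("(time, replicate) pairs must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.time, dtype=float)

    def labels(self) -> list[str]:
        return [sample_label(t, c, r) for t, c, r in zip(self.time, self.cycle, self.replicate)]

    def is_regular(self, tol: float = 1e-9) -> bool:
        """True if one replicate per time and times form an even grid."""
        if len(set(self.replicate)) != 1:
            return False
        t = np.sort(self.times)
        if len(t) < 2:
            return True
        d = np.diff(t)
        return bool(np.all(np.abs(d - d[0]) < tol) and d[0] > 0)

    @classmethod
    def regular(cls, n_timepoints: int, step: float, n_replicates: int = 1,
                cycle_length: float = 24.0) -> "SampleDesign":
        """Evenly spaced design: ``n_timepoints`` every ``step`` hours.

        The cycle label of a sample is ``1 + floor(time / cycle_length)``.
        Replicates repeat each time with the same cycle label.
        """
        times, cycles, reps = [], [], []
        for i in range(n_timepoints):
            t = i * step
            for r in range(1, n_replicates + 1):
                times.append(float(t))
                cycles.append(1 + int(t // cycle_length))
                reps.append(r)
        return cls(tuple(times), tuple(cycles), tuple(reps))

    @classmethod
    def from_labels(cls, labels: list[str]) -> "SampleDesign":
        parsed = [parse_sample_label(x) for x in labels]
        return cls(tuple(p[0] for p in parsed), tuple(p[1] for p in parsed),
                   tuple(p[2] for p in parsed))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus the sample design.

    ``values`` is a pandas DataFrame indexed by gene id with columns in the
    order of ``design``. Missing values (NaN) are allowed before filtering.
    """

    values: pd.DataFrame
    design: SampleDesign = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.design is None:
            self.design = SampleDesign.from_labels(list(self.values.columns))
        if self.values.shape[1] != self.design.n_samples:
            raise ValueError("value grid does not match the design")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene ids (first: {dup!r})")
        expected = self.design.labels()
        if list(self.values.columns) != expected:
            self.values = self.values.set_axis(expected, axis=1)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy_with(self, values: pd.DataFrame | None = None,
                  design: SampleDesign | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy() if values is None else values,
                                self.design if design is None else design)

    def log2(self, pseudocount: float = 0.0) -> "ExpressionMatrix":
        """log2-transform (the scale on which array intensities are analysed)."""
        return ExpressionMatrix(np.log2(self.values + pseudocount), self.design)
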