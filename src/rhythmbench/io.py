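"""Tab-separated round-trip IO for the pipeline's tables.

Expression matrices are written as TSV with a ``gene_id`` column and one
column per sample named ``t<time>_c<cycle>_r<rep>``; the design is
recovered from the header on load. Truth tables, results and ortholog
maps are plain TSV with fixed column sets.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleDesign
from .simulate import GeneTruth, OrthologMap
from .waveforms import WaveformSpec

_FLOAT_FMT = "%.17g"  # full round-trip precision, stable hashes


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.insert(0, "gene_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df.columns[0] != "gene_id":
        raise ValueError("expression TSV must start with a gene_id column")
    df = df.set_index("gene_id")
    df.index.name = None
    design = SampleDesign.from_labels(list(df.columns))  # raises citing the column
    return ExpressionMatrix(df.astype(float), design)


def write_truths(truths: list[GeneTruth], path) -> None:
    rows = []
    for t in truths:
        wf = t.waveform
        rows.append({
            "gene_id": t.gene_id, "is_rhythmic": int(t.is_rhythmic),
            "baseline": t.baseline,
            "shape": wf.shape if wf else "",
            "period": wf.period if wf else np.nan,
            "phase": wf.phase if wf else np.nan,
            "asymmetry": wf.asymmetry if wf else np.nan,
            "rel_amplitude": wf.rel_amplitude if wf else np.nan,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_truths(path) -> list[GeneTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    out = []
    for _, row in df.iterrows():
        rhythmic = bool(row["is_rhythmic"])
        wf = None
        if rhythmic:
            wf = WaveformSpec(shape=row["shape"], period=float(row["period"]),
                              phase=float(row["phase"]),
                              asymmetry=float(row["asymmetry"]),
                              rel_amplitude=float(row["rel_amplitude"]))
        out.append(GeneTruth(str(row["gene_id"]), rhythmic, wf, float(row["baseline"])))
    return out


def write_ortholog_map(omap: OrthologMap, path) -> None:
    omap.to_frame().to_csv(path, sep="\t", index=False)


def load_ortholog_map(path) -> OrthologMap:
    return OrthologMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_table(obj, path) -> None:
    """Write a DataFrame (or Series) as TSV at full precision."""
    if isinstance(obj, pd.Series):
        obj = obj.to_frame()
    obj.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
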