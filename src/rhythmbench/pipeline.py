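"""End-to-end pipeline: simulate -> preprocess -> methods -> diagnostics
-> conservation benchmark, from one config with deterministic seeding.

Every artifact lands in the output directory, is listed with a content
hash in ``manifest.json``, and the headline numbers are collected in
``summary.json``; re-running with the same config reproduces the summary
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons_mod
from . import diagnostics as diag
from .io import (ensure_dir, write_expression, write_ortholog_map,
                 write_table, write_truths)
from .matrix import ExpressionMatrix, SampleDesign
from .methods import MethodConfig, results_frame, run_method_on_matrix
from .preprocess import summarize_expression
from .simulate import (ConservationConfig, SpeciesSimConfig,
                       randomize_time_labels, simulate_ortholog_pair)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent, reproducible per-stage seed derived from the master."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass(frozen=True)
class PipelineConfig:
    n_genes: int = 400
    n_orthologs: int = 300
    frac_rhythmic: float = 0.3
    expression_rhythm_coupling: float = 0.0
    noise_cv: float = 0.25
    p_conserved: float = 0.8
    phase_jitter_sd: float = 1.0
    baseline_log_correlation: float = 0.3
    n_timepoints: int = 24
    time_step: float = 2.0
    methods: tuple = ("jtk", "ls", "ejtk", "rgc")
    n_permutations: int = 500
    null_size: int = 20000
    bench_method: str = "rgc"
    bench_kind: str = "p"
    bench_cutoff: float = 0.01
    diagnostics_bins: int = 20
    top_n: tuple = (100,)
    overlap_cutoff: float = 0.05
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "top_n"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def species_config(self, which: str) -> SpeciesSimConfig:
        seed = stage_seed(self.master_seed, f"simulate:{which}")
        return SpeciesSimConfig(
            n_genes=self.n_genes, frac_rhythmic=self.frac_rhythmic,
            expression_rhythm_coupling=self.expression_rhythm_coupling,
            noise_cv=self.noise_cv,
            design=SampleDesign.regular(self.n_timepoints, self.time_step),
            seed=seed, gene_prefix="a" if which == "A" else "b")

    def conservation_config(self) -> ConservationConfig:
        return ConservationConfig(
            n_orthologs=self.n_orthologs, p_conserved=self.p_conserved,
            phase_jitter_sd=self.phase_jitter_sd,
            baseline_log_correlation=self.baseline_log_correlation,
            seed=stage_seed(self.master_seed, "conservation"))

    def method_config(self) -> MethodConfig:
        return MethodConfig(n_permutations=self.n_permutations,
                            null_size=self.null_size,
                            seed=stage_seed(self.master_seed, "methods"))


@dataclass
class ReportBundle:
    out_dir: Path
    manifest: dict
    summary: dict

    def write(self) -> None:
        with open(self.out_dir / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        files = sorted(p for p in self.out_dir.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
        self.manifest["files"] = {
            str(p.relative_to(self.out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in files}
        with open(self.out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _run_methods(m: ExpressionMatrix, methods, cfg: MethodConfig) -> dict:
    analysed = m.log2()
    return {name: results_frame(run_method_on_matrix(analysed, name, cfg))
            for name in methods}


def run_pipeline(cfg: PipelineConfig, out_dir) -> ReportBundle:
    """Execute all stages; failures abort naming the failing stage."""
    out = ensure_dir(out_dir)
    summary: dict = {"config": asdict(cfg)}
    manifest = {"config": asdict(cfg), "versions": {
        "numpy": np.__version__, "pandas": pd.__version__},
        "seeds": {s: stage_seed(cfg.master_seed, s)
                  for s in ("simulate:A", "simulate:B", "conservation",
                            "methods", "randomize", "ttest")}}
    stage = "simulate"
    t0 = time.time()
    try:
        mA, mB, omap, (truthsA, truthsB) = simulate_ortholog_pair(
            cfg.species_config("A"), cfg.species_config("B"),
            cfg.conservation_config())
        write_expression(mA, out / "speciesA_expression.tsv")
        write_expression(mB, out / "speciesB_expression.tsv")
        write_truths(truthsA, out / "speciesA_truth.tsv")
        write_truths(truthsB, out / "speciesB_truth.tsv")
        write_ortholog_map(omap, out / "orthologs.tsv")
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "methods"
        mcfg = cfg.method_config()
        resA = _run_methods(mA, cfg.methods, mcfg)
        resB = _run_methods(mB, cfg.methods, mcfg)
        for name, frame in resA.items():
            write_table(frame.drop(columns="gene_id"), out / f"speciesA_{name}_results.tsv")
        for name, frame in resB.items():
            write_table(frame.drop(columns="gene_id"), out / f"speciesB_{name}_results.tsv")

        stage = "diagnostics"
        rand = randomize_time_labels(mA, stage_seed(cfg.master_seed, "randomize"))
        res_rand = _run_methods(rand, cfg.methods, mcfg)
        profiles = {}
        for name in cfg.methods:
            col = "default_p" if name == "ejtk" else "raw_p"
            prof_null = diag.pvalue_profile(res_rand[name][col], "randomized",
                                            cfg.diagnostics_bins, name)
            prof_full = diag.pvalue_profile(resA[name][col], "full",
                                            cfg.diagnostics_bins, name)
            profiles[name] = {
                "randomized": {"ks_d": prof_null.ks_d, "ks_p": prof_null.ks_p,
                               "frac_below_0.05": prof_null.frac_below[0.05]},
                "full": {"ks_d": prof_full.ks_d, "ks_p": prof_full.ks_p,
                         "frac_below_0.05": prof_full.frac_below[0.05]}}
        summary["pvalue_profiles"] = profiles
        overlap = diag.method_overlap(results=resA, mode="threshold",
                                      cutoff=cfg.overlap_cutoff)
        summary["overlap"] = {
            "union_size": overlap.union_size,
            "exclusive": {"+".join(sorted(k)): v
                          for k, v in sorted(overlap.exclusive.items(),
                                             key=lambda kv: "+".join(sorted(kv[0])))}}
        write_table(overlap.jaccard, out / "jaccard.tsv")
        levelsA = summarize_expression(mA, "median")
        ttest = diag.rhythmic_expression_ttest(
            levelsA, resA[cfg.methods[0]], seed=stage_seed(cfg.master_seed, "ttest"))
        summary["expression_ttest"] = ttest

        stage = "benchmark"
        bench = cons_mod.build_benchmark_set(resB[cfg.bench_method], omap,
                                             cfg.bench_method, cfg.bench_kind,
                                             cfg.bench_cutoff)
        summary["benchmark"] = {"size": len(bench.members),
                                "base_rate": bench.base_rate}
        ks = {}
        curves = {}
        for name in cfg.methods:
            d, p, direction = cons_mod.ks_conserved_vs_not(resA[name], omap, bench)
            ks[name] = {"D": d, "p": p, "direction": direction}
            curves[name] = cons_mod.proportion_curve(resA[name], omap, bench)
        summary["conservation_ks"] = ks
        naive = cons_mod.naive_curve(levelsA, omap, bench)
        crossing = cons_mod.compare_curves(curves, naive)
        summary["crossing"] = {
            name: {"crossing_rank": int(row["crossing_rank"]),
                   "marker_rank": (None if pd.isna(row["marker_rank"])
                                   else int(row["marker_rank"])),
                   "marker_beyond_crossing": bool(row["marker_beyond_crossing"])}
            for name, row in crossing.iterrows()}
        for name, curve in curves.items():
            write_table(pd.DataFrame({
                "rank": np.arange(1, len(curve.gene_ids) + 1),
                "gene_id": curve.gene_ids,
                "ordering_value": curve.ordering_values,
                "in_benchmark": curve.in_benchmark.astype(int),
                "proportion": curve.proportions}).set_index("rank"),
                out / f"curve_{name}.tsv")
        write_table(pd.DataFrame({
            "rank": np.arange(1, len(naive.gene_ids) + 1),
            "gene_id": naive.gene_ids,
            "ordering_value": naive.ordering_values,
            "in_benchmark": naive.in_benchmark.astype(int),
            "proportion": naive.proportions}).set_index("rank"),
            out / "curve_naive.tsv")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = ReportBundle(out, manifest, summary)
    bundle.write()
    logger.info("pipeline complete: %s", out)
    return bundle
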