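#!/usr/bin/env python
"""Overlap of rhythmic calls between methods.

At a fixed p-value threshold methods disagree widely on which genes are
rhythmic; fixing the number of top genes instead tightens the overlap.
Writes exclusive (upset-style) intersection counts and the pairwise
Jaccard matrix for both modes.
"""

import argparse
from pathlib import Path

import pandas as pd

from rhythmbench.diagnostics import method_overlap
from rhythmbench.experiments import _method_cfg, _sub_seed
from rhythmbench.io import ensure_dir
from rhythmbench.matrix import SampleDesign
from rhythmbench.methods import results_frame, run_method_on_matrix
from rhythmbench.simulate import SpeciesSimConfig, simulate_species

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-genes", type=int, default=800)
ap.add_argument("--out", type=Path, default=Path("results"))
args = ap.parse_args()

cfg = SpeciesSimConfig(n_genes=args.n_genes,
                       design=SampleDesign.regular(24, 2.0),
                       expression_rhythm_coupling=1.0,
                       seed=_sub_seed(args.seed, "overlap-sim"))
m, _ = simulate_species(cfg)
mcfg = _method_cfg(args.seed)
results = {name: results_frame(run_method_on_matrix(m.log2(), name, mcfg))
           for name in ("jtk", "ls", "ejtk", "rgc")}

ensure_dir(args.out)
rows = []
for mode, cutoff in (("threshold", 0.05), ("threshold", 0.01), ("topN", 100)):
    out = method_overlap(results=results, mode=mode, cutoff=cutoff)
    label = f"{mode}_{cutoff}"
    out.jaccard.to_csv(args.out / f"overlap_jaccard_{label}.tsv", sep="\t")
    for key, count in sorted(out.exclusive.items(),
                             key=lambda kv: -kv[1]):
        rows.append({"mode": label, "methods": "+".join(sorted(key)),
                     "count": count})
    all_methods = frozenset(results)
    full = out.exclusive.get(all_methods, 0)
    print(f"{label}: union {out.union_size}, called by all methods: {full}")
pd.DataFrame(rows).to_csv(args.out / "overlap_exclusive.tsv", sep="\t",
                          index=False)
print(f"wrote overlap tables -> {args.out}")
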