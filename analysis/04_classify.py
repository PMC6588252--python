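#!/usr/bin/env python
"""Repeated k-fold cross-validated classification of eyes.

Trains the one-vs-one bank of binary RBF SVMs (forward selection of 6
features per model inside each training fold) and reports the
distribution of performance indicators over runs: per-class sensitivity
and specificity, accuracy, two-eye agreement, two-eye correctness, and
the Unknown rate.  Writes ``predictions.csv``, ``model_specs.csv`` and
the five-number ``cv_summary.csv`` under ``results/``.

Run:  python analysis/04_classify.py [--k 5] [--runs 10] [--seed 17]
"""

import argparse
from pathlib import Path

import pandas as pd

from octexture import CVConfig, run_cv
from octexture.evaluate import run_metrics, summarize_runs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--k", type=int, default=5)
    ap.add_argument("--runs", type=int, default=10)
    ap.add_argument("--layers", default="GCL,IPL,INL,OPL,ONL")
    ap.add_argument("--seed", type=int, default=17)
    args = ap.parse_args()

    features = pd.read_csv(args.results / "features.csv")
    meta = pd.read_csv(args.results / "meta.csv")
    cfg = CVConfig(k=args.k, n_runs=args.runs,
                   layers=tuple(args.layers.split(",")), seed=args.seed)
    results = run_cv(features, meta, cfg)

    preds = pd.concat(
        [r.predictions.assign(run=r.run_index) for r in results],
        ignore_index=True,
    )
    preds.to_csv(args.results / "predictions.csv", index=False)
    specs = pd.DataFrame([
        {"run": r.run_index, "layer": s.layer,
         "pair": f"{s.pair[0]}-{s.pair[1]}", "selected": ";".join(s.selected)}
        for r in results for s in r.model_specs
    ])
    specs.to_csv(args.results / "model_specs.csv", index=False)

    metrics = [run_metrics(r.predictions) for r in results]
    summary = summarize_runs(metrics)
    summary.to_csv(args.results / "cv_summary.csv")
    print(f"k={args.k}, {args.runs} runs, {len(meta)} eyes")
    print(summary.round(1).to_string())


if __name__ == "__main__":
    main()
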