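#!/usr/bin/env python
"""Feature provenance and feature–thickness relationships.

Summarises where the selected texture features come from (macular
quadrants vs global wavelet features, per class pair) and how strongly
each frequently selected local feature correlates with the mean layer
thickness over its own quadrant footprint, within each group.  Writes
``origin_tally.csv`` and ``feature_thickness_corr.csv``.

Run:  python analysis/05_report.py
"""

import argparse
from collections import Counter
from pathlib import Path

import pandas as pd

from octexture.classify import ModelSpec
from octexture.evaluate import feature_origin_tally, feature_thickness_correlation
from octexture.io import load_cohort
from octexture.fundus import compute_layer_thickness
from octexture.texture import QUADRANTS, quadrant_layer_thickness


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--top", type=int, default=8,
                    help="most-selected local features to correlate")
    args = ap.parse_args()

    spec_rows = pd.read_csv(args.results / "model_specs.csv")
    specs = [
        ModelSpec(r["layer"], tuple(r["pair"].split("-")),
                  tuple(r["selected"].split(";")), 1.0, 1.0)
        for _, r in spec_rows.iterrows()
    ]
    tally = feature_origin_tally(specs)
    tally.to_csv(args.results / "origin_tally.csv")
    pct = tally.div(tally["total"], axis=0).drop(columns="total") * 100
    print("selected-feature origins (% per class pair):")
    print(pct.round(1).to_string())

    # most frequently selected local features
    counts = Counter(
        name for s in specs for name in s.selected
        if ".glcm_" in name
    )
    top = [name for name, _ in counts.most_common(args.top)]

    features = pd.read_csv(args.results / "features.csv")
    meta = pd.read_csv(args.results / "meta.csv")

    # per-eye quadrant layer thickness for each (layer, quadrant) needed
    need = {(n.split(".")[0], n.split("_glcm_")[0]) for n in top}
    thick_rows = []
    for eye in load_cohort(args.cohort):
        surf = eye.surfaces.mirrored() if eye.laterality == "left" else eye.surfaces
        row = {}
        for name in top:
            layer, feat = name.split(".", 1)
            quad = next(q for q in QUADRANTS if f"_{q}_" in f"_{feat}_"
                        or feat.startswith(f"glcm_{q}_"))
            tmap = compute_layer_thickness(surf, layer)
            row[name] = quadrant_layer_thickness(tmap, quad)
        thick_rows.append(row)
    thickness = pd.DataFrame(thick_rows)

    corr_rows = []
    for name in top:
        df = feature_thickness_correlation(
            features[name].to_numpy(), thickness[name].to_numpy(),
            meta["class"].to_numpy(),
        )
        df.insert(0, "feature", name)
        corr_rows.append(df)
    corr = pd.concat(corr_rows, ignore_index=True)
    corr.to_csv(args.results / "feature_thickness_corr.csv", index=False)
    print(f"\nfeature–thickness Pearson r (top {args.top} selected local "
          "features, per group):")
    print(corr.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
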