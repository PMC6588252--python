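"""Canned simulation studies: the strong-effect and null cohort analyses.

These are the package's reference end-to-end experiments, used by the
analysis drivers, the acceptance script, and the test suite.  Problem
sizes: the strong-effect study uses 20 subjects per class with 10-fold
cross-validation over 20 runs; the null study (all classes share one
texture parameter set) uses 12 subjects per class with 5-fold
cross-validation over 6 runs, which is ample to locate chance-level
accuracy.  Both use the reduced 256x128x64 acquisition grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import CVConfig, run_cv
from .evaluate import run_metrics, summarize_runs
from .pipeline import cohort_tables, small_cohort_config
from .synth import example_class_params


def cohort_study(
    seed: int,
    effect_scale: float,
    n_subjects: int,
    k: int,
    n_runs: int,
    layers=("GCL", "IPL", "INL", "OPL", "ONL"),
):
    """Generate a cohort, extract features, run repeated k-fold CV.

    Returns ``(results, metrics_per_run, summary, meta)`` where ``summary``
    is the five-number table over runs.
    """
    cfg = small_cohort_config(n_subjects, seed=seed)
    params = example_class_params(effect_scale)
    features, meta, _ = cohort_tables(cfg, params, layers, with_thickness=False)
    cv = CVConfig(k=k, n_runs=n_runs, layers=layers, seed=seed)
    results = run_cv(features, meta, cv)
    metrics = [run_metrics(r.predictions) for r in results]
    return results, metrics, summarize_runs(metrics), meta


def strong_effect_study(seed: int, n_subjects: int = 20, k: int = 10,
                        n_runs: int = 20):
    """Well-separated class textures: the pipeline should recover the
    labels far above chance."""
    return cohort_study(seed, 1.0, n_subjects, k, n_runs)


def null_study(seed: int, n_subjects: int = 12, k: int = 5, n_runs: int = 6):
    """Identical texture parameters for all classes: accuracy must sit at
    chance (1/3) within Monte-Carlo error."""
    return cohort_study(seed, 0.0, n_subjects, k, n_runs)


def null_accuracy_band(metrics: list[dict], n_eyes: int) -> tuple[float, float]:
    """Mean accuracy (fraction) and a conservative Monte-Carlo SE.

    Runs share one cohort, so the run-to-run spread understates the
    cohort-level uncertainty; the binomial SE over eyes is the dominant
    conservative term and the larger of the two is returned.
    """
    accs = np.array([m["accuracy"] for m in metrics]) / 100.0
    p = float(accs.mean())
    se_runs = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    se_binom = float(np.sqrt(max(p * (1 - p), 1e-12) / n_eyes))
    return p, max(se_runs, se_binom)
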