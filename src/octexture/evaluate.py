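"""Performance metrics and summaries for the voting classifier.

Implements the 3x4 confusion matrix (three true classes, four predicted
outcomes including "Unknown"), per-class sensitivity/specificity and
accuracy, two-eye agreement, the Unknown rate, five-number distribution
summaries over repeated runs, selected-feature origin tallies,
feature–thickness Pearson correlations, and the per-sector one-way
thickness ANOVA.

Conventions with the extra "Unknown" column: an Unknown prediction is a
negative for *every* class — it counts against sensitivity and accuracy
and can only help specificity.  Undefined ratios (empty denominators) are
returned as NaN rather than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import CLASSES

PREDICTED_LABELS = (*CLASSES, "Unknown")

METRIC_COLUMNS = (
    "sen_HC", "spe_HC", "sen_AD", "spe_AD", "sen_PD", "spe_PD",
    "accuracy", "two_eyes", "two_eyes_correct", "unknown",
)

SUMMARY_ROWS = ("max", "q3", "median", "q1", "min")


def confusion(predictions, truths) -> pd.DataFrame:
    """3x4 confusion matrix: true classes x predicted labels (counts)."""
    predictions = pd.Series(list(predictions), dtype=object)
    truths = pd.Series(list(truths), dtype=object)
    if not set(truths) <= set(CLASSES):
        raise ValueError(f"true labels outside {CLASSES}")
    if not set(predictions) <= set(PREDICTED_LABELS):
        raise ValueError(f"predicted labels outside {PREDICTED_LABELS}")
    cm = pd.DataFrame(0, index=list(CLASSES), columns=list(PREDICTED_LABELS))
    for t, p in zip(truths, predictions):
        cm.loc[t, p] += 1
    return cm


def class_metrics(cm: pd.DataFrame) -> dict[str, float]:
    """Per-class sensitivity/specificity (%) and overall accuracy (%).

    sensitivity(c) = cm[c, c] / (eyes truly c);
    specificity(c) = (eyes of other classes not predicted c) / (eyes of
    other classes); accuracy = trace / total.  Empty denominators → NaN.
    """
    cm = cm.loc[list(CLASSES), list(PREDICTED_LABELS)]
    total = cm.to_numpy().sum()
    out: dict[str, float] = {}
    for c in CLASSES:
        row_sum = cm.loc[c].sum()
        out[f"sen_{c}"] = 100.0 * cm.loc[c, c] / row_sum if row_sum else np.nan
        others = cm.drop(index=c)
        n_others = others.to_numpy().sum()
        out[f"spe_{c}"] = (
            100.0 * (n_others - others[c].sum()) / n_others if n_others else np.nan
        )
    diag = sum(cm.loc[c, c] for c in CLASSES)
    out["accuracy"] = 100.0 * diag / total if total else np.nan
    return out


def two_eye_metrics(predictions: pd.DataFrame) -> dict[str, float]:
    """Two-eye agreement rates over subjects with exactly two tested eyes.

    Returns the percentage of such subjects whose eyes received the same
    classification, and the percentage of *those* that are also correct
    (same-Unknown pairs agree but are never correct).  Subjects with one
    tested eye are excluded from the denominators and counted separately.
    """
    per_subject = predictions.groupby("subject_id")
    same = correct_and_same = n_pairs = n_single = 0
    for _, grp in per_subject:
        if len(grp) != 2:
            n_single += 1
            continue
        n_pairs += 1
        a, b = grp["predicted"].tolist()
        if a == b:
            same += 1
            if (a != "Unknown") and (grp["predicted"] == grp["true"]).all():
                correct_and_same += 1
    return {
        "two_eyes": 100.0 * same / n_pairs if n_pairs else np.nan,
        "two_eyes_correct": 100.0 * correct_and_same / same if same else np.nan,
        "n_two_eye_subjects": n_pairs,
        "n_excluded_subjects": n_single,
    }


def unknown_rate(predictions) -> float:
    """Percentage of eyes whose voting ended in an unresolved tie."""
    preds = pd.Series(list(predictions["predicted"])
                      if isinstance(predictions, pd.DataFrame) else list(predictions))
    return 100.0 * (preds == "Unknown").mean() if len(preds) else np.nan


def run_metrics(predictions: pd.DataFrame) -> dict[str, float]:
    """All per-run performance indicators from a predictions table."""
    cm = confusion(predictions["predicted"], predictions["true"])
    out = class_metrics(cm)
    out.update({k: v for k, v in two_eye_metrics(predictions).items()
                if k in ("two_eyes", "two_eyes_correct")})
    out["unknown"] = unknown_rate(predictions)
    return out


def summarize_runs(metrics_per_run: list[dict[str, float]]) -> pd.DataFrame:
    """Five-number summary (max, Q3, median, Q1, min) per metric over runs.

    Quartiles use linear interpolation between order statistics.
    """
    if not metrics_per_run:
        raise ValueError("need at least one run")
    df = pd.DataFrame(metrics_per_run)
    rows = {}
    with np.errstate(invalid="ignore"):
        rows["max"] = df.max()
        rows["q3"] = df.quantile(0.75, interpolation="linear")
        rows["median"] = df.quantile(0.5, interpolation="linear")
        rows["q1"] = df.quantile(0.25, interpolation="linear")
        rows["min"] = df.min()
    return pd.DataFrame(rows).T.loc[list(SUMMARY_ROWS)]


def feature_origin_tally(model_specs) -> pd.DataFrame:
    """Counts of selected features by regional origin per class-pair.

    Rows: class pairs ("HC-AD", ...); columns: the four quadrants, "global",
    and "total".  Origin is parsed from the feature name ("{layer}.glcm_
    {quadrant}_{metric}" or "{layer}.dtcwt_var_{band}").
    """
    from .texture import QUADRANTS  # local import to avoid cycle at import time

    origins = (*QUADRANTS, "global")
    pairs = sorted({f"{s.pair[0]}-{s.pair[1]}" for s in model_specs})
    tally = pd.DataFrame(0, index=pairs, columns=[*origins, "total"])
    for spec in model_specs:
        key = f"{spec.pair[0]}-{spec.pair[1]}"
        for name in spec.selected:
            feat = name.split(".", 1)[-1]
            if feat.startswith("dtcwt_"):
                origin = "global"
            else:
                origin = next(q for q in QUADRANTS if f"_{q}_" in f"_{feat}_"
                              or feat.startswith(f"glcm_{q}_"))
            tally.loc[key, origin] += 1
            tally.loc[key, "total"] += 1
    return tally


def feature_thickness_correlation(
    feature_values: np.ndarray,
    thickness_values: np.ndarray,
    group_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson correlation of a selected feature with its quadrant thickness.

    Computed within each group (or once overall when ``group_labels`` is
    None).  Pairs with fewer than 3 observations are undefined (NaN r,
    flagged).  Classification: strong if |r| > 0.7, moderate if 0.5 ≤ |r|
    ≤ 0.7, else weak.
    """
    x = np.asarray(feature_values, dtype=float)
    t = np.asarray(thickness_values, dtype=float)
    if group_labels is None:
        group_labels = np.zeros(len(x), dtype=int)
    groups = np.asarray(group_labels)
    rows = []
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() < 3:
            rows.append({"group": g, "r": np.nan, "p": np.nan,
                         "n": int(m.sum()), "strength": "undefined"})
            continue
        r, p = stats.pearsonr(x[m], t[m])
        strength = ("strong" if abs(r) > 0.7
                    else "moderate" if abs(r) >= 0.5 else "weak")
        rows.append({"group": g, "r": float(r), "p": float(p),
                     "n": int(m.sum()), "strength": strength})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    F: float
    p: float
    degenerate: bool = False


def sector_anova(
    sector_values: np.ndarray, group_labels: np.ndarray
) -> AnovaResult:
    """One-way ANOVA of one ETDRS sector's thickness across groups."""
    values = np.asarray(sector_values, dtype=float)
    groups = np.asarray(group_labels)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two observations per group")
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        return AnovaResult(np.nan, np.nan, degenerate=True)
    F, p = stats.f_oneway(*samples)
    return AnovaResult(float(F), float(p))


def sector_anova_table(
    sectors_per_eye: pd.DataFrame, group_labels: np.ndarray
) -> pd.DataFrame:
    """Per-sector one-way ANOVA: one row per sector column, F and p."""
    rows = []
    for col in sectors_per_eye.columns:
        res = sector_anova(sectors_per_eye[col].to_numpy(), group_labels)
        rows.append({"sector": col, "F": res.F, "p": res.p,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)
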