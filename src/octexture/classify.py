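"""One-vs-one SVM voting classification of eyes with forward feature
selection under repeated k-fold cross-validation.

For every retinal layer in use and every pair of classes (HC–AD, HC–PD,
AD–PD) an independent binary RBF-kernel SVM is trained on six features
chosen by greedy forward selection.  An eye receives one vote per
(layer, pair) decision; the most voted class wins, a three-way tie yields
"Unknown", and a two-way tie for the top is broken by the pairwise
sub-tally between the tied classes (itself tied → "Unknown").

All fitting — z-scoring, feature selection, SVM training — happens inside
each training fold; held-out eyes never influence any fitted artefact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import _fast_svm
from .evaluate import confusion
from .synth import CLASSES

DEFAULT_LAYERS = ("GCL", "IPL", "INL", "OPL", "ONL")
PAIR_ORDER = (("HC", "AD"), ("HC", "PD"), ("AD", "PD"))
UNKNOWN = "Unknown"


@dataclass(frozen=True)
class ModelSpec:
    """Identity and fitted configuration of one binary model."""

    layer: str
    pair: tuple[str, str]
    selected: tuple[str, ...]  # exactly 6 feature names from the layer's 86
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be distinct")


@dataclass
class VoteTally:
    """Per-class vote counts plus the pairwise sub-tallies they came from."""

    votes: dict[str, int]
    pair_tallies: dict[tuple[str, str], dict[str, int]]

    def total(self) -> int:
        return sum(self.votes.values())


@dataclass
class Prediction:
    eye_id: str
    label: str  # HC | AD | PD | Unknown
    tally: VoteTally


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol.

    ``unit`` controls the partition unit: ``"subject"`` keeps both eyes of a
    subject in the same fold (the leak-free default); ``"eye"`` splits eyes
    independently.  ``selection`` places forward selection either inside
    each training fold (``"per_fold"``) or once per run on the full dataset
    (``"global"``, the laxer reading; leaks test information).
    """

    k: int = 10
    n_runs: int = 1
    layers: tuple[str, ...] = DEFAULT_LAYERS
    unit: str = "subject"
    selection: str = "per_fold"
    n_features: int = 6
    internal_cv: int = 3
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.unit not in ("subject", "eye"):
            raise ValueError("unit must be 'subject' or 'eye'")
        if self.selection not in ("per_fold", "global"):
            raise ValueError("selection must be 'per_fold' or 'global'")


@dataclass
class RunResult:
    """Predictions, confusion matrix and fitted specs of one CV run."""

    run_index: int
    predictions: pd.DataFrame  # eye_id, subject_id, true, predicted, fold
    confusion: pd.DataFrame  # 3 true rows x 4 predicted columns
    model_specs: list[ModelSpec]
    seed: int


# ---------------------------------------------------------------------------
# z-scoring

def zscore_fit(table: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and sample standard deviation from training rows."""
    X = np.asarray(table, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training table must be a non-empty 2-D array")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    if np.any(sd == 0):
        warnings.warn("zero-variance feature(s); transformed to 0", stacklevel=2)
    return mean, sd


def zscore_apply(table, params: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Apply training-fold statistics; zero-variance features map to 0."""
    mean, sd = params
    X = np.asarray(table, dtype=float)
    safe = np.where(sd > 0, sd, 1.0)
    out = (X - mean) / safe
    return np.where(sd > 0, out, 0.0)


# ---------------------------------------------------------------------------
# forward selection and binary training

def _subset_gamma(var_per_col: np.ndarray, cols: list[int]) -> float:
    """gamma = 1 / (n_features * mean feature variance) of the subset."""
    mv = float(np.mean(var_per_col[cols]))
    return 1.0 / (len(cols) * mv) if mv > 0 else 1.0 / len(cols)


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    n_features: int = 6,
    rng: np.random.Generator | None = None,
    internal_cv: int = 3,
    C: float = 1.0,
    scorer=None,
) -> list[int]:
    """Greedy forward selection of feature column indices.

    At each step every remaining feature is scored jointly with the current
    set and the best is kept; ties break to the lowest feature index.  The
    default scorer is stratified internal cross-validated accuracy of the
    RBF SVM that will ultimately be trained.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, d = X.shape
    if d < n_features:
        raise ValueError("fewer candidate features than requested")
    if len(np.unique(y)) != 2:
        raise ValueError("forward_select requires binary labels")
    rng = rng or np.random.default_rng(0)
    yf = (y == np.unique(y)[1]).astype(np.float64)

    if scorer is None:
        seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=internal_cv, shuffle=True, random_state=seed)
        folds = list(skf.split(X, yf))
        var_per_col = X.var(axis=0)

        def scorer(cols: list[int]) -> float:
            gamma = _subset_gamma(var_per_col, cols)
            Xs = np.ascontiguousarray(X[:, cols])
            correct = 0
            for tr, te in folds:
                pred = _fast_svm.fit_predict(Xs[tr], yf[tr], Xs[te], C, gamma)
                correct += int((pred == yf[te]).sum())
            return correct / n

    selected: list[int] = []
    remaining = list(range(d))
    for _ in range(n_features):
        best_f, best_score = None, -np.inf
        for f in remaining:  # index order => lowest-index tie-break
            score = scorer(selected + [f])
            if score > best_score:
                best_f, best_score = f, score
        selected.append(best_f)
        remaining.remove(best_f)
    return selected


def train_binary(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                 gamma: float | None = None) -> SVC:
    """Fit the final RBF-kernel SVM on the selected (z-scored) features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    if gamma is None:
        mv = float(X.var(axis=0).mean())
        gamma = 1.0 / (X.shape[1] * mv) if mv > 0 else 1.0 / X.shape[1]
    model = SVC(C=C, kernel="rbf", gamma=gamma)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# voting

def _resolve_votes(votes: dict[str, int],
                   pair_tallies: dict[tuple[str, str], dict[str, int]]) -> str:
    """Plurality with the tie rules.

    Strict plurality wins.  All three classes tied → Unknown.  Exactly two
    tied at the top → the pairwise sub-tally between the tied classes
    decides; if that sub-tally is itself tied → Unknown.
    """
    counts = sorted(votes.values(), reverse=True)
    top = counts[0]
    leaders = [c for c in CLASSES if votes[c] == top]
    if len(leaders) == 1:
        return leaders[0]
    if len(leaders) == 3:
        return UNKNOWN
    a, b = leaders
    pair = (a, b) if (a, b) in pair_tallies else (b, a)
    sub = pair_tallies[pair]
    if sub[a] > sub[b]:
        return a
    if sub[b] > sub[a]:
        return b
    return UNKNOWN


def vote_classify(
    eye_features,
    model_bank: dict[tuple[str, tuple[str, str]], tuple[SVC, ModelSpec]],
    layers: tuple[str, ...] = DEFAULT_LAYERS,
) -> Prediction:
    """Classify one eye from its z-scored feature mapping.

    ``eye_features`` maps full feature-column names ("{layer}.{name}",
    already z-scored with the training-fold statistics) to values; each
    model slices out its own selected features.
    """
    votes = {c: 0 for c in CLASSES}
    pair_tallies = {p: {p[0]: 0, p[1]: 0} for p in PAIR_ORDER}
    for layer in layers:
        for pair in PAIR_ORDER:
            key = (layer, pair)
            if key not in model_bank:
                raise KeyError(f"model bank is missing model for {key}")
            model, spec = model_bank[key]
            x = np.array([[eye_features[n] for n in spec.selected]])
            label = model.predict(x)[0]
            votes[label] += 1
            pair_tallies[pair][label] += 1
    tally = VoteTally(votes, pair_tallies)
    return Prediction("", _resolve_votes(votes, pair_tallies), tally)


# ---------------------------------------------------------------------------
# cross-validation driver

def layer_columns(columns, layer: str) -> list[str]:
    return [c for c in columns if c.startswith(f"{layer}.")]


@dataclass
class FoldModels:
    """Artefacts fitted on one training fold."""

    zscore: tuple[np.ndarray, np.ndarray]
    columns: list[str]
    bank: dict[tuple[str, tuple[str, str]], tuple[SVC, ModelSpec]]
    specs: list[ModelSpec] = field(default_factory=list)


def fit_fold(
    features: pd.DataFrame,
    classes: pd.Series,
    cfg: CVConfig,
    rng: np.random.Generator,
    selected_override: dict[tuple[str, tuple[str, str]], tuple[str, ...]] | None = None,
) -> FoldModels:
    """Fit z-scoring, feature selection and the SVM bank on training rows only."""
    columns = list(features.columns)
    zs = zscore_fit(features.to_numpy(dtype=float))
    Z = pd.DataFrame(zscore_apply(features.to_numpy(dtype=float), zs),
                     index=features.index, columns=columns)
    bank: dict[tuple[str, tuple[str, str]], tuple[SVC, ModelSpec]] = {}
    specs: list[ModelSpec] = []
    for layer in cfg.layers:
        cols = layer_columns(columns, layer)
        for pair in PAIR_ORDER:
            rows = classes.isin(pair).to_numpy()
            if classes[rows].nunique() < 2:
                raise ValueError(f"training fold lacks a class for pair {pair}")
            Xp = Z.loc[rows, cols].to_numpy()
            yp = classes[rows].to_numpy()
            key = (layer, pair)
            if selected_override is not None:
                sel_names = selected_override[key]
                idx = [cols.index(s) for s in sel_names]
            else:
                idx = forward_select(
                    Xp, yp == pair[1], cfg.n_features, rng,
                    internal_cv=cfg.internal_cv, C=cfg.C,
                )
                sel_names = tuple(cols[i] for i in idx)
            Xsel = Xp[:, idx]
            mv = float(Xsel.var(axis=0).mean())
            gamma = 1.0 / (cfg.n_features * mv) if mv > 0 else 1.0 / cfg.n_features
            model = train_binary(Xsel, yp, C=cfg.C, gamma=gamma)
            spec = ModelSpec(layer, pair, sel_names, cfg.C, gamma)
            bank[key] = (model, spec)
            specs.append(spec)
    return FoldModels(zs, columns, bank, specs)


def predict_fold(fold: FoldModels, features: pd.DataFrame) -> list[Prediction]:
    """Vote-classify every row of ``features`` with a fitted fold's bank."""
    Z = zscore_apply(features[fold.columns].to_numpy(dtype=float), fold.zscore)
    Z = pd.DataFrame(Z, index=features.index, columns=fold.columns)
    n = len(features)
    votes = [({c: 0 for c in CLASSES},
              {p: {p[0]: 0, p[1]: 0} for p in PAIR_ORDER}) for _ in range(n)]
    for (layer, pair), (model, _spec) in fold.bank.items():
        labels = model.predict(Z[list(_spec.selected)].to_numpy())
        for i, lab in enumerate(labels):
            votes[i][0][lab] += 1
            votes[i][1][pair][lab] += 1
    preds = []
    for i, eye_id in enumerate(features.index):
        v, pt = votes[i]
        tally = VoteTally(v, pt)
        preds.append(Prediction(str(eye_id), _resolve_votes(v, pt), tally))
    return preds


def _partition(meta: pd.DataFrame, cfg: CVConfig, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds over the partition unit; returns eye-row index splits.

    Redraws (bounded) if any training split misses a class, then errors.
    """
    if cfg.unit == "subject":
        units = meta.drop_duplicates("subject_id")
        ids = units["subject_id"].to_numpy()
        labels = units["class"].to_numpy()
    else:
        ids = meta["eye_id"].to_numpy()
        labels = meta["class"].to_numpy()
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=cfg.k, shuffle=True,
                              random_state=(seed + attempt) % (2**32))
        splits = []
        ok = True
        for tr, te in skf.split(ids, labels):
            if len(np.unique(labels[tr])) < len(np.unique(labels)):
                ok = False
                break
            if cfg.unit == "subject":
                tr_rows = meta.index[meta["subject_id"].isin(ids[tr])].to_numpy()
                te_rows = meta.index[meta["subject_id"].isin(ids[te])].to_numpy()
            else:
                tr_rows, te_rows = tr, te
            splits.append((tr_rows, te_rows))
        if ok:
            return splits
    raise ValueError("could not draw a partition with every class in every fold")


def run_cv(features: pd.DataFrame, meta: pd.DataFrame, cfg: CVConfig) -> list[RunResult]:
    """Repeated stratified k-fold cross-validation of the full pipeline.

    ``features``: one row per eye (index = eye_id), columns "{layer}.{name}".
    ``meta``: columns eye_id, subject_id, class — aligned row-for-row.
    Returns one :class:`RunResult` per run; fully reproducible from
    ``cfg.seed``.
    """
    meta = meta.reset_index(drop=True)
    features = features.reset_index(drop=True).set_index(meta["eye_id"])
    results = []
    for run in range(cfg.n_runs):
        ss = np.random.SeedSequence(cfg.seed, spawn_key=(run,))
        run_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(ss)
        splits = _partition(meta, cfg, run_seed)

        selected_override = None
        if cfg.selection == "global":
            full = fit_fold(features, meta.set_index("eye_id")["class"], cfg, rng)
            selected_override = {k: s.selected for k, (_, s) in full.bank.items()}

        rows = []
        specs: list[ModelSpec] = []
        for fold_i, (tr, te) in enumerate(splits):
            tr_ids = meta.loc[tr, "eye_id"]
            te_ids = meta.loc[te, "eye_id"]
            fold = fit_fold(
                features.loc[tr_ids],
                meta.set_index("eye_id").loc[tr_ids, "class"],
                cfg, rng, selected_override,
            )
            specs.extend(fold.specs)
            preds = predict_fold(fold, features.loc[te_ids])
            for (_, m), p in zip(meta.loc[te].iterrows(), preds):
                rows.append({
                    "eye_id": m["eye_id"], "subject_id": m["subject_id"],
                    "true": m["class"], "predicted": p.label, "fold": fold_i,
                })
        pred_df = pd.DataFrame(rows)
        cm = confusion(pred_df["predicted"], pred_df["true"])
        results.append(RunResult(run, pred_df, cm, specs, run_seed))
    return results
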