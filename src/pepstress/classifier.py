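"""Load-state discrimination from (ΔPEP, ΔHR) with k-nearest neighbours.

One feature point per subject and state (rest / mental / physical): the
state-mean PEP and heart rate expressed as deltas to the subject's single
rest-calibration measurement. Evaluation is subject-wise fivefold
cross-validation — all of a subject's points live in either the train or the
test split, never both — repeated with shuffled fold assignments to
stabilise the stochastic estimate.

Neighbour search is delegated to scikit-learn; the vote uses a deterministic
tie-break (smaller summed neighbour distance, then fixed class order) so the
decision map is reproducible regardless of training-point order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from pepstress.config import ClassifierConfig
from pepstress.protocol import STATES
from pepstress.stress_stats import rest_reference

FEATURE_COLUMNS = ["subject_id", "state", "d_pep_ms", "d_hr_bpm"]


def build_features(measurements: pd.DataFrame) -> pd.DataFrame:
    """One (ΔPEP, ΔHR) point per subject per state.

    Deltas are computed against the subject's rest-calibration measurement
    (their single first valid rest-phase record); the rest-state point uses
    the mean over the remaining rest-state measurements. Subjects missing a
    valid calibration or any state are excluded (listed in ``attrs``).
    """
    valid = measurements[measurements["valid"].astype(bool)]
    ref_pep = rest_reference(measurements)
    rest_rows = valid[valid["phase"] == "rest"]
    ref_hr = rest_rows.groupby("subject_id")["hr_bpm"].first()

    rows, excluded = [], []
    for sid, grp in valid.groupby("subject_id"):
        if sid not in ref_pep.index:
            excluded.append(sid)
            continue
        states = {}
        for state in STATES:
            sub = grp[grp["state"] == state]
            if state == "rest":
                # drop the calibration row itself where possible
                non_cal = sub.iloc[1:] if len(sub) > 1 else sub
                states[state] = non_cal
            else:
                states[state] = sub
        if any(len(v) == 0 for v in states.values()):
            excluded.append(sid)
            continue
        for state, sub in states.items():
            rows.append((sid, state,
                         sub["pep_ms"].mean() - ref_pep[sid],
                         sub["hr_bpm"].mean() - ref_hr[sid]))
    out = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    out.attrs["excluded_subjects"] = excluded
    return out


class KnnLoadClassifier:
    """k-NN on z-scored (ΔPEP, ΔHR) with deterministic tie-breaking.

    Standardisation statistics are fitted on the training data only. Ties in
    the neighbour vote are resolved by the smaller summed neighbour distance
    and then by fixed class order (rest, mental, physical).
    """

    def __init__(self, k: int = 13, standardize: bool = True):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KnnLoadClassifier":
        X = np.asarray(X, dtype=float)
        if self.k >= len(X):
            raise ValueError(f"k={self.k} must be smaller than the training set ({len(X)})")
        self._mu = X.mean(axis=0) if self.standardize else np.zeros(X.shape[1])
        self._sigma = X.std(axis=0) if self.standardize else np.ones(X.shape[1])
        self._sigma = np.where(self._sigma == 0, 1.0, self._sigma)
        self._nn = NearestNeighbors(n_neighbors=self.k).fit((X - self._mu) / self._sigma)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=float) - self._mu) / self._sigma
        dist, idx = self._nn.kneighbors(X)
        out = []
        for d_row, i_row in zip(dist, idx):
            labels = self._y[i_row]
            counts = {c: int(np.sum(labels == c)) for c in STATES if np.any(labels == c)}
            top = max(counts.values())
            tied = [c for c, n in counts.items() if n == top]
            if len(tied) > 1:
                sums = {c: float(d_row[labels == c].sum()) for c in tied}
                best = min(sums.values())
                tied = [c for c in tied if sums[c] == best]  # then fixed class order
            out.append(tied[0])
        return np.asarray(out)


@dataclass
class ClassifierReport:
    """Aggregate confusion counts and macro scores over all folds/repeats."""

    confusion_matrix: pd.DataFrame
    ppv: dict[str, float]
    sensitivity: dict[str, float]
    macro_ppv: float
    macro_sensitivity: float
    k: int
    n_folds: int
    n_repeats: int
    fold_scores: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion_matrix.to_dict(),
            "ppv": self.ppv, "sensitivity": self.sensitivity,
            "macro_ppv": self.macro_ppv, "macro_sensitivity": self.macro_sensitivity,
            "k": self.k, "n_folds": self.n_folds, "n_repeats": self.n_repeats,
        }


def _subject_folds(subjects: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(subjects)
    return [order[i::n_folds] for i in range(n_folds)]


def evaluate_knn(features: pd.DataFrame, config: ClassifierConfig | None = None,
                 seed: int = 0) -> ClassifierReport:
    """Subject-wise k-fold evaluation of the k-NN load-state classifier.

    Per repeat, subjects are partitioned into ``n_folds`` folds; per fold the
    classifier is fitted on the training subjects' points (standardisation
    fitted on train only) and scored on the held-out subjects. Positive
    predictive value and sensitivity are computed per class per fold and
    averaged over the three classes and all folds/repeats.
    """
    config = config or ClassifierConfig()
    rng = np.random.default_rng(seed)
    subjects = np.asarray(sorted(features["subject_id"].unique()))
    X = features[["d_pep_ms", "d_hr_bpm"]].to_numpy(dtype=float)
    y = features["state"].to_numpy()
    sid = features["subject_id"].to_numpy()

    confusion = pd.DataFrame(0, index=list(STATES), columns=list(STATES))
    fold_rows = []
    for rep in range(config.n_repeats):
        for fold, test_subjects in enumerate(_subject_folds(subjects, config.n_folds, rng)):
            test_mask = np.isin(sid, test_subjects)
            if not test_mask.any() or test_mask.all():
                continue
            clf = KnnLoadClassifier(config.k, config.standardize)
            clf.fit(X[~test_mask], y[~test_mask])
            pred = clf.predict(X[test_mask])
            truth = y[test_mask]
            scores = {"repeat": rep, "fold": fold}
            for c in STATES:
                tp = int(np.sum((pred == c) & (truth == c)))
                fp = int(np.sum((pred == c) & (truth != c)))
                fn = int(np.sum((pred != c) & (truth == c)))
                scores[f"ppv_{c}"] = tp / (tp + fp) if tp + fp else np.nan
                scores[f"sens_{c}"] = tp / (tp + fn) if tp + fn else np.nan
            fold_rows.append(scores)
            for t_lab, p_lab in zip(truth, pred):
                confusion.loc[t_lab, p_lab] += 1

    folds = pd.DataFrame(fold_rows)
    ppv = {c: float(np.nanmean(folds[f"ppv_{c}"])) for c in STATES}
    sens = {c: float(np.nanmean(folds[f"sens_{c}"])) for c in STATES}
    return ClassifierReport(
        confusion_matrix=confusion,
        ppv=ppv, sensitivity=sens,
        macro_ppv=float(np.mean(list(ppv.values()))),
        macro_sensitivity=float(np.mean(list(sens.values()))),
        k=config.k, n_folds=config.n_folds, n_repeats=config.n_repeats,
        fold_scores=folds,
    )


def decision_map(features: pd.DataFrame, config: ClassifierConfig | None = None,
                 d_hr_range: tuple[float, float] = (-15.0, 90.0),
                 d_pep_range: tuple[float, float] = (-70.0, 25.0),
                 n_grid: int = 120) -> pd.DataFrame:
    """Predicted load state over a (ΔHR, ΔPEP) grid, trained on all features."""
    if n_grid < 2:
        raise ValueError("empty grid")
    config = config or ClassifierConfig()
    clf = KnnLoadClassifier(config.k, config.standardize)
    clf.fit(features[["d_pep_ms", "d_hr_bpm"]].to_numpy(dtype=float),
            features["state"].to_numpy())
    hr = np.linspace(*d_hr_range, n_grid)
    pep = np.linspace(*d_pep_range, n_grid)
    gh, gp = np.meshgrid(hr, pep)
    labels = clf.predict(np.column_stack([gp.ravel(), gh.ravel()]))
    return pd.DataFrame({"d_hr_bpm": gh.ravel(), "d_pep_ms": gp.ravel(),
                         "state": labels})
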