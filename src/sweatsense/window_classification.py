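"""Paired-window (run-start vs run-end) classifier sweep with importance ranking.

For each window separation, one start window (negative class) and one end
window (positive class) are taken from every run, features are extracted, and
a depth-2, learning-rate-0.01 gradient-boosted tree ensemble is scored with
run-grouped k-fold cross-validation.  The sweep moves both windows inwards by
the window step until they would overlap.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GroupKFold

from .feature_extraction import WindowSpec, extract_window_features
from .synthetic_ppg import PPG_WAVELENGTHS, PPGRecording

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierParams:
    """Boosted-tree hyperparameters; everything else stays at library defaults."""

    max_depth: int = 2
    learning_rate: float = 0.01
    n_estimators: int = 100
    seed: int = 0

    def make(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            random_state=self.seed,
        )


@dataclass
class WindowPairDataset:
    """One labelled start/end window pair per run."""

    X: pd.DataFrame
    y: np.ndarray  # 0 = start (negative), 1 = end (positive)
    groups: np.ndarray  # run identifier per row
    separation_s: float  # window center-to-center separation

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.y) != len(self.groups):
            raise ClassificationError("dataset rows misaligned")
        n_pos = int(np.sum(self.y == 1))
        if n_pos * 2 != len(self.y):
            raise ClassificationError("class balance must be exact")


def sweep_separations(
    duration_s: float, window: WindowSpec
) -> list[tuple[float, float, float]]:
    """(left start, right start, center separation) per sweep step.

    Step 0 anchors the windows at the run ends; each later step moves both
    windows inwards by one window step until they would overlap.
    """
    w, s = window.duration_s, window.step_s
    if duration_s < 2 * w:
        raise ClassificationError("run shorter than two windows")
    out = []
    k = 0
    while True:
        left = k * s
        right = duration_s - w - k * s
        if right < left + w:
            break
        out.append((left, right, right - left))
        k += 1
    return out


def build_pair_dataset(
    recordings: list[PPGRecording],
    window: WindowSpec,
    left_start_s: float,
    right_start_s: float,
    wavelengths=PPG_WAVELENGTHS,
    include_frequency_domain: bool = True,
    n_channels: int | None = None,
) -> WindowPairDataset:
    """Extract one labelled window pair per run at fixed window positions."""
    rows, labels, groups = [], [], []
    kwargs = {} if n_channels is None else {"n_channels": n_channels}
    for run_id, rec in enumerate(recordings):
        if rec.duration_s < right_start_s + window.duration_s:
            logger.warning("run %d too short for this gap: skipped", run_id)
            continue
        for start, label in ((left_start_s, 0), (right_start_s, 1)):
            fv = extract_window_features(
                rec,
                start,
                window,
                wavelengths=wavelengths,
                include_frequency_domain=include_frequency_domain,
                **kwargs,
            )
            rows.append(fv.values)
            labels.append(label)
            groups.append(run_id)
    if not rows:
        raise ClassificationError("no run is long enough for this gap")
    X = pd.DataFrame(rows)
    return WindowPairDataset(
        X=X,
        y=np.asarray(labels),
        groups=np.asarray(groups),
        separation_s=right_start_s - left_start_s,
    )


def grouped_cv_accuracy(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    params: ClassifierParams,
    folds: int = 4,
) -> float:
    """Mean accuracy over run-grouped folds (no run spans train and test)."""
    if len(np.unique(groups)) < folds:
        raise ClassificationError("fewer runs than folds")
    cv = GroupKFold(n_splits=folds)
    accs = []
    Xv = X.to_numpy()
    for train, test in cv.split(Xv, y, groups):
        clf = params.make()
        clf.fit(Xv[train], y[train])
        accs.append(float(np.mean(clf.predict(Xv[test]) == y[test])))
    return float(np.mean(accs))


@dataclass
class GapSweepStep:
    separation_s: float
    left_start_s: float
    right_start_s: float
    accuracy: float
    model: GradientBoostingClassifier
    dataset: WindowPairDataset


@dataclass
class GapSweepResult:
    """Cross-validated accuracy and trained model per window separation."""

    steps: list[GapSweepStep]
    window: WindowSpec
    folds: int
    params: ClassifierParams

    def __post_init__(self) -> None:
        seps = [st.separation_s for st in self.steps]
        if any(b >= a for a, b in zip(seps, seps[1:])):
            raise ClassificationError("steps must be ordered by decreasing gap")
        if any(not 0.0 <= st.accuracy <= 1.0 for st in self.steps):
            raise ClassificationError("accuracies must lie in [0, 1]")

    @property
    def separations_s(self) -> np.ndarray:
        return np.array([st.separation_s for st in self.steps])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([st.accuracy for st in self.steps])

    def mean_accuracy(self, min_separation_s: float = 0.0) -> float:
        sel = self.separations_s >= min_separation_s
        if not sel.any():
            raise ClassificationError("no sweep step at that separation")
        return float(self.accuracies[sel].mean())

    def to_json(self, path) -> None:
        payload = {
            "window_s": self.window.duration_s,
            "step_s": self.window.step_s,
            "folds": self.folds,
            "separations_s": self.separations_s.tolist(),
            "accuracies": self.accuracies.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def gap_sweep(
    recordings: list[PPGRecording],
    window: WindowSpec | None = None,
    params: ClassifierParams | None = None,
    folds: int = 4,
    wavelengths=PPG_WAVELENGTHS,
    include_frequency_domain: bool = True,
    n_channels: int | None = None,
) -> GapSweepResult:
    """Train one classifier per separation, from maximal gap to first overlap."""
    window = window or WindowSpec()
    params = params or ClassifierParams()
    if len(recordings) < 2 * folds:
        raise ClassificationError(
            f"need at least {2 * folds} runs for {folds}-fold grouped CV"
        )
    duration = min(rec.duration_s for rec in recordings)
    steps = []
    for left, right, sep in sweep_separations(duration, window):
        ds = build_pair_dataset(
            recordings,
            window,
            left,
            right,
            wavelengths=wavelengths,
            include_frequency_domain=include_frequency_domain,
            n_channels=n_channels,
        )
        acc = grouped_cv_accuracy(ds.X, ds.y, ds.groups, params, folds)
        model = params.make()
        model.fit(ds.X.to_numpy(), ds.y)
        steps.append(
            GapSweepStep(
                separation_s=sep,
                left_start_s=left,
                right_start_s=right,
                accuracy=acc,
                model=model,
                dataset=ds,
            )
        )
    return GapSweepResult(steps=steps, window=window, folds=folds, params=params)


def feature_importance(
    model: GradientBoostingClassifier,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.Series:
    """Mean-absolute permutation attribution per feature.

    Stands in for tree-path Shapley attributions, which need an external
    attribution library; permutation importance is the documented fallback.
    """
    res = permutation_importance(
        model, X.to_numpy(), y, n_repeats=n_repeats, random_state=seed
    )
    return pd.Series(np.abs(res.importances_mean), index=X.columns)


def rank_features(
    sweep: GapSweepResult, top_k: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Importance table: rows = union of per-model top-k features, cols = models."""
    n_features = sweep.steps[0].dataset.X.shape[1]
    if top_k > n_features:
        warnings.warn(
            f"top_k={top_k} exceeds feature count {n_features}; clipped"
        )
        top_k = n_features
    per_model = {}
    selected: list[str] = []
    for st in sweep.steps:
        imp = feature_importance(st.model, st.dataset.X, st.dataset.y, seed=seed)
        per_model[f"sep_{int(st.separation_s)}s"] = imp
        for name in imp.sort_values(ascending=False).head(top_k).index:
            if name not in selected:
                selected.append(name)
    table = pd.DataFrame({col: imp for col, imp in per_model.items()})
    return table.loc[selected]
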