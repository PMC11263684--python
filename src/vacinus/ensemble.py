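"""The peptide-MHC immunogenicity ensemble classifier.

A binary classifier over candidate feature vectors, trained with recursive
feature elimination (RFE) that optimizes grouped cross-validated area under
the precision-recall curve (PRAUC), followed by an operating-threshold
selection rule: among score cuts whose F1 is within tolerance of the maximum,
take the one with the highest sensitivity (ties -> lowest threshold).

Exposed statsmodels-style: ``ImmunogenicityModel`` is built from data and
``fit()`` returns an ``ImmunogenicityResults`` carrying the fitted learner,
the selected feature subset, the decision threshold and cross-validated
metrics, with ``summary()``, ``predict()`` and JSON persistence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold


# ---------------------------------------------------------------------------
# metrics


def prauc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve by step-wise integration.

    Points are taken at every distinct score threshold in decreasing order;
    the area is sum over points of (recall_i - recall_{i-1}) * precision_i.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("PRAUC undefined for single-class labels")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = y.sum()
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at the last index of each distinct score
    distinct = np.r_[s[1:] != s[:-1], True]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def confusion_metrics(pred: np.ndarray, y: np.ndarray) -> dict[str, float]:
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return {"sensitivity": sens, "ppv": ppv, "f1": f1}


def select_threshold(
    scores: Sequence[float], labels: Sequence[int], f1_tol: float = 1e-9
) -> float:
    """Operating-point rule: among distinct score cuts whose F1 is within
    ``f1_tol`` of the maximum F1, return the cut with maximal sensitivity;
    ties break to the lowest threshold. Prediction at a cut t is score >= t.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    cuts = np.unique(s)
    if len(cuts) < 2:
        raise ValueError("degenerate scores: all values identical")
    rows = []
    for t in cuts:
        m = confusion_metrics((s >= t).astype(int), y)
        rows.append((t, m["f1"], m["sensitivity"]))
    best_f1 = max(r[1] for r in rows)
    eligible = [r for r in rows if r[1] >= best_f1 - f1_tol]
    best_sens = max(r[2] for r in eligible)
    return float(min(r[0] for r in eligible if r[2] == best_sens))


# ---------------------------------------------------------------------------
# model


def _make_learner(spec: str, seed: int):
    if spec == "gbm":
        return GradientBoostingClassifier(
            n_estimators=60, max_depth=2, learning_rate=0.1, random_state=seed
        )
    if spec == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown learner spec {spec!r}")


def _importances(learner, n_features: int) -> np.ndarray:
    if hasattr(learner, "feature_importances_"):
        return np.asarray(learner.feature_importances_)
    return np.abs(np.asarray(learner.coef_).ravel())


class ImmunogenicityModel:
    """Binary immunogenicity classifier over a candidate feature matrix.

    Parameters
    ----------
    X : DataFrame, candidates x features.
    y : binary labels (immunogenic = 1).
    groups : per-candidate patient ids for grouped cross-validation
        (prevents within-patient leakage); defaults to one group per row.
    """

    def __init__(self, X: pd.DataFrame, y, groups=None):
        self.X = pd.DataFrame(X).astype(float)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(self.y)) < 2:
            raise ValueError("need both classes present to fit")
        self.groups = (
            np.asarray(groups) if groups is not None else np.arange(len(self.y))
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", group_col: str | None = "patient"
    ) -> "ImmunogenicityModel":
        cols = [c for c in df.columns if c not in (label_col, group_col)]
        groups = df[group_col].to_numpy() if group_col and group_col in df else None
        return cls(df[cols], df[label_col].to_numpy(), groups)

    # -- cross-validation helpers

    def _folds(self, cv_folds: int):
        n_groups = len(np.unique(self.groups))
        k = min(cv_folds, n_groups)
        if k < cv_folds:
            warnings.warn(
                f"only {n_groups} groups; reducing CV folds to {k}", stacklevel=3
            )
        return GroupKFold(n_splits=k)

    def _cv_scores(self, features: list[str], learner_spec: str, seed: int, cv) -> np.ndarray:
        """Out-of-fold predicted probabilities for the given feature subset."""
        Xs = self.X[features].to_numpy()
        oof = np.full(len(self.y), np.nan)
        for tr, te in cv.split(Xs, self.y, self.groups):
            if len(np.unique(self.y[tr])) < 2:
                oof[te] = float(self.y[tr][0])
                continue
            lr = _make_learner(learner_spec, seed)
            lr.fit(Xs[tr], self.y[tr])
            oof[te] = lr.predict_proba(Xs[te])[:, 1]
        return oof

    def _cv_prauc(self, features: list[str], learner_spec: str, seed: int, cv) -> float:
        return prauc(self._cv_scores(features, learner_spec, seed, cv), self.y)

    # -- fitting

    def fit(
        self,
        learner: str = "gbm",
        cv_folds: int = 5,
        seed: int = 0,
        min_features: int = 1,
        f1_tol: float = 1e-9,
    ) -> "ImmunogenicityResults":
        """Recursive feature elimination optimizing grouped-CV PRAUC, then
        refit on all data and select the decision threshold on out-of-fold
        scores by the highest-sensitivity-at-max-F1 rule.

        Backward elimination drops the least-important feature (importance
        from a learner fit on all data) at each step; the retained subset is
        the one with maximal CV PRAUC, ties broken toward fewer features.
        Fully reproducible given ``seed``.
        """
        if len(self.y) < 20:
            warnings.warn("fewer than 20 observations; estimates will be unstable")
        cv = self._folds(cv_folds)
        features = list(self.X.columns)
        if len(features) < 2:
            raise ValueError("need at least 2 features for elimination")

        path: list[tuple[list[str], float]] = []
        current = features[:]
        while True:
            score = self._cv_prauc(current, learner, seed, cv)
            path.append((current[:], score))
            if len(current) <= min_features:
                break
            probe = _make_learner(learner, seed)
            probe.fit(self.X[current].to_numpy(), self.y)
            imp = _importances(probe, len(current))
            current = [f for i, f in enumerate(current) if i != int(np.argmin(imp))]

        # max PRAUC; ties -> fewest features (path is ordered largest-first)
        best_score = max(s for _, s in path)
        tied = [(fs, s) for fs, s in path if s >= best_score - 1e-12]
        selected = min(tied, key=lambda t: len(t[0]))[0]

        final = _make_learner(learner, seed)
        final.fit(self.X[selected].to_numpy(), self.y)
        oof = self._cv_scores(selected, learner, seed, cv)
        threshold = select_threshold(oof, self.y, f1_tol=f1_tol)
        metrics = confusion_metrics((oof >= threshold).astype(int), self.y)
        metrics["prauc"] = prauc(oof, self.y)
        metrics["prauc_full_featureset"] = path[0][1]

        return ImmunogenicityResults(
            model=self,
            learner=final,
            learner_spec=learner,
            selected_features=list(selected),
            threshold=threshold,
            training_metrics=metrics,
            seed=seed,
            rfe_path=[(list(fs), float(s)) for fs, s in path],
        )


@dataclass
class ImmunogenicityResults:
    """Fitted ensemble: selected features, decision threshold, CV metrics."""

    model: ImmunogenicityModel | None
    learner: object
    learner_spec: str
    selected_features: list[str]
    threshold: float
    training_metrics: dict[str, float]
    seed: int
    rfe_path: list[tuple[list[str], float]]

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score new candidates; ``pass`` means score >= threshold."""
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        if len(X) == 0:
            return pd.DataFrame(columns=["score", "pass"])
        scores = self.learner.predict_proba(
            X[self.selected_features].to_numpy(dtype=float)
        )[:, 1]
        return pd.DataFrame(
            {"score": scores, "pass": scores >= self.threshold}, index=X.index
        )

    def evaluate(self, X: pd.DataFrame, y) -> dict[str, float]:
        y = np.asarray(y, dtype=int)
        scores = self.predict(X)["score"].to_numpy()
        m = confusion_metrics((scores >= self.threshold).astype(int), y)
        m["prauc"] = prauc(scores, y)
        return m

    def summary(self) -> str:
        lines = [
            "Immunogenicity ensemble (pMHC stage)",
            "=" * 44,
            f"learner:            {self.learner_spec}",
            f"seed:               {self.seed}",
            f"features selected:  {len(self.selected_features)} of "
            f"{len(self.rfe_path[0][0])}",
            f"decision threshold: {self.threshold:.4f}  (score >= t passes)",
            "-" * 44,
            "cross-validated training metrics:",
        ]
        for k in ("prauc_full_featureset", "prauc", "sensitivity", "ppv", "f1"):
            if k in self.training_metrics:
                lines.append(f"  {k:<22} {self.training_metrics[k]:.4f}")
        lines.append("-" * 44)
        lines.append("selected features: " + ", ".join(self.selected_features))
        return "\n".join(lines)

    # -- persistence (learner hyperparameters + threshold; the learner blob
    #    itself is refit from data on load, keeping the artifact text-only)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "learner_spec": self.learner_spec,
            "selected_features": self.selected_features,
            "threshold": self.threshold,
            "training_metrics": self.training_metrics,
            "seed": self.seed,
            "rfe_path": [[fs, s] for fs, s in self.rfe_path],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path, model: ImmunogenicityModel) -> "ImmunogenicityResults":
        payload = json.loads(Path(path).read_text())
        learner = _make_learner(payload["learner_spec"], payload["seed"])
        learner.fit(
            model.X[payload["selected_features"]].to_numpy(), model.y
        )
        return cls(
            model=model,
            learner=learner,
            learner_spec=payload["learner_spec"],
            selected_features=payload["selected_features"],
            threshold=payload["threshold"],
            training_metrics=payload["training_metrics"],
            seed=payload["seed"],
            rfe_path=[(fs, s) for fs, s in payload["rfe_path"]],
        )


def rfe_fit(
    X: pd.DataFrame, y, groups=None, learner: str = "gbm", cv_folds: int = 5, seed: int = 0
) -> ImmunogenicityResults:
    """Functional wrapper: build the model and fit in one call."""
    return ImmunogenicityModel(X, y, groups).fit(
        learner=learner, cv_folds=cv_folds, seed=seed
    )
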