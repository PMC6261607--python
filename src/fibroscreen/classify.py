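"""Control-anchored SVM classification and per-well percent effect.

Cells from the in-plate control wells train a linear support-vector
classifier: the TGF-β1-stimulated negative controls supply myofibroblast
exemplars (0% compound effect) and the unstimulated positive controls
supply fibroblast exemplars (100% effect). The model classifies every cell
on the plate; per-well myofibroblast fractions are rescaled against the
control means to a percent-effect value — 0% at the negative-control mean,
100% at the positive-control mean.

A linear kernel on standardized features keeps the per-feature weights
interpretable and exportable as a relevance ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .hca import feature_columns

__all__ = [
    "ClassifierModel",
    "WellEffect",
    "train_classifier",
    "rank_feature_weights",
    "classify_cells",
    "well_percent_effect",
]

MYOFIBROBLAST = "myofibroblast"
FIBROBLAST = "fibroblast"


@dataclass
class ClassifierModel:
    """A trained linear decision function on standardized cell features.

    Decision value > 0 ⇒ myofibroblast. ``cv_accuracy`` is the stratified
    k-fold cross-validation accuracy measured on the training controls.
    """

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bias: float
    cv_accuracy: float
    k_folds: int
    seed: int
    n_train: int
    control_wells: list[str] = field(default_factory=list)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.means) / self.sds
        return Z @ self.weights + self.bias

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "cv_accuracy": self.cv_accuracy,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "n_train": self.n_train,
            "control_wells": self.control_wells,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            feature_names=d["feature_names"],
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            weights=np.asarray(d["weights"]),
            bias=d["bias"],
            cv_accuracy=d["cv_accuracy"],
            k_folds=d["k_folds"],
            seed=d["seed"],
            n_train=d["n_train"],
            control_wells=d.get("control_wells", []),
        )


@dataclass
class WellEffect:
    """Per-well aggregate: classified myofibroblast fraction and the
    control-anchored percent effect."""

    well: str
    n_cells: int
    myo_fraction: float
    percent_effect: float
    role: str = "sample"


def train_classifier(
    features: pd.DataFrame,
    layout,
    k: int = 10,
    seed: int = 0,
    *,
    C: float = 1.0,
    balance: bool = True,
) -> ClassifierModel:
    """Train a linear SVM on the two control-well cell populations.

    Cells in negative-control wells are labelled myofibroblast, cells in
    positive-control wells fibroblast (the wells, not per-cell ground
    truth, define the training labels — as in a real screen). The majority
    class is subsampled to balance training when ``balance`` is set.
    """
    roles = layout.wells.set_index("well")["role"]
    ctrl = features[features["well"].map(roles).isin(["neg_control", "pos_control"])]
    if ctrl.empty:
        raise ValueError("no control-well cells found in the feature table")
    y = (ctrl["well"].map(roles) == "neg_control").astype(int).to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    counts = np.bincount(y)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} cells per control role")

    cols = feature_columns(ctrl)
    X = ctrl[cols].to_numpy(dtype=float)

    if balance and counts[0] != counts[1]:
        rng = np.random.default_rng(seed)
        keep = []
        n_min = counts.min()
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if idx.size > n_min:
                idx = rng.choice(idx, size=n_min, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        X, y = X[keep], y[keep]

    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", LinearSVC(C=C, dual="auto", random_state=seed, max_iter=10000)),
        ]
    )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv_acc = float(cross_val_score(pipe, X, y, cv=cv, scoring="accuracy").mean())
    pipe.fit(X, y)

    scaler: StandardScaler = pipe.named_steps["scale"]
    svm: LinearSVC = pipe.named_steps["svm"]
    sds = scaler.scale_.copy()
    sds[sds == 0] = 1.0
    return ClassifierModel(
        feature_names=list(cols),
        means=scaler.mean_.copy(),
        sds=sds,
        weights=svm.coef_.ravel().copy(),
        bias=float(svm.intercept_[0]),
        cv_accuracy=cv_acc,
        k_folds=k,
        seed=seed,
        n_train=int(y.size),
        control_wells=sorted(ctrl["well"].unique()),
    )


def rank_feature_weights(model: ClassifierModel) -> pd.DataFrame:
    """Features ranked by absolute decision weight (descending).

    Ties break deterministically by feature name. The top of this ranking
    identifies which measurements carry the phenotype contrast.
    """
    if model.weights is None or len(model.weights) == 0:
        raise ValueError("model has no trained weights")
    df = pd.DataFrame(
        {"feature": model.feature_names, "weight": model.weights}
    )
    df["abs_weight"] = df["weight"].abs()
    df = df.sort_values(
        ["abs_weight", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["rank", "feature", "weight"]]


def classify_cells(
    model: ClassifierModel, features: pd.DataFrame
) -> pd.DataFrame:
    """Classify every cell; returns well, cell_id, decision value, label."""
    if features.empty:
        return pd.DataFrame(columns=["well", "cell_id", "decision", "label"])
    cols = feature_columns(features)
    if set(cols) != set(model.feature_names):
        raise ValueError("feature columns do not match the trained model")
    X = features[model.feature_names].to_numpy(dtype=float)
    dec = model.decision_values(X)
    return pd.DataFrame(
        {
            "well": features["well"].to_numpy(),
            "cell_id": features["cell_id"].to_numpy(),
            "decision": dec,
            "label": np.where(dec > 0, MYOFIBROBLAST, FIBROBLAST),
        }
    )


def well_percent_effect(
    labels: pd.DataFrame,
    layout,
    *,
    clip: bool = False,
) -> list[WellEffect]:
    """Aggregate per-cell labels to per-well percent effect.

    percent effect = 100 · (f_neg − f_well) / (f_neg − f_pos), where f_neg
    and f_pos are the mean classified myofibroblast fractions of the
    negative (stimulated) and positive (unstimulated) control wells.
    Unclipped by default: effects outside [0, 100] are informative.
    """
    roles = layout.wells.set_index("well")["role"]
    lab = labels.assign(is_myo=(labels["label"] == MYOFIBROBLAST).astype(float))
    per_well = lab.groupby("well").agg(
        n_cells=("is_myo", "size"), myo_fraction=("is_myo", "mean")
    )
    per_well["role"] = per_well.index.map(roles)

    f_neg = per_well.loc[per_well["role"] == "neg_control", "myo_fraction"].mean()
    f_pos = per_well.loc[per_well["role"] == "pos_control", "myo_fraction"].mean()
    if np.isnan(f_neg) or np.isnan(f_pos):
        raise ValueError("both control roles must be classified on the plate")
    if f_neg == f_pos:
        raise ValueError("degenerate controls: equal mean fractions")

    out = []
    for wname, row in per_well.iterrows():
        eff = 100.0 * (f_neg - row["myo_fraction"]) / (f_neg - f_pos)
        if clip:
            eff = float(np.clip(eff, 0.0, 100.0))
        out.append(
            WellEffect(
                well=str(wname),
                n_cells=int(row["n_cells"]),
                myo_fraction=float(row["myo_fraction"]),
                percent_effect=float(eff),
                role=str(row["role"]) if isinstance(row["role"], str) else "sample",
            )
        )
    return out


def effects_frame(effects: list[WellEffect]) -> pd.DataFrame:
    """Tabular view of a list of :class:`WellEffect`."""
    return pd.DataFrame(
        [
            {
                "well": e.well, "role": e.role, "n_cells": e.n_cells,
                "myo_fraction": e.myo_fraction, "percent_effect": e.percent_effect,
            }
            for e in effects
        ]
    )
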