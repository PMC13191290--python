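"""Element-responsiveness classification and predictive-feature ranking.

A gradient-boosted tree ensemble (XGBoost) with L1/L2 leaf-weight penalties
is trained on the binary occupancy matrix to separate responsive elements
from insensitive-linked negatives. Class imbalance is handled by synthetic
minority oversampling (SMOTE) fitted strictly inside each training fold;
performance is summarized by held-out accuracy, AUROC and AUPR under
stratified k-fold cross-validation. Feature contributions come from exact
TreeSHAP attributions (additive, locally accurate). Predictive features are
ranked by the natural-log odds ratio of occupancy at positive vs negative
elements and gated on footprint evidence under stimulation and occupancy in
at least 10% of positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

DEFAULT_HYPERPARAMS = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.1,
    "reg_alpha": 0.5,   # L1 leaf-weight penalty
    "reg_lambda": 1.0,  # L2 leaf-weight penalty
}
MIN_OCCUPANCY_FRACTION = 0.10


@dataclass
class TrainingSet:
    features: pd.DataFrame        # rows = labelled elements, columns = factors
    labels: np.ndarray            # 1 = positive class, 0 = negative

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if len(self.features) != len(self.labels):
            raise ValueError("feature rows and labels disagree in length")
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("training set must contain both classes")


@dataclass
class ModelMetrics:
    accuracy: list[float] = field(default_factory=list)
    auroc: list[float] = field(default_factory=list)
    aupr: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.accuracy)

    def summary(self) -> dict[str, float]:
        out = {}
        for name in ("accuracy", "auroc", "aupr"):
            vals = np.asarray(getattr(self, name))
            out[f"mean_{name}"] = float(vals.mean())
            out[f"sd_{name}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out


def smote_balance(ts: TrainingSet, k_neighbors: int = 5, seed: int = 0) -> TrainingSet:
    """Equalize class sizes by synthetic minority oversampling.

    Each synthetic row is x + u*(x' - x) with u ~ U[0,1], where x is a
    minority row and x' one of its k nearest minority neighbours (Euclidean).
    Original rows are preserved; synthetic values on binary features stay
    fractional, the standard behaviour.
    """
    y = ts.labels
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == n_neg:
        return TrainingSet(ts.features.copy(), y.copy())
    minority = 1 if n_pos < n_neg else 0
    need = abs(n_neg - n_pos)
    x_min = ts.features.to_numpy(dtype=float)[y == minority]
    if len(x_min) < k_neighbors + 1:
        raise ValueError(
            f"minority class has {len(x_min)} rows; needs >= k_neighbors+1 "
            f"({k_neighbors + 1}) — use a smaller k_neighbors"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x_min)
    _, idx = nn.kneighbors(x_min)          # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(x_min), size=need)
    pick = rng.integers(1, k_neighbors + 1, size=need)
    u = rng.random(size=need)
    synth = x_min[base] + u[:, None] * (x_min[idx[base, pick]] - x_min[base])
    synth_df = pd.DataFrame(synth, columns=ts.features.columns,
                            index=[f"synthetic_{i}" for i in range(need)])
    features = pd.concat([ts.features, synth_df])
    labels = np.concatenate([y, np.full(need, minority)])
    return TrainingSet(features, labels)


def train_classifier(
    ts: TrainingSet, hyperparams: dict | None = None, seed: int = 0
) -> XGBClassifier:
    """Fit the gradient-boosted ensemble with a fixed seed."""
    if len(np.unique(ts.labels)) < 2:
        raise ValueError("cannot train on a single class")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    model = XGBClassifier(
        **params,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    model.fit(ts.features.to_numpy(dtype=float), ts.labels)
    model.feature_names_kre_ = list(ts.features.columns)
    return model


def save_model(model: XGBClassifier, path) -> None:
    """Serialize the fitted ensemble as a Booster JSON artifact."""
    model.get_booster().save_model(str(path))


def load_model(path):
    """Reload a saved ensemble; returns a Booster with identical predictions.

    Use `predict_positive` to score a feature matrix with either the sklearn
    wrapper or a reloaded Booster.
    """
    import xgboost as xgb

    booster = xgb.Booster()
    booster.load_model(str(path))
    return booster


def predict_positive(model, features: pd.DataFrame) -> np.ndarray:
    """Positive-class probability from an XGBClassifier or a Booster."""
    import xgboost as xgb

    x = features.to_numpy(dtype=float)
    if isinstance(model, xgb.Booster):
        return model.predict(xgb.DMatrix(x))
    return model.predict_proba(x)[:, 1]


def kfold_evaluate(
    ts: TrainingSet,
    k: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
    oversample: bool = True,
    k_neighbors: int = 5,
) -> ModelMetrics:
    """Stratified k-fold cross-validation with oversampling inside each fold.

    SMOTE sees only the training split of each fold; metrics are computed on
    the untouched held-out split.
    """
    y = ts.labels
    if k > min(int(y.sum()), int((1 - y).sum())):
        raise ValueError(f"k={k} exceeds the minority class size")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    metrics = ModelMetrics()
    x = ts.features
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        fold_ts = TrainingSet(x.iloc[tr], y[tr])
        if oversample:
            fold_ts = smote_balance(fold_ts, k_neighbors=k_neighbors,
                                    seed=seed * 1000 + fold)
        model = train_classifier(fold_ts, hyperparams=hyperparams, seed=seed)
        x_te = x.iloc[te].to_numpy(dtype=float)
        prob = model.predict_proba(x_te)[:, 1]
        pred = (prob >= 0.5).astype(int)
        metrics.accuracy.append(float(accuracy_score(y[te], pred)))
        metrics.auroc.append(float(roc_auc_score(y[te], prob)))
        metrics.aupr.append(float(average_precision_score(y[te], prob)))
    return metrics


def attribute_features(model: XGBClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Per-element, per-feature additive attributions (exact TreeSHAP).

    Rows sum (with the bias term) to the margin prediction, so local accuracy
    holds. Returns the per-element attribution matrix; the per-feature score
    is `attribution_scores`.
    """
    names = getattr(model, "feature_names_kre_", None)
    if names is not None and list(features.columns) != list(names):
        raise ValueError("feature columns do not match the trained model")
    import xgboost as xgb

    dm = xgb.DMatrix(features.to_numpy(dtype=float))
    contribs = model.get_booster().predict(dm, pred_contribs=True)
    attr = pd.DataFrame(
        contribs[:, :-1], columns=features.columns, index=features.index
    )
    attr["_bias"] = contribs[:, -1]
    return attr


def attribution_scores(attr: pd.DataFrame) -> pd.Series:
    """Mean |attribution| per feature, bias excluded."""
    cols = [c for c in attr.columns if c != "_bias"]
    return attr[cols].abs().mean(axis=0).rename("attribution")


def log_odds_features(
    occ: pd.DataFrame, positives: set[str], negatives: set[str]
) -> pd.DataFrame:
    """Per-feature natural-log odds ratio of occupancy, positives vs negatives.

    2x2 cells: a = occupied positives, b = unoccupied positives,
    c = occupied negatives, d = unoccupied negatives. With any zero cell the
    Haldane-Anscombe +0.5 correction is applied to all four cells; otherwise
    the plain ln(ad/bc) is used.
    """
    positives, negatives = set(positives), set(negatives)
    if positives & negatives:
        raise ValueError("positive and negative id sets overlap")
    if not positives or not negatives:
        raise ValueError("both id sets must be non-empty")
    pos = occ.loc[sorted(positives & set(occ.index))]
    neg = occ.loc[sorted(negatives & set(occ.index))]
    if len(pos) != len(positives) or len(neg) != len(negatives):
        raise ValueError("id sets contain elements missing from the matrix")
    a = pos.sum(axis=0).to_numpy(dtype=float)
    b = len(pos) - a
    c = neg.sum(axis=0).to_numpy(dtype=float)
    d = len(neg) - c
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    aa, bb, cc, dd = (np.where(corrected, v + 0.5, v) for v in (a, b, c, d))
    log_or = np.log(aa * dd / (bb * cc))
    return pd.DataFrame(
        {
            "feature": occ.columns,
            "log_odds_ratio": log_or,
            "occupied_positives": a.astype(int),
            "occupied_negatives": c.astype(int),
            "positive_fraction": a / len(pos),
            "zero_cell_corrected": corrected,
        }
    )


def select_predictors(
    fw: pd.DataFrame,
    footprint_flags: pd.Series,
    min_fraction: float = MIN_OCCUPANCY_FRACTION,
) -> pd.DataFrame:
    """Gate features: logOR > 0, occupancy fraction >= min_fraction at
    positives, and a stimulation footprint; sort by logOR descending
    (ties: occupancy fraction, then name)."""
    missing = [f for f in fw["feature"] if f not in footprint_flags.index]
    if missing:
        raise ValueError(f"features lack footprint flags: {missing[:10]}")
    out = fw.copy()
    out["footprint_scf"] = footprint_flags.loc[out["feature"]].astype(bool).to_numpy()
    out["selected"] = (
        (out["log_odds_ratio"] > 0)
        & (out["positive_fraction"] >= min_fraction)
        & out["footprint_scf"]
    )
    out = out.sort_values(
        by=["log_odds_ratio", "positive_fraction", "feature"],
        ascending=[False, False, True],
        ignore_index=True,
    )
    return out
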