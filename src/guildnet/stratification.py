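"""Classifier-probability stratification into clear and grey zones.

A binary classifier (pluggable; L1 feature selection followed by a random
forest by default) produces per-sample case probabilities.  Samples are
then stratified: probabilities in [0.4, 0.6] form the grey zone
regardless of clinical label, while the clear zones additionally require
label concordance (P >= 0.7 with a case label, P <= 0.3 with a control
label).  Probabilities in the gaps, or label-discordant extremes, are
left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .core_data import SampleMetadata

__all__ = [
    "PredictionSet",
    "ZoneAssignment",
    "ClassifierSpec",
    "ZONES",
    "stratified_split",
    "oversample_minority",
    "fit_predict",
    "auc",
    "assign_zones",
    "bin_misclassification",
    "zone_concordance",
    "write_predictions",
    "write_zones",
]

ZONES = ("Clear_GDM", "Clear_NonGDM", "grey", "unassigned")


@dataclass
class PredictionSet:
    """Predicted case probabilities with the true clinical labels."""

    sample_ids: tuple[str, ...]
    probabilities: np.ndarray
    labels: tuple[str, ...]  # "case" / "control"
    model_id: str = "model"

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.labels = tuple(self.labels)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not (
            len(self.sample_ids) == len(self.labels) == self.probabilities.shape[0]
        ):
            raise ValueError("sample_ids, probabilities and labels must align")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        bad = set(self.labels) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")


@dataclass
class ZoneAssignment:
    """Per-sample stratum from probability + clinical label."""

    zones: dict[str, str]
    model_id: str = "model"

    def samples_in(self, zone: str) -> set[str]:
        return {s for s, z in self.zones.items() if z == zone}


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of the stratification classifier pipeline."""

    l1_strength: float = 0.1  # C of the L1 logistic selector
    split_ratio: float = 0.7
    cv_folds: int = 5
    oversample_k: int = 5
    seed: int = 42
    model: str = "random_forest"  # or "gradient_boosting"

    def __post_init__(self) -> None:
        if self.l1_strength <= 0:
            raise ValueError("l1_strength must be positive")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")


# ---------------------------------------------------------------------------
# Splitting and resampling
# ---------------------------------------------------------------------------

def stratified_split(
    metadata: Sequence[SampleMetadata], ratio: float = 0.7, seed: int = 42
) -> tuple[list[str], list[str]]:
    """Label-stratified train/test split of sample ids.

    Per label, round(n * (1 - ratio)) samples go to the test set; the
    split is deterministic for a fixed seed.
    """
    by_label: dict[str, list[str]] = {}
    for rec in metadata:
        by_label.setdefault(rec.condition, []).append(rec.sample_id)
    if set(by_label) != {"case", "control"}:
        raise ValueError("both 'case' and 'control' labels are required")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for label in sorted(by_label):
        ids = by_label[label]
        if len(ids) < 2:
            raise ValueError(f"label {label!r} has fewer than 2 samples")
        n_test = int(round(len(ids) * (1 - ratio)))
        perm = rng.permutation(len(ids))
        test.extend(ids[i] for i in sorted(perm[:n_test]))
        train.extend(ids[i] for i in sorted(perm[n_test:]))
    return train, test


def oversample_minority(
    features: np.ndarray,
    labels: Sequence[str],
    k: int = 5,
    seed: int = 42,
) -> tuple[np.ndarray, list[str]]:
    """SMOTE-style oversampling to an exact 1:1 class balance.

    Each synthetic minority point is x + u * (x_nn - x) with
    u ~ Uniform(0, 1) and x_nn one of the k nearest minority neighbours
    (Euclidean).  Returns the original data with synthetic rows appended.
    """
    features = np.asarray(features, dtype=float)
    labels = list(labels)
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if len(counts) != 2:
        raise ValueError("exactly two classes required")
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    deficit = counts[majority] - counts[minority]
    if deficit == 0:
        return features.copy(), labels
    minority_idx = [i for i, lab in enumerate(labels) if lab == minority]
    x_min = features[minority_idx]
    if len(minority_idx) < k + 1:
        raise ValueError(
            f"minority class has {len(minority_idx)} samples; needs >= {k + 1} "
            f"for k={k} neighbours — use a smaller k"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, nbr = nn.kneighbors(x_min)
    nbr = nbr[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(minority_idx), size=deficit)
    pick = rng.integers(0, k, size=deficit)
    u = rng.uniform(0.0, 1.0, size=deficit)
    synthetic = x_min[base] + u[:, None] * (x_min[nbr[base, pick]] - x_min[base])
    out_x = np.vstack([features, synthetic])
    out_y = labels + [minority] * deficit
    return out_x, out_y


# ---------------------------------------------------------------------------
# Classifier pipeline
# ---------------------------------------------------------------------------

_GRIDS = {
    "random_forest": {
        "n_estimators": [100, 300],
        "max_depth": [3, 10, None],
    },
    "gradient_boosting": {
        "n_estimators": [100, 300],
        "max_depth": [2, 3],
    },
}


def fit_predict(
    spec: ClassifierSpec,
    train_features: np.ndarray,
    train_labels: Sequence[str],
    test_features: np.ndarray,
    test_labels: Sequence[str],
    test_sample_ids: Sequence[str] | None = None,
    oversample: bool = True,
) -> PredictionSet:
    """Standardise, L1-select, oversample, fit and predict probabilities.

    Features are standardised on training statistics; features whose L1
    logistic coefficient is exactly zero are dropped; the downstream
    classifier is tuned by grid search with stratified cross-validation.
    """
    x_tr = np.asarray(train_features, dtype=float)
    x_te = np.asarray(test_features, dtype=float)
    y_tr = list(train_labels)
    y_te = list(test_labels)
    if test_sample_ids is None:
        test_sample_ids = [f"S{i}" for i in range(len(y_te))]

    mu = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    x_tr = (x_tr - mu) / sd
    x_te = (x_te - mu) / sd

    if oversample:
        x_tr, y_tr = oversample_minority(
            x_tr, y_tr, k=spec.oversample_k, seed=spec.seed
        )

    y_bin = np.array([1 if lab == "case" else 0 for lab in y_tr])
    selector = LogisticRegression(
        l1_ratio=1,
        C=spec.l1_strength,
        solver="liblinear",
        random_state=spec.seed,
        max_iter=2000,
    ).fit(x_tr, y_bin)
    keep = np.flatnonzero(np.abs(selector.coef_.ravel()) > 0)
    if keep.size == 0:
        raise ValueError(
            f"no features survive L1 selection at l1_strength={spec.l1_strength}"
        )
    x_tr, x_te = x_tr[:, keep], x_te[:, keep]

    if spec.model == "random_forest":
        base = RandomForestClassifier(random_state=spec.seed)
    elif spec.model == "gradient_boosting":
        base = GradientBoostingClassifier(random_state=spec.seed)
    else:
        raise ValueError(f"unknown model {spec.model!r}")
    cv = StratifiedKFold(
        n_splits=min(spec.cv_folds, int(np.bincount(y_bin).min())),
        shuffle=True,
        random_state=spec.seed,
    )
    search = GridSearchCV(base, _GRIDS[spec.model], cv=cv, scoring="roc_auc", n_jobs=1)
    search.fit(x_tr, y_bin)
    probs = search.predict_proba(x_te)[:, list(search.classes_).index(1)]
    return PredictionSet(
        sample_ids=tuple(map(str, test_sample_ids)),
        probabilities=probs,
        labels=tuple(y_te),
        model_id=spec.model,
    )


def auc(preds: PredictionSet) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties."""
    y = np.array([1 if lab == "case" else 0 for lab in preds.labels])
    if y.min() == y.max():
        raise ValueError("AUC requires both labels")
    ranks = stats.rankdata(preds.probabilities)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Zones
# ---------------------------------------------------------------------------

def assign_zones(
    preds: PredictionSet, strict_boundaries: bool = False
) -> ZoneAssignment:
    """Stratify samples by predicted probability and clinical label.

    grey iff 0.4 <= P <= 0.6 (label-agnostic); Clear_GDM iff P >= 0.7 and
    label case; Clear_NonGDM iff P <= 0.3 and label control; everything
    else (gap probabilities and label-discordant extremes) is unassigned.
    ``strict_boundaries`` switches the clear-zone comparisons to strict
    inequalities.
    """
    zones: dict[str, str] = {}
    for sid, p, lab in zip(preds.sample_ids, preds.probabilities, preds.labels):
        if 0.4 <= p <= 0.6:
            zones[sid] = "grey"
        elif (p > 0.7 if strict_boundaries else p >= 0.7) and lab == "case":
            zones[sid] = "Clear_GDM"
        elif (p < 0.3 if strict_boundaries else p <= 0.3) and lab == "control":
            zones[sid] = "Clear_NonGDM"
        else:
            zones[sid] = "unassigned"
    return ZoneAssignment(zones=zones, model_id=preds.model_id)


def bin_misclassification(
    preds: PredictionSet, bin_edges: Sequence[float] | None = None
) -> dict[tuple[float, float], tuple[int, float | None]]:
    """Per-probability-bin misclassification of the P >= 0.5 call.

    Bins are [e_k, e_{k+1}) except the last, which is closed.  Returns
    bin -> (n, error rate), with rate None for empty bins.
    """
    if bin_edges is None:
        bin_edges = np.round(np.arange(0.0, 1.01, 0.1), 10).tolist()
    edges = list(map(float, bin_edges))
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 0.0 or edges[-1] != 1.0:
        raise ValueError("bins must partition [0, 1]")
    out: dict[tuple[float, float], tuple[int, float | None]] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        mask = [
            (lo <= p < hi) or (last and p == hi) for p in preds.probabilities
        ]
        n = int(sum(mask))
        if n == 0:
            out[(lo, hi)] = (0, None)
            continue
        wrong = 0
        for p, lab, m in zip(preds.probabilities, preds.labels, mask):
            if not m:
                continue
            call = "case" if p >= 0.5 else "control"
            wrong += call != lab
        out[(lo, hi)] = (n, wrong / n)
    return out


def zone_concordance(
    zA: ZoneAssignment, zB: ZoneAssignment
) -> tuple[int, float]:
    """Grey-zone overlap between two models: (intersection size, Jaccard)."""
    if set(zA.zones) != set(zB.zones):
        raise ValueError("zone assignments cover different sample universes")
    ga, gb = zA.samples_in("grey"), zB.samples_in("grey")
    union = ga | gb
    inter = ga & gb
    return len(inter), (len(inter) / len(union) if union else 0.0)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tprobability\tlabel\tmodel_id\n")
        for sid, p, lab in zip(preds.sample_ids, preds.probabilities, preds.labels):
            fh.write(f"{sid}\t{p:.10g}\t{lab}\t{preds.model_id}\n")


def write_zones(assignment: ZoneAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tzone\tmodel_id\n")
        for sid in sorted(assignment.zones):
            fh.write(f"{sid}\t{assignment.zones[sid]}\t{assignment.model_id}\n")
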