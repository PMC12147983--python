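"""Fast gentle boosting of regression stumps with per-class vote vectors.

This is the classifier family used by CellProfiler-Analyst-style phenotype
scoring: each boosting round fits one decision stump (feature, threshold) by
weighted least squares against the ±1 one-vs-rest class indicators, every
class receiving its own vote pair (a for x > t, b for x <= t).  Scoring sums
the votes over rounds and predicts the arg-max class.

Training is fully deterministic given the training-set ordering: all features
and all candidate thresholds (midpoints between consecutive sorted unique
values) are searched exhaustively each round, ties broken by (lower feature
index, lower threshold).  The weighted exponential loss is tracked every round
and is non-increasing (asserted in the test suite).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

#: Classes ordered along the developmental continuum (earliest first); score
#: ties resolve to the earlier stage, which is conservative for yield.
DEFAULT_CLASS_ORDER: tuple[str, ...] = (
    "EBLike",
    "AmorphousXEn",
    "XEnNonPolarizedEpi",
    "XEnEpiRosette",
    "XEnEpiC",
)


@dataclass
class TrainingSet:
    """Feature matrix + labels, with non-finite values median-imputed."""

    X: np.ndarray  # (n, F) float64, finite
    labels: np.ndarray  # (n,) str
    feature_names: list[str]
    class_order: tuple[str, ...]
    medians: np.ndarray  # (F,) training medians used for imputation
    provenance: pd.DataFrame | None = None

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        class_order: tuple[str, ...] | None = None,
        provenance_cols: tuple[str, ...] = (),
    ) -> "TrainingSet":
        labels = df[label_col].to_numpy(dtype=str)
        present = set(labels)
        if len(present) < 2:
            raise ValueError("training set must contain at least 2 classes")
        if class_order is None:
            order = tuple(c for c in DEFAULT_CLASS_ORDER if c in present)
            order += tuple(sorted(present - set(order)))
        else:
            order = tuple(class_order)
            missing = present - set(order)
            if missing:
                raise ValueError(f"labels not in class_order: {sorted(missing)}")
        feat_cols = [c for c in df.columns
                     if c != label_col and c not in provenance_cols
                     and pd.api.types.is_numeric_dtype(df[c])]
        X = df[feat_cols].to_numpy(dtype=np.float64)
        medians = np.nanmedian(np.where(np.isfinite(X), X, np.nan), axis=0)
        medians = np.where(np.isfinite(medians), medians, 0.0)
        X = np.where(np.isfinite(X), X, medians)
        prov = df[list(provenance_cols)].copy() if provenance_cols else None
        return cls(X=X, labels=labels, feature_names=feat_cols,
                   class_order=order, medians=medians, provenance=prov)

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in self.class_order}


@dataclass
class Stump:
    feature_name: str
    threshold: float
    vote_if_greater: np.ndarray  # (K,)
    vote_if_not: np.ndarray  # (K,)


@dataclass
class BoostModel:
    """Ordered stump list; class order and imputation medians are embedded."""

    rounds: list[Stump]
    class_order: tuple[str, ...]
    feature_names: list[str]
    medians: dict[str, float] = field(default_factory=dict)
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def train_gentle_boost(ts: TrainingSet, n_rounds: int = 50) -> BoostModel:
    """Train a multi-class gentle-boosting stump ensemble.

    Per round, for every feature f and candidate threshold t, the stump
    responses are the weighted class-indicator means of the two sides,
    a_k = Σ_{x>t} w·y / Σ_{x>t} w (b_k analogous for x<=t); the (f, t)
    minimizing the total weighted squared error Σ w (y - h)² is appended and
    the weights updated multiplicatively, w <- w·exp(-y·h), then renormalized.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X, labels = ts.X, ts.labels
    n, F = X.shape
    K = len(ts.class_order)
    if n < 2:
        raise ValueError("need at least 2 training objects")
    y = np.where(labels[:, None] == np.array(ts.class_order)[None, :], 1.0, -1.0)
    w = np.full((n, K), 1.0 / (n * K))

    orders = [np.argsort(X[:, f], kind="stable") for f in range(F)]
    splittable = [np.any(np.diff(X[orders[f], f]) > 0) for f in range(F)]
    if not any(splittable):
        raise ValueError("no informative split: all features are constant")

    rounds: list[Stump] = []
    loss_history: list[float] = []
    log_loss_scale = np.log(w.sum())  # running log of un-normalized loss / (nK)

    for _ in range(n_rounds):
        best = None  # (gain, f, threshold, a, b)
        for f in range(F):
            if not splittable[f]:
                continue
            o = orders[f]
            xs = X[o, f]
            ws = w[o]
            wy = ws * y[o]
            cw = np.cumsum(ws, axis=0)  # prefix sums (x <= t side)
            cwy = np.cumsum(wy, axis=0)
            tot_w = cw[-1]
            tot_wy = cwy[-1]
            cut = np.flatnonzero(np.diff(xs) > 0)  # split after sorted index i
            if cut.size == 0:
                continue
            w_le = cw[cut]
            wy_le = cwy[cut]
            w_gt = tot_w[None, :] - w_le
            wy_gt = tot_wy[None, :] - wy_le
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(w_gt > 0, wy_gt / np.maximum(w_gt, 1e-300), 0.0)
                b = np.where(w_le > 0, wy_le / np.maximum(w_le, 1e-300), 0.0)
            gains = (a * wy_gt + b * wy_le).sum(axis=1)  # SSE reduction per split
            j = int(np.argmax(gains))  # first max -> lowest threshold
            gain = float(gains[j])
            if best is None or gain > best[0] + 1e-15:
                thr = 0.5 * (xs[cut[j]] + xs[cut[j] + 1])
                best = (gain, f, float(thr), a[j].copy(), b[j].copy())
        assert best is not None
        _, f, thr, a, b = best
        h = np.where(X[:, f][:, None] > thr, a[None, :], b[None, :])
        w = w * np.exp(-y * h)
        s = w.sum()
        log_loss_scale += np.log(s)
        w /= s
        rounds.append(Stump(ts.feature_names[f], thr, a, b))
        loss_history.append(float(np.exp(log_loss_scale)))

    return BoostModel(
        rounds=rounds,
        class_order=ts.class_order,
        feature_names=list(ts.feature_names),
        medians=dict(zip(ts.feature_names, ts.medians.tolist())),
        loss_history=loss_history,
    )


def _feature_matrix(model: BoostModel, features) -> np.ndarray:
    """Extract (n, n_used) matrix of the model's stump features, imputing
    non-finite values with the training medians."""
    used = sorted({s.feature_name for s in model.rounds})
    if isinstance(features, pd.DataFrame):
        for name in used:
            if name not in features.columns:
                raise KeyError(f"missing feature: {name!r}")
        M = features[used].to_numpy(dtype=np.float64)
    else:
        X = np.asarray(features, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.feature_names):
            raise KeyError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}")
        cols = {n: i for i, n in enumerate(model.feature_names)}
        M = X[:, [cols[n] for n in used]]
    med = np.array([model.medians.get(n, 0.0) for n in used])
    M = np.where(np.isfinite(M), M, med[None, :])
    return M, {n: i for i, n in enumerate(used)}  # type: ignore[return-value]


def score(model: BoostModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Per-class vote totals and predicted classes.

    ``features`` is a DataFrame (columns by name) or an array in the model's
    training feature order.  Ties resolve to the earliest class in
    ``class_order``.  An empty model scores 0 everywhere and predicts the
    first class.
    """
    K = len(model.class_order)
    if not model.rounds:
        n = len(features) if hasattr(features, "__len__") else 1
        scores = np.zeros((n, K))
        preds = np.array([model.class_order[0]] * n)
        return scores, preds
    M, col = _feature_matrix(model, features)
    scores = np.zeros((M.shape[0], K))
    for s in model.rounds:
        x = M[:, col[s.feature_name]]
        scores += np.where(x[:, None] > s.threshold,
                           s.vote_if_greater[None, :], s.vote_if_not[None, :])
    preds = np.array([model.class_order[i] for i in np.argmax(scores, axis=1)])
    return scores, preds


@dataclass
class EvalReport:
    confusion: pd.DataFrame  # rows = truth, cols = predicted
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        })


def evaluate(model: BoostModel, features, labels) -> EvalReport:
    """Confusion matrix, accuracy and one-vs-rest precision/recall/F1."""
    _, preds = score(model, features)
    labels = np.asarray(labels, dtype=str)
    order = list(model.class_order)
    cm = _sk_confusion(labels, preds, labels=order)
    conf = pd.DataFrame(cm, index=order, columns=order)
    accuracy = float(np.trace(cm) / max(cm.sum(), 1))
    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(order):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else float("nan")
        r = tp / (tp + fn) if tp + fn > 0 else float("nan")
        precision[c] = float(p)
        recall[c] = float(r)
        f1[c] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    return EvalReport(conf, accuracy, precision, recall, f1)


# ------------------------------------------------------------- rules text IO

_RULE_RE = re.compile(
    r"^IF \((?P<feat>.+?) > (?P<thr>[-+0-9.eE]+), "
    r"\[(?P<a>[^\]]*)\], \[(?P<b>[^\]]*)\]\)$"
)


def export_rules(model: BoostModel) -> str:
    """Human-readable rules text; round-trips through :func:`import_rules`."""
    lines = ["# morphoscreen gentle-boosting rules v1"]
    lines.append("classes: " + ",".join(model.class_order))
    lines.append("features: " + ",".join(model.feature_names))
    for name, med in model.medians.items():
        lines.append(f"median: {name} {med!r}")
    for s in model.rounds:
        a = " ".join(repr(float(v)) for v in s.vote_if_greater)
        b = " ".join(repr(float(v)) for v in s.vote_if_not)
        lines.append(f"IF ({s.feature_name} > {s.threshold!r}, [{a}], [{b}])")
    return "\n".join(lines) + "\n"


def import_rules(text: str) -> BoostModel:
    """Parse rules text; raises ValueError naming the offending line."""
    class_order: tuple[str, ...] | None = None
    feature_names: list[str] = []
    medians: dict[str, float] = {}
    rounds: list[Stump] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("classes:"):
            class_order = tuple(c.strip() for c in line[len("classes:"):].split(",")
                                if c.strip())
            continue
        if line.startswith("features:"):
            feature_names = [c.strip() for c in line[len("features:"):].split(",")
                             if c.strip()]
            continue
        if line.startswith("median:"):
            try:
                _, name, val = line.split(None, 2)
                medians[name] = float(val)
            except ValueError as e:
                raise ValueError(f"line {ln}: malformed median line") from e
            continue
        m = _RULE_RE.match(line)
        if not m:
            raise ValueError(f"line {ln}: malformed rule: {line!r}")
        if class_order is None:
            raise ValueError(f"line {ln}: rule before 'classes:' header")
        try:
            a = np.array([float(v) for v in m.group("a").split()])
            b = np.array([float(v) for v in m.group("b").split()])
            thr = float(m.group("thr"))
        except ValueError as e:
            raise ValueError(f"line {ln}: malformed number in rule") from e
        if a.size != len(class_order) or b.size != len(class_order):
            raise ValueError(
                f"line {ln}: vote vector length {a.size}/{b.size} does not "
                f"match {len(class_order)} classes")
        rounds.append(Stump(m.group("feat"), thr, a, b))
    if class_order is None:
        raise ValueError("no 'classes:' header found")
    if not feature_names:
        feature_names = sorted({s.feature_name for s in rounds})
    return BoostModel(rounds=rounds, class_order=class_order,
                      feature_names=feature_names, medians=medians)
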