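"""Complete-information common spatial patterns (CICSP) for left/right
motor-imagery decoding.

Plain CSP finds spatial filters that maximize the variance of one class
while minimizing the other's, by simultaneous diagonalization of the two
class covariance matrices; only the first m and last m filters are
normally kept.  CICSP additionally projects trials through the
intermediate filters and compresses their log-variance features to k
dimensions by PCA, so the discriminative information usually discarded
with the middle eigenvectors still reaches the classifier.  The combined
feature vector ``F = [f1, f2']`` (length 2m + k) feeds a linear
support-vector machine.

Online, a 1.5 s window is decoded by computing f1 from the full window
and f2' from three 0.5 s sub-windows whose PCA-reduced intermediate
features are averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from . import preprocess
from .types import EEGRecording, EpochWindow, LabeledTrialSet, MI_CHANNELS

__all__ = [
    "SpatialFilterBank", "CICSPModel", "FeatureVector",
    "preprocess_mi", "class_covariances", "solve_csp", "logvar_features",
    "fit_cicsp", "predict_mi", "predict_mi_online",
    "save_model", "load_model",
]

_COV_RIDGE = 1e-9
_LOGVAR_EPS = 1e-12
_MODEL_VERSION = 1

#: Number of 0.5 s sub-windows the online procedure cuts a 1.5 s window into.
_N_SUBWINDOWS = 3


@dataclass
class SpatialFilterBank:
    """CSP filters, one per row, sorted by eigenvalue descending.

    ``eigvals[i]`` is the share of class-1 variance captured by filter i
    relative to the pooled variance; the pooled projected covariance is
    the identity, so the two class diagonals sum to 1 per filter.
    """

    W: np.ndarray        # C x C, rows are filters
    eigvals: np.ndarray  # length C, in (0, 1)

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]


@dataclass
class FeatureVector:
    """One trial's CICSP features: edge-filter log-variances (f1) and the
    PCA-reduced intermediate log-variances (f2')."""

    f1: np.ndarray
    f2prime: np.ndarray

    @property
    def F(self) -> np.ndarray:
        return np.concatenate([self.f1, self.f2prime])


@dataclass
class CICSPModel:
    """Trained CICSP decoder.

    ``Q1`` holds the m first and m last spatial filters (edge filters);
    ``Q2`` the intermediate ones.  The PCA loading maps intermediate
    log-variance vectors to k dimensions; a linear decision rule
    ``sign(w . F + b)`` separates the two classes (positive margin maps
    to ``classes[1]``).
    """

    W: np.ndarray
    eigvals: np.ndarray
    m: int
    k: int
    channels: tuple[str, ...]
    band: tuple[float, float]
    classes: tuple[str, str]
    pca_mean: np.ndarray | None
    pca_components: np.ndarray | None  # k x (C - 2m)
    clf_w: np.ndarray
    clf_b: float
    training_accuracy: float

    @property
    def Q1(self) -> np.ndarray:
        return np.vstack([self.W[: self.m], self.W[-self.m:]])

    @property
    def Q2(self) -> np.ndarray:
        return self.W[self.m: self.W.shape[0] - self.m]

    @property
    def n_features(self) -> int:
        return 2 * self.m + self.k

    def decide(self, F: np.ndarray) -> str:
        return self.classes[1] if float(self.clf_w @ F + self.clf_b) > 0 \
            else self.classes[0]


def preprocess_mi(rec: EEGRecording,
                  channels: tuple[str, ...] = MI_CHANNELS) -> EEGRecording:
    """The motor-imagery conditioning chain: 9-12 Hz band-pass, common
    average reference over the 10 sensorimotor electrodes, then restriction
    to those electrodes."""
    rec = preprocess.bandpass(rec, *preprocess.MI_BAND)
    rec = preprocess.car(rec, channels)
    return rec.pick(channels)


def _trial_cov(X: np.ndarray) -> np.ndarray:
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("zero-power trial")
    return C / tr


def class_covariances(
    trials: LabeledTrialSet, classes: tuple[str, str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Trace-normalized spatial covariances averaged within each class.

    Expects trials already band-passed and CAR-filtered.  Each trial
    contributes ``X X^T / tr(X X^T)``, so amplitude differences between
    trials do not bias the average.
    """
    if classes is None:
        classes = trials.classes
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
    out = []
    for cls in classes:
        recs = trials.by_label(cls)
        if not recs:
            raise ValueError(f"no trials for class {cls!r}")
        out.append(np.mean([_trial_cov(r.data) for r in recs], axis=0))
    return out[0], out[1]


def solve_csp(C1: np.ndarray, C2: np.ndarray) -> SpatialFilterBank:
    """Simultaneously diagonalize two class covariances.

    Solves the generalized eigenproblem ``C1 w = lambda (C1 + C2) w``
    (ridge-stabilized), returning filters sorted by eigenvalue
    descending with ``W (C1 + C2) W^T = I``.  The first filters maximize
    class-1 variance relative to the pooled variance, the last minimize it.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    comp = C1 + C2
    comp = comp + _COV_RIDGE * np.trace(comp) * np.eye(comp.shape[0])
    try:
        vals, vecs = linalg.eigh(C1, comp)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError("composite covariance not positive definite") from exc
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    W = vecs[:, order].T
    # filter signs are arbitrary; fix the largest-magnitude coefficient positive
    for i in range(W.shape[0]):
        j = np.argmax(np.abs(W[i]))
        if W[i, j] < 0:
            W[i] = -W[i]
    return SpatialFilterBank(W=W, eigvals=np.clip(vals, 0.0, 1.0))


def logvar_features(Z: np.ndarray) -> np.ndarray:
    """Normalized log-variance per filter row.

    ``lambda_i = log((Z Z^T)_ii / tr(Z Z^T))``, hence
    ``sum_i exp(lambda_i) = 1``.  Zero-power rows are clamped at
    ``log(1e-12)``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    power = np.einsum("ij,ij->i", Z, Z)
    total = power.sum()
    if total <= 0:
        raise ValueError("all-zero projection")
    ratio = np.clip(power / total, _LOGVAR_EPS, None)
    return np.log(ratio)


def _features_batch(model_W: np.ndarray, m: int, X: np.ndarray,
                    pca_mean, pca_components) -> FeatureVector:
    Q1 = np.vstack([model_W[:m], model_W[-m:]])
    Q2 = model_W[m: model_W.shape[0] - m]
    f1 = logvar_features(Q1 @ X)
    lam2 = logvar_features(Q2 @ X)
    if pca_components is None:
        return FeatureVector(f1=f1, f2prime=np.empty(0))
    f2p = pca_components @ (lam2 - pca_mean)
    return FeatureVector(f1=f1, f2prime=f2p)


def fit_cicsp(
    trials: LabeledTrialSet,
    m: int = 2,
    k: int = 1,
    C_reg: float = 1.0,
    preprocessed: bool = False,
    channels: tuple[str, ...] = MI_CHANNELS,
) -> CICSPModel:
    """Train the CICSP decoder on labeled calibration trials.

    With ``k = 0`` the intermediate path is dropped and the model reduces
    to plain CSP with 2m log-variance features.  ``C_reg`` is the SVM
    regularization parameter.
    """
    if not preprocessed:
        trials = trials.map(lambda r: preprocess_mi(r, channels))
    classes = trials.classes
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    classes = tuple(sorted(classes))  # match sklearn's class ordering
    C = trials.trials[0][0].n_channels
    if C - 2 * m < k:
        raise ValueError(
            f"m={m} leaves {C - 2 * m} intermediate filters, need >= k={k}"
        )
    C1, C2 = class_covariances(trials, classes)
    bank = solve_csp(C1, C2)

    lam2 = np.array([
        logvar_features(bank.W[m: C - m] @ rec.data) for rec, _ in trials
    ])
    if k > 0:
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(lam2)
        pca_mean, pca_components = pca.mean_, pca.components_
    else:
        pca_mean = pca_components = None

    feats = np.array([
        _features_batch(bank.W, m, rec.data, pca_mean, pca_components).F
        for rec, _ in trials
    ])
    y = np.array([lab for _, lab in trials])
    svm = SVC(kernel="linear", C=C_reg)
    svm.fit(feats, y)
    acc = float((svm.predict(feats) == y).mean())
    return CICSPModel(
        W=bank.W, eigvals=bank.eigvals, m=m, k=k,
        channels=tuple(channels), band=preprocess.MI_BAND,
        classes=tuple(svm.classes_),
        pca_mean=pca_mean, pca_components=pca_components,
        clf_w=svm.coef_.ravel().copy(), clf_b=float(svm.intercept_[0]),
        training_accuracy=acc,
    )


def predict_mi(
    window: EEGRecording, model: CICSPModel, preprocessed: bool = False
) -> str:
    """Batch-mode prediction: both f1 and f2' from the full window."""
    if not preprocessed:
        window = preprocess_mi(window, model.channels)
    fv = _features_batch(model.W, model.m, window.data,
                         model.pca_mean, model.pca_components)
    return model.decide(fv.F)


def predict_mi_online(
    window: EpochWindow, model: CICSPModel, preprocessed: bool = False
) -> str:
    """Online prediction for one 1.5 s window.

    f1 comes from the full window through the edge filters; the window is
    then cut into three 0.5 s sub-windows, each projected through the
    intermediate filters, and the three PCA-reduced feature vectors are
    averaged into f2'.
    """
    n_expected = int(round(preprocess.WINDOW_S * window.fs))
    if window.n_samples != n_expected:
        raise ValueError(
            f"online windows must be {preprocess.WINDOW_S} s "
            f"({n_expected} samples), got {window.n_samples}"
        )
    if not preprocessed:
        window = preprocess_mi(window, model.channels)
    X = window.data
    Q1 = model.Q1
    Q2 = model.Q2
    f1 = logvar_features(Q1 @ X)
    if model.k > 0:
        sub = np.array_split(np.arange(X.shape[1]), _N_SUBWINDOWS)
        f2ps = []
        for idx in sub:
            lam2k = logvar_features(Q2 @ X[:, idx])
            f2ps.append(model.pca_components @ (lam2k - model.pca_mean))
        f2p = np.mean(f2ps, axis=0)
    else:
        f2p = np.empty(0)
    return model.decide(np.concatenate([f1, f2p]))


# ---------------------------------------------------------------------------
# Serialization: one self-describing .npz with matrices and a metadata record


def save_model(model: CICSPModel, path) -> None:
    meta = {
        "version": _MODEL_VERSION,
        "m": model.m, "k": model.k,
        "channels": list(model.channels),
        "band": list(model.band),
        "classes": list(model.classes),
        "clf_b": model.clf_b,
        "training_accuracy": model.training_accuracy,
    }
    arrays = {
        "W": model.W, "eigvals": model.eigvals, "clf_w": model.clf_w,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if model.k > 0:
        arrays["pca_mean"] = model.pca_mean
        arrays["pca_components"] = model.pca_components
    np.savez(path, **arrays)


def load_model(path) -> CICSPModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta["version"] != _MODEL_VERSION:
            raise ValueError(f"unsupported model version {meta['version']}")
        k = meta["k"]
        return CICSPModel(
            W=z["W"], eigvals=z["eigvals"], m=meta["m"], k=k,
            channels=tuple(meta["channels"]),
            band=tuple(meta["band"]),
            classes=tuple(meta["classes"]),
            pca_mean=z["pca_mean"] if k > 0 else None,
            pca_components=z["pca_components"] if k > 0 else None,
            clf_w=z["clf_w"], clf_b=meta["clf_b"],
            training_accuracy=meta["training_accuracy"],
        )
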