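"""Profile embeddings and class discrimination: PCA, delegated UMAP, OPLS-DA.

OPLS-DA follows the orthogonal signal correction scheme: components of
X-variation orthogonal to the class vector are removed iteratively, then a
single-component PLS1 model is fitted on the filtered matrix.  Discrimination
is summarised by stratified cross-validated accuracy and Q2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from crossfluid.errors import InsufficientDataError, ParameterError


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray
    method: str
    seed: int | None = None
    explained_variance: np.ndarray | None = None


def pca_embed(matrix: np.ndarray, n_components: int = 2) -> EmbeddingResult:
    """PCA scores via SVD of the column-centered matrix.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so scores are reproducible across runs.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise InsufficientDataError("PCA needs >= 3 samples and >= 2 features")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if rank < n_components:
        raise ParameterError(f"matrix rank {rank} < requested {n_components} components")
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :n_components] * s[:n_components]
    total = float((s**2).sum())
    ev = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return EmbeddingResult(scores, "pca", explained_variance=ev)


def umap_embed(matrix: np.ndarray, seed: int = 0, **kwargs) -> EmbeddingResult:
    """2-D nonlinear embedding delegated to umap-learn.

    Contract: output shape (n_samples, 2), finite, deterministic for a fixed
    seed.  Raises a clear error when the backend is unavailable.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 10:
        raise InsufficientDataError("UMAP embedding requires >= 10 samples")
    try:
        import umap
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "umap-learn is not installed; install the 'umap' extra or use pca_embed"
        ) from exc
    reducer = umap.UMAP(n_components=2, random_state=seed, **kwargs)
    coords = np.asarray(reducer.fit_transform(X), dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("UMAP produced non-finite coordinates")
    return EmbeddingResult(coords, "umap", seed=seed)


@dataclass
class OplsModel:
    """Single-predictive-component OPLS-DA model."""

    weights: np.ndarray                     # predictive weight vector
    loadings: np.ndarray                    # predictive loading vector
    q: float                                # y-loading of the predictive component
    orth_weights: np.ndarray                # (n_orth, p)
    orth_loadings: np.ndarray               # (n_orth, p)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    scores: np.ndarray                      # training predictive scores
    orth_scores: np.ndarray                 # (n, n_orth)
    cv_accuracy: float = np.nan
    q2: float = np.nan
    classes: tuple = ()

    def _filter(self, X: np.ndarray) -> np.ndarray:
        Xf = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        for w_o, p_o in zip(self.orth_weights, self.orth_loadings):
            t_o = Xf @ w_o
            Xf = Xf - np.outer(t_o, p_o)
        return Xf

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._filter(X) @ self.weights * self.q + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, self.classes[1], self.classes[0])


def _fit_opls_core(X: np.ndarray, y: np.ndarray, n_orth: int):
    """OSC filtering + PLS1 on centered/scaled data. Returns model pieces."""
    w_orth_list, p_orth_list, t_orth_list = [], [], []
    Xf = X.copy()
    yss = float(y @ y)
    for _ in range(n_orth):
        w = Xf.T @ y / yss
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = Xf @ w
        p = Xf.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o = w_o / n_o
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / float(t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        w_orth_list.append(w_o)
        p_orth_list.append(p_o)
        t_orth_list.append(t_o)

    w = Xf.T @ y / yss
    w = w / np.linalg.norm(w)
    t = Xf @ w
    p = Xf.T @ t / float(t @ t)
    q = float(y @ t / (t @ t))
    return w, p, q, w_orth_list, p_orth_list, t_orth_list, t


def opls_da_fit(
    matrix: np.ndarray,
    labels,
    n_orth: int = 1,
    cv_folds: int = 7,
    scale: bool = True,
    seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA for a binary class vector and cross-validate it.

    Labels are encoded as -1/+1 by sorted class order.  CV folds are
    stratified; accuracy is the fraction of held-out samples whose decision
    value falls on the correct side, Q2 = 1 - PRESS/TSS on the encoded y.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ParameterError(f"need exactly 2 classes, got {classes}")
    if n_orth < 0:
        raise ParameterError("n_orth must be >= 0")
    y_enc = np.where(labels == classes[1], 1.0, -1.0)

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xs = (X - x_mean) / x_scale
    y_mean = float(y_enc.mean())
    yc = y_enc - y_mean

    w, p, q, w_o, p_o, t_o, t = _fit_opls_core(Xs, yc, n_orth)
    model = OplsModel(
        weights=w,
        loadings=p,
        q=q,
        orth_weights=np.array(w_o) if w_o else np.empty((0, X.shape[1])),
        orth_loadings=np.array(p_o) if p_o else np.empty((0, X.shape[1])),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        scores=t,
        orth_scores=np.column_stack(t_o) if t_o else np.empty((X.shape[0], 0)),
        classes=classes,
    )

    # stratified cross-validation
    from sklearn.model_selection import StratifiedKFold

    n_folds = min(cv_folds, int(np.bincount((y_enc > 0).astype(int)).min()))
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        press = 0.0
        tss = float(((y_enc - y_enc.mean()) ** 2).sum())
        n_correct = 0
        for train, test in skf.split(X, labels):
            sub = _opls_no_cv(X[train], labels[train], n_orth=n_orth, scale=scale)
            pred = sub.decision_function(X[test])
            press += float(((y_enc[test] - pred) ** 2).sum())
            n_correct += int((np.sign(pred) == np.sign(y_enc[test])).sum())
        model.cv_accuracy = n_correct / X.shape[0]
        model.q2 = 1.0 - press / tss
    return model


# fold-level refits share the fitting core but skip cross-validation
def _opls_no_cv(matrix, labels, n_orth=1, scale=True):
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    y_enc = np.where(labels == classes[1], 1.0, -1.0)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xs = (X - x_mean) / x_scale
    y_mean = float(y_enc.mean())
    yc = y_enc - y_mean
    w, p, q, w_o, p_o, t_o, t = _fit_opls_core(Xs, yc, n_orth)
    return OplsModel(
        weights=w,
        loadings=p,
        q=q,
        orth_weights=np.array(w_o) if w_o else np.empty((0, X.shape[1])),
        orth_loadings=np.array(p_o) if p_o else np.empty((0, X.shape[1])),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        scores=t,
        orth_scores=np.column_stack(t_o) if t_o else np.empty((X.shape[0], 0)),
        classes=classes,
    )
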