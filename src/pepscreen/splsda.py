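"""Sparse partial least squares discriminant analysis (sPLS-DA).

PLS-DA regresses a one-hot class-indicator matrix Y on the abundance
matrix X through a small number of latent components, which makes it
usable when variables (peptides) vastly outnumber samples.  The sparse
variant constrains each component's X-loading vector to at most ``keep_x``
nonzero entries by soft-thresholding inside the NIPALS inner loop, so a
fitted component names the small peptide set that drives the group
separation.

Conventions used here:

* X columns are mean-centered and scaled to unit variance (zero-variance
  columns are kept with scale 1 and naturally receive zero loadings);
  Y columns are mean-centered.
* Per component, the X-loading is the dominant left singular direction of
  X_h' Y_h, soft-thresholded to ``keep_x`` nonzeros and renormalized,
  iterated with the Y-direction to convergence; scores are t_h = X_h a_h;
  X and Y are deflated by regression on t_h (regression-mode deflation),
  which makes score vectors mutually orthogonal.
* Sign indeterminacy is fixed by making the largest-magnitude entry of
  each loading column positive, so loadings are comparable across
  cross-validation refits.
* Classification of new samples is by the nearest class centroid in latent
  score space (Euclidean distance; ties go to the first class in training
  label order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SplsdaModel", "soft_threshold", "fit", "predict", "transform"]

_TOL = 1e-9
_MAX_ITER = 500


class DegenerateInputError(ValueError):
    pass


def soft_threshold(v: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(v) * max(|v| - delta, 0) for delta >= 0."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - delta, 0.0)


def _sparsify(a: np.ndarray, keep_x: int) -> np.ndarray:
    """Soft-threshold ``a`` so at most ``keep_x`` entries stay nonzero.

    delta is the (keep_x+1)-th largest magnitude, the smallest threshold
    achieving the sparsity level (zero when keep_x >= len(a)).
    """
    if keep_x >= len(a):
        return a.copy()
    mags = np.sort(np.abs(a))[::-1]
    delta = mags[keep_x]
    return soft_threshold(a, delta)


@dataclass
class SplsdaModel:
    """A fitted sparse PLS-DA model."""

    classes: list[str]
    ncomp: int
    keep_x: int
    x_loadings: np.ndarray  # (p, ncomp) sparse weight vectors, unit norm
    x_proj: np.ndarray  # (p, ncomp) regression loadings used for deflation
    y_loadings: np.ndarray  # (n_classes, ncomp)
    x_scores: np.ndarray  # (n, ncomp) training latent scores
    centroids: np.ndarray  # (n_classes, ncomp) class centroids in score space
    x_center: np.ndarray  # (p,)
    x_scale: np.ndarray  # (p,)
    feature_ids: list = field(default_factory=list)

    def n_selected(self) -> int:
        """Number of distinct variables with a nonzero loading on any component."""
        return int((np.abs(self.x_loadings).max(axis=1) > 0).sum())

    def selected_per_component(self) -> list[int]:
        return [int((self.x_loadings[:, h] != 0).sum()) for h in range(self.ncomp)]

    # --- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "classes": self.classes,
            "ncomp": self.ncomp,
            "keep_x": self.keep_x,
            "x_loadings": self.x_loadings.tolist(),
            "x_proj": self.x_proj.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "centroids": self.centroids.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "feature_ids": list(self.feature_ids),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SplsdaModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        doc = json.loads(text)
        return cls(
            classes=doc["classes"],
            ncomp=doc["ncomp"],
            keep_x=doc["keep_x"],
            x_loadings=np.array(doc["x_loadings"]),
            x_proj=np.array(doc["x_proj"]),
            y_loadings=np.array(doc["y_loadings"]),
            x_scores=np.array(doc["x_scores"]),
            centroids=np.array(doc["centroids"]),
            x_center=np.array(doc["x_center"]),
            x_scale=np.array(doc["x_scale"]),
            feature_ids=doc["feature_ids"],
        )


def _one_hot(y: np.ndarray, classes: list[str]) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    index = {c: j for j, c in enumerate(classes)}
    for i, label in enumerate(y):
        Y[i, index[label]] = 1.0
    return Y


def fit(
    X: np.ndarray,
    y,
    ncomp: int,
    keep_x: int,
    feature_ids=None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> SplsdaModel:
    """Fit a sparse PLS-DA model.

    Parameters
    ----------
    X : (n_samples, n_peptides) abundance matrix.
    y : per-sample class labels (any hashable); class order follows first
        appearance sorted lexicographically for determinism.
    ncomp : number of latent components; must be <= n_classes - 1, since n
        groups are separable by n-1 latent variables.
    keep_x : maximum nonzero loadings per component.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    classes = sorted(set(y.tolist()))
    n, p = X.shape
    if len(classes) < 2:
        raise DegenerateInputError("need at least two classes")
    if not 1 <= ncomp <= len(classes) - 1:
        raise ValueError(f"ncomp={ncomp} outside [1, n_classes-1={len(classes)-1}]")
    if not 1 <= keep_x:
        raise ValueError("keep_x must be >= 1")
    if n <= ncomp:
        raise ValueError("need more samples than components")
    keep_x = min(keep_x, p)

    x_center = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    Xh = (X - x_center) / x_scale
    Y = _one_hot(y, classes)
    Yh = Y - Y.mean(axis=0)

    A = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    D = np.zeros((len(classes), ncomp))
    T = np.zeros((n, ncomp))

    for h in range(ncomp):
        M = Xh.T @ Yh  # p x K cross-covariance
        # init u from the Y column best covarying with X
        j0 = int(np.argmax(np.linalg.norm(M, axis=0)))
        u = Yh[:, j0]
        if np.allclose(u, 0):
            u = Yh[:, 0]
        a = np.zeros(p)
        for _ in range(max_iter):
            a_new = Xh.T @ u
            a_new = _sparsify(a_new, keep_x)
            norm = np.linalg.norm(a_new)
            if norm == 0:
                break
            a_new /= norm
            t = Xh @ a_new
            q = Yh.T @ t
            qn = np.linalg.norm(q)
            if qn == 0:
                a = a_new
                break
            q /= qn
            u = Yh @ q
            if np.linalg.norm(a_new - a) < tol:
                a = a_new
                break
            a = a_new
        # fix sign: largest-magnitude loading entry positive
        if np.any(a != 0):
            imax = int(np.argmax(np.abs(a)))
            if a[imax] < 0:
                a = -a
        t = Xh @ a
        tt = float(t @ t)
        if tt == 0:
            A[:, h] = a
            continue
        p_load = Xh.T @ t / tt
        d = Yh.T @ t / tt
        Xh = Xh - np.outer(t, p_load)
        Yh = Yh - np.outer(t, d)
        A[:, h], P[:, h], D[:, h], T[:, h] = a, p_load, d, t

    centroids = np.vstack([T[y == c].mean(axis=0) for c in classes])
    return SplsdaModel(
        classes=classes,
        ncomp=ncomp,
        keep_x=keep_x,
        x_loadings=A,
        x_proj=P,
        y_loadings=D,
        x_scores=T,
        centroids=centroids,
        x_center=x_center,
        x_scale=x_scale,
        feature_ids=list(feature_ids) if feature_ids is not None else list(range(p)),
    )


def transform(model: SplsdaModel, X_new: np.ndarray) -> np.ndarray:
    """Project new samples into the model's latent score space."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.x_center):
        raise ValueError(
            f"expected {len(model.x_center)} peptides, got {X_new.shape[1]}"
        )
    Xc = (X_new - model.x_center) / model.x_scale
    T = np.zeros((X_new.shape[0], model.ncomp))
    for h in range(model.ncomp):
        t = Xc @ model.x_loadings[:, h]
        Xc = Xc - np.outer(t, model.x_proj[:, h])
        T[:, h] = t
    return T


def predict(model: SplsdaModel, X_new: np.ndarray) -> np.ndarray:
    """Classify new samples by the nearest class centroid in score space.

    Ties are broken deterministically in favor of the first class in
    training label order.
    """
    T = transform(model, X_new)
    d2 = ((T[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)  # argmin returns the first minimum
    return np.array([model.classes[i] for i in idx])
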