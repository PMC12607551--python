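"""Partial least squares discriminant analysis (PLS-DA) via NIPALS.

PLS regresses a class-indicator matrix Y on mean-centered spectra X through
a small number of latent variables (LVs) — directions in spectral space that
maximize covariance with class membership.  NIPALS extracts LVs one at a
time: an inner power iteration finds the X-weight vector w, the score
t = X w, the Y-loading q, and X is deflated by the rank-one fit t p^T before
the next LV.  Classification assigns the class whose indicator column has
the largest predicted value (for two classes this is the usual 0.5
threshold); ties go to the first class in sorted vocabulary order.

Only mean-centering is applied — no unit-variance scaling — which is the
usual choice for derivative spectra, where amplitude is informative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500


def encode_classes(labels) -> tuple[np.ndarray, list]:
    """Indicator matrix (one column per class, sorted vocabulary order)."""
    vocab = sorted(set(labels))
    if len(vocab) < 2:
        raise ValueError("discrimination needs at least 2 classes")
    index = {c: j for j, c in enumerate(vocab)}
    Y = np.zeros((len(labels), len(vocab)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return Y, vocab


@dataclass
class PLSModel:
    """Fitted PLS(-DA) model: centering vectors plus per-LV factors."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray        # W  (n_vars, n_lv)
    x_loadings: np.ndarray     # P  (n_vars, n_lv)
    y_loadings: np.ndarray     # Q  (n_classes, n_lv)
    scores: np.ndarray         # T  (n_samples, n_lv) calibration scores
    explained_y_variance: np.ndarray  # cumulative % per LV
    vocab: list | None = None

    def rotation(self, n_lv: int | None = None) -> np.ndarray:
        """R = W (P^T W)^-1, mapping centered X to scores.

        ``n_lv`` beyond the extracted components (early stop on an exact
        fit) is clamped to the model's actual count.
        """
        a = self.n_lv if n_lv is None else min(n_lv, self.n_lv)
        W, P = self.weights[:, :a], self.x_loadings[:, :a]
        return W @ np.linalg.pinv(P.T @ W)

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """Regression coefficients B (n_vars, n_classes) at a given LV count."""
        a = self.n_lv if n_lv is None else min(n_lv, self.n_lv)
        return self.rotation(a) @ self.y_loadings[:, :a].T

    def predict(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Predicted indicator values: (X - x_mean) B + y_mean."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coefficients(n_lv) + self.y_mean

    def classify(self, X: np.ndarray, n_lv: int | None = None) -> list:
        """Class of the largest predicted indicator (ties: first in vocab)."""
        if self.vocab is None:
            raise ValueError("model has no class vocabulary")
        yhat = self.predict(X, n_lv)
        return [self.vocab[j] for j in np.argmax(yhat, axis=1)]

    def transform(self, X: np.ndarray, n_lv: int | None = None) -> np.ndarray:
        """Project spectra onto the LV basis (scores for plotting)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.rotation(n_lv)

    def to_json(self, path=None) -> str:
        payload = {
            "n_lv": self.n_lv,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "explained_y_variance": self.explained_y_variance.tolist(),
            "vocab": self.vocab,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PLSModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            n_lv=payload["n_lv"],
            x_mean=np.array(payload["x_mean"]),
            y_mean=np.array(payload["y_mean"]),
            weights=np.array(payload["weights"]),
            x_loadings=np.array(payload["x_loadings"]),
            y_loadings=np.array(payload["y_loadings"]),
            scores=np.array(payload["scores"]),
            explained_y_variance=np.array(payload["explained_y_variance"]),
            vocab=payload["vocab"],
        )


def fit_pls(X: np.ndarray, Y: np.ndarray, n_lv: int,
            vocab: list | None = None) -> PLSModel:
    """NIPALS PLS2 on mean-centered X and Y.

    Deterministic given input order.  If the X residual vanishes before
    ``n_lv`` components are extracted (exact fit), extraction stops early and
    the model carries the achievable number of LVs.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, min(n_samples-1, n_vars)] "
                         f"= [1, {min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    ss_y = float(np.sum(F ** 2))

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    expl = np.zeros(n_lv)
    extracted = 0
    for a in range(n_lv):
        # start u from the Y-residual column with the largest variance
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if not np.any(u):
            break
        t_old = np.zeros(n)
        for _ in range(NIPALS_MAX_ITER):
            w = E.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0.0:
                break
            w /= norm_w
            t = E @ w
            tt = float(t @ t)
            if tt == 0.0:
                break
            q = F.T @ t / tt
            qq = float(q @ q)
            if qq == 0.0:
                break
            u = F @ q / qq
            if np.linalg.norm(t - t_old) <= NIPALS_TOL * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        tt = float(t @ t)
        if norm_w == 0.0 or tt <= 0.0:
            break
        p_vec = E.T @ t / tt
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_vec, q, t
        expl[a] = 100.0 * tt * float(q @ q) / ss_y if ss_y > 0 else 0.0
        extracted = a + 1

    return PLSModel(
        n_lv=extracted,
        x_mean=x_mean, y_mean=y_mean,
        weights=W[:, :extracted], x_loadings=P[:, :extracted],
        y_loadings=Q[:, :extracted], scores=T[:, :extracted],
        explained_y_variance=np.cumsum(expl[:extracted]),
        vocab=vocab,
    )


def fit_plsda(X: np.ndarray, labels, n_lv: int) -> PLSModel:
    """Convenience wrapper: encode labels, then fit."""
    Y, vocab = encode_classes(labels)
    return fit_pls(X, Y, n_lv, vocab=vocab)


def predict_pls(model: PLSModel, X: np.ndarray,
                n_lv: int | None = None) -> np.ndarray:
    return model.predict(X, n_lv)


def classify(model: PLSModel, X: np.ndarray, n_lv: int | None = None) -> list:
    return model.classify(X, n_lv)


def scores_loadings(model: PLSModel,
                    X: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Scores of X (calibration scores if X is None) and per-LV X loadings."""
    scores = model.scores if X is None else model.transform(X)
    return scores, model.x_loadings


def explained_y_variance(model: PLSModel) -> np.ndarray:
    """Cumulative % of centered-Y sum of squares captured per LV."""
    return model.explained_y_variance
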