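"""Fisher linear discriminant analysis as a supervised projection.

The model maximizes the Fisher criterion

    J(w) = (w' S_b w) / (w' S_w w),

where ``S_w`` and ``S_b`` are the within- and between-class scatter matrices.
The maximizers are the top generalized eigenvectors of ``S_b v = lambda S_w v``;
at most ``C - 1`` components carry discriminative information for ``C``
classes, and the binary solution coincides (up to scale) with the closed form
``w ~ S_w^{-1} (mu_1 - mu_0)``.

Following standard modelling-package conventions, :class:`FisherLDA` is built
from data and ``fit()`` returns a :class:`FisherLDAResults` object carrying
the projection, projected class means, decision threshold, diagnostics and a
``summary()`` table. Features are z-normalized internally with statistics
computed from the fitting data, so the results object is self-contained: it
applies the same normalization when projecting new data.

The binary decision rule is linear with equal class priors: the threshold is
the midpoint of the projected class means, with the positive class (ASD) on
the high side and ties going to ASD. A singular ``S_w`` is handled by a ridge
``eps * tr(S_w)/d * I`` (default ``eps = 1e-6``) rather than a pseudo-inverse,
for determinism across linear-algebra backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .errors import (
    ArgumentError,
    DegenerateClassError,
    ShapeError,
    SingularityError,
)
from .features import FeatureMatrix, NormalizationStats, zscore_apply, zscore_fit
from .signal_io import ASD, NORMAL

DEFAULT_RIDGE = 1e-6


def scatter_matrices(
    X: np.ndarray, y: Sequence, *, allow_degenerate: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class scatter matrices ``(S_w, S_b)``.

    ``S_w = sum_c sum_{i in c} (x_i - mu_c)(x_i - mu_c)'`` and
    ``S_b = sum_c n_c (mu_c - mu)(mu_c - mu)'``; both symmetric PSD.
    Classes with fewer than two rows are rejected unless
    ``allow_degenerate`` is set (useful for algebraic edge-case checks).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ShapeError("X must be [n_rows, n_features] with one label per row")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateClassError(f"need >= 2 classes, got {classes.tolist()}")
    d = X.shape[1]
    mu = X.mean(axis=0)
    S_w = np.zeros((d, d))
    S_b = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        if Xc.shape[0] < 2 and not allow_degenerate:
            raise DegenerateClassError(f"class {c!r} has {Xc.shape[0]} row(s); need >= 2")
        mu_c = Xc.mean(axis=0)
        R = Xc - mu_c
        S_w += R.T @ R
        diff = (mu_c - mu)[:, None]
        S_b += Xc.shape[0] * (diff @ diff.T)
    return S_w, S_b


def fisher_criterion(w: np.ndarray, S_w: np.ndarray, S_b: np.ndarray) -> float:
    """Rayleigh quotient ``(w' S_b w) / (w' S_w w)``; scale-invariant in w."""
    w = np.asarray(w, dtype=np.float64).ravel()
    denom = float(w @ S_w @ w)
    if denom <= 0:
        raise SingularityError("w' S_w w = 0: direction lies in the null space of S_w")
    return float(w @ S_b @ w) / denom


@dataclass
class FisherLDAResults:
    """Fitted discriminant: projection, threshold, diagnostics.

    ``W`` has unit-norm columns (at most C-1); on component 1 the positive
    class (ASD) projects at or above the negative class (NORMAL). For binary
    problems ``threshold`` is the midpoint of the projected class means;
    multi-class prediction is nearest projected mean.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    classes: tuple
    class_means_projected: dict
    class_counts: dict
    threshold: float | None
    class_order: tuple
    norm_stats: NormalizationStats
    ridge: float
    n_obs: int

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def _prepare(self, X) -> np.ndarray:
        X = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.W.shape[0]:
            raise ShapeError(
                f"X has {X.shape[1]} features, model expects {self.W.shape[0]}"
            )
        return zscore_apply(self.norm_stats, X)

    def project(self, X) -> np.ndarray:
        """Discriminant scores [n_rows, n_components] (normalization applied)."""
        return self._prepare(X) @ self.W

    def predict(self, X) -> np.ndarray:
        """Class labels; binary rule: ASD iff score >= threshold (ties -> ASD)."""
        scores = self.project(X)
        if len(self.classes) == 2:
            neg, pos = self.class_order
            return np.where(scores[:, 0] >= self.threshold, pos, neg).astype(object)
        means = np.stack([self.class_means_projected[c] for c in self.classes])
        dists = np.linalg.norm(scores[:, None, :] - means[None, :, :], axis=2)
        idx = np.argmin(dists, axis=1)
        return np.asarray(self.classes, dtype=object)[idx]

    def criterion(self, S_w: np.ndarray, S_b: np.ndarray) -> float:
        """J(w) of the leading fitted direction against given scatter matrices."""
        return fisher_criterion(self.W[:, 0], S_w, S_b)

    def summary(self) -> str:
        lines = [
            "Fisher Linear Discriminant Results",
            "=" * 50,
            f"observations:        {self.n_obs}",
            f"features:            {self.W.shape[0]}",
            f"classes:             {', '.join(map(str, self.classes))}"
            f"  (n = {', '.join(str(self.class_counts[c]) for c in self.classes)})",
            f"components:          {self.n_components}",
            f"ridge (eps):         {self.ridge:g}",
            f"leading eigenvalue:  {self.eigenvalues[0]:.6g}",
        ]
        for c in self.classes:
            m = np.atleast_1d(self.class_means_projected[c])
            lines.append(f"projected mean [{c}]: "
                         + ", ".join(f"{v:.6g}" for v in m))
        if self.threshold is not None:
            neg, pos = self.class_order
            lines.append(f"threshold:           {self.threshold:.6g} "
                         f"(score >= threshold -> {pos}, else {neg}; ties -> {pos})")
        return "\n".join(lines)

    def plot_scores(self, X, ax=None):
        """Histogram of component-1 scores by true class (needs matplotlib)."""
        import matplotlib.pyplot as plt

        y = X.y if isinstance(X, FeatureMatrix) else None
        scores = self.project(X)[:, 0]
        if ax is None:
            _, ax = plt.subplots()
        if y is None:
            ax.hist(scores, bins=50)
        else:
            for c in self.classes:
                ax.hist(scores[np.asarray(y) == c], bins=50, alpha=0.6, label=str(c))
            ax.legend()
        if self.threshold is not None:
            ax.axvline(self.threshold, color="k", linestyle="--", lw=1)
        ax.set_xlabel("discriminant score")
        ax.set_ylabel("rows")
        return ax

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format_version": "1",
            "W": self.W.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "classes": list(self.classes),
            "class_means_projected": {
                str(c): np.atleast_1d(m).tolist()
                for c, m in self.class_means_projected.items()
            },
            "class_counts": {str(c): int(n) for c, n in self.class_counts.items()},
            "threshold": self.threshold,
            "class_order": list(self.class_order),
            "norm_stats": self.norm_stats.to_dict(),
            "ridge": self.ridge,
            "n_obs": self.n_obs,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FisherLDAResults":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            W=np.asarray(d["W"], dtype=np.float64),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=np.float64),
            classes=tuple(d["classes"]),
            class_means_projected={
                c: np.asarray(m, dtype=np.float64)
                for c, m in d["class_means_projected"].items()
            },
            class_counts={c: int(n) for c, n in d["class_counts"].items()},
            threshold=d["threshold"],
            class_order=tuple(d["class_order"]),
            norm_stats=NormalizationStats.from_dict(d["norm_stats"]),
            ridge=float(d["ridge"]),
            n_obs=int(d["n_obs"]),
        )


class FisherLDA:
    """Fisher discriminant model built from feature rows and class labels.

    Parameters
    ----------
    X : array or FeatureMatrix
        Feature rows (training set). A FeatureMatrix also supplies ``y``.
    y : sequence, optional
        Class labels per row (required when ``X`` is a bare array).
    normalize : bool
        Fit z-normalization on ``X`` and bake it into the results (default).
        With ``False`` the caller guarantees X is already normalized.
    positive_label, negative_label :
        Orientation of component 1 and of the binary decision rule.
    """

    def __init__(
        self,
        X,
        y=None,
        *,
        normalize: bool = True,
        positive_label=ASD,
        negative_label=NORMAL,
    ) -> None:
        if isinstance(X, FeatureMatrix):
            if y is None:
                y = X.y
            X = X.X
        if y is None:
            raise ArgumentError("labels y are required")
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ShapeError("X must be [n_rows, n_features] with one label per row")
        if not np.isfinite(self.X).all():
            raise ArgumentError("X contains non-finite values")
        self.normalize = normalize
        self.positive_label = positive_label
        self.negative_label = negative_label

    @classmethod
    def from_feature_matrix(cls, fm: FeatureMatrix, **kwargs) -> "FisherLDA":
        return cls(fm.X, fm.y, **kwargs)

    def fit(self, ridge: float = DEFAULT_RIDGE) -> FisherLDAResults:
        """Solve the generalized eigenproblem; returns a results object.

        ``ridge`` is the relative coefficient eps of the stabilizer
        ``eps * tr(S_w)/d * I`` added to ``S_w``; 0 requests the unregularized
        problem and raises :class:`SingularityError` when ``S_w`` is singular.
        """
        if ridge < 0:
            raise ArgumentError(f"ridge must be >= 0, got {ridge}")
        if self.normalize:
            stats = zscore_fit(self.X)
            Z = zscore_apply(stats, self.X)
        else:
            d_ = self.X.shape[1]
            stats = NormalizationStats(
                mean=np.zeros(d_), sd=np.ones(d_), fitted_on=self.X.shape[0]
            )
            Z = self.X
        y = self.y
        classes = tuple(np.unique(y))
        S_w, S_b = scatter_matrices(Z, y)
        d = Z.shape[1]
        if ridge > 0:
            tr = np.trace(S_w)
            S_w_reg = S_w + ridge * (tr / d if tr > 0 else 1.0) * np.eye(d)
        else:
            S_w_reg = S_w
        try:
            # eigh solves the symmetric-definite generalized problem S_b v = lam S_w v
            eigvals, eigvecs = scipy.linalg.eigh(S_b, S_w_reg)
        except np.linalg.LinAlgError as exc:
            raise SingularityError(
                "S_w is singular; refit with ridge > 0 (default 1e-6)"
            ) from exc
        order = np.argsort(eigvals)[::-1]
        k = min(len(classes) - 1, d)
        W = eigvecs[:, order[:k]]
        eigenvalues = eigvals[order[:k]]
        W = W / np.linalg.norm(W, axis=0, keepdims=True)

        # orientation: positive class at or above negative class on component 1
        proj_means = {c: Z[y == c].mean(axis=0) @ W for c in classes}
        if len(classes) == 2 and {self.positive_label, self.negative_label} == set(classes):
            neg, pos = self.negative_label, self.positive_label
        else:
            neg, pos = classes[0], classes[-1]
        if len(classes) == 2 and proj_means[pos][0] < proj_means[neg][0]:
            W = W.copy()
            W[:, 0] = -W[:, 0]
            proj_means = {c: Z[y == c].mean(axis=0) @ W for c in classes}
        threshold = None
        if len(classes) == 2:
            threshold = float(0.5 * (proj_means[pos][0] + proj_means[neg][0]))
        return FisherLDAResults(
            W=W,
            eigenvalues=eigenvalues,
            classes=classes,
            class_means_projected={c: m.copy() for c, m in proj_means.items()},
            class_counts={c: int((y == c).sum()) for c in classes},
            threshold=threshold,
            class_order=(neg, pos),
            norm_stats=stats,
            ridge=ridge,
            n_obs=Z.shape[0],
        )


def flda_fit(X, y=None, ridge: float = DEFAULT_RIDGE, **kwargs) -> FisherLDAResults:
    """Functional wrapper: ``FisherLDA(X, y, **kwargs).fit(ridge)``."""
    return FisherLDA(X, y, **kwargs).fit(ridge=ridge)


def flda_project(model: FisherLDAResults, X) -> np.ndarray:
    return model.project(X)


def flda_predict(model: FisherLDAResults, X) -> np.ndarray:
    return model.predict(X)
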