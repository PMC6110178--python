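"""Two-class PCA-LDA classification of binned single-cell mass spectra.

The model reduces each 3,000-bin spectrum to its scores on the top-k principal
components (k = 2 by default; PCA by SVD of the column-mean-centred matrix, no
variance scaling) and separates the classes with a Fisher linear discriminant
on those scores: w proportional to Sw^-1 (mu1 - mu2) with the decision
threshold at the midpoint of the projected class means (equal priors, shared
covariance — the 50/50 training design).

Organised as a model / results pair: build :class:`PcaLda` from a feature
matrix with labels, call :meth:`PcaLda.fit`, and work with the returned
:class:`PcaLdaResults` (prediction, leave-one-out cross-validation, summary
table, score plot, JSON serialization). Leave-one-out refits the *entire*
model — PCA included — inside every fold, so no information leaks from the
held-out spectrum into the projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .msproc import N_BINS


@dataclass
class FeatureMatrix:
    """Rows = cells, columns = the fixed 3,000-bin m/z grid."""

    values: np.ndarray
    labels: list[str] | None = None
    ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != N_BINS:
            raise ValueError(f"feature matrix must have exactly {N_BINS} columns")
        n = self.values.shape[0]
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != n:
                raise ValueError("one label per row required")
            if len(set(self.labels)) > 2:
                raise ValueError("at most two classes are supported")
        if self.ids is None:
            self.ids = list(range(n))
        elif len(self.ids) != n:
            raise ValueError("one id per row required")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str | None = "label") -> "FeatureMatrix":
        """Build from a DataFrame whose non-label columns are the 3,000 bins."""
        labels = None
        if label_column is not None and label_column in df.columns:
            labels = df[label_column].tolist()
            df = df.drop(columns=[label_column])
        return cls(values=df.to_numpy(dtype=float), labels=labels, ids=list(df.index))


def fit_pca(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Top-k principal components of a row-sample matrix.

    Returns (mean, loadings (k, p), explained_variance_fraction (k,),
    scores (n, k)). Centering is by column mean; no variance scaling. Loading
    signs are fixed so each component's largest-magnitude element is positive.
    Raises on zero total variance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 rows")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_var = float((Xc**2).sum()) / (n - 1)
    if total_var <= 0:
        raise ValueError("zero total variance: all rows identical")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt[:k]
    # deterministic sign: largest-|.| element of each loading positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] = -loadings[j]
    explained = (s[:k] ** 2 / (n - 1)) / total_var
    scores = Xc @ loadings.T
    return mean, loadings, explained, scores


@dataclass
class Discriminant:
    """Fisher discriminant in PCA score space."""

    direction: np.ndarray  # unit vector in score space
    threshold: float  # midpoint of projected class means
    class_names: tuple[str, str]  # alphabetical; class_names[0] on the positive side

    def classify(self, scores: np.ndarray) -> list[str]:
        proj = np.atleast_2d(scores) @ self.direction
        # tie at the threshold goes to the alphabetically first class
        return [self.class_names[0] if v >= self.threshold else self.class_names[1] for v in proj]


def fit_lda(scores: np.ndarray, labels: Sequence[str], ridge: float = 1e-8) -> Discriminant:
    """Fisher LDA on k-dimensional scores: w ∝ Sw^-1 (mu1 - mu2).

    Classes are ordered alphabetically and the direction oriented so the first
    class projects above the midpoint threshold. A small ridge is added to the
    pooled within-class covariance when it is near-singular.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = [str(l) for l in labels]
    names = tuple(sorted(set(labels)))
    if len(names) != 2:
        raise ValueError("exactly two classes are required")
    groups = [scores[[l == name for l in labels]] for name in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each class needs at least 2 members")
    mus = [g.mean(axis=0) for g in groups]
    k = scores.shape[1]
    sw = np.zeros((k, k))
    for g, mu in zip(groups, mus):
        d = g - mu
        sw += d.T @ d
    sw /= len(labels) - 2
    if np.linalg.cond(sw) > 1e12:
        sw = sw + ridge * np.trace(sw) * np.eye(k)
    w = np.linalg.solve(sw, mus[0] - mus[1])
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("class means coincide; no discriminant direction")
    w = w / norm
    if mus[0] @ w < mus[1] @ w:
        w = -w
    threshold = float(0.5 * (mus[0] @ w + mus[1] @ w))
    return Discriminant(direction=w, threshold=threshold, class_names=names)


class PcaLda:
    """PCA-LDA model of labeled binned spectra (statsmodels-style endog container).

    Parameters
    ----------
    X : FeatureMatrix or (n, 3000) array
        Training spectra, total-ion normalized and binned.
    labels : sequence of str, optional
        Two-class labels; required unless ``X`` is a labeled FeatureMatrix.
    """

    def __init__(self, X, labels: Sequence[str] | None = None, ids: Sequence[int] | None = None):
        if isinstance(X, FeatureMatrix):
            self.data = X
        else:
            self.data = FeatureMatrix(values=np.asarray(X), labels=list(labels) if labels is not None else None, ids=list(ids) if ids is not None else None)
        if self.data.labels is None:
            raise ValueError("training data must carry class labels")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "PcaLda":
        return cls(FeatureMatrix.from_dataframe(df, label_column))

    def fit(self, k: int = 2) -> "PcaLdaResults":
        """Fit PCA (top-k components) then Fisher LDA on the training scores."""
        mean, loadings, explained, scores = fit_pca(self.data.values, k)
        disc = fit_lda(scores, self.data.labels)
        centroids = {
            name: scores[[l == name for l in self.data.labels]].mean(axis=0)
            for name in disc.class_names
        }
        return PcaLdaResults(
            model=self,
            k=k,
            mean=mean,
            loadings=loadings,
            explained_variance_fraction=explained,
            training_scores=scores,
            discriminant=disc,
            class_centroids=centroids,
        )


@dataclass
class PcaLdaResults:
    """Fitted PCA-LDA model: projection, discriminant, and diagnostics."""

    model: PcaLda | None
    k: int
    mean: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    training_scores: np.ndarray
    discriminant: Discriminant
    class_centroids: dict[str, np.ndarray] = field(default_factory=dict)

    # -- projection / prediction ------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Project spectra into the training score space (training mean removed)."""
        values = X.values if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
        if values.shape[1] != self.mean.size:
            raise ValueError("column count does not match the trained model")
        return (values - self.mean) @ self.loadings.T

    def predict(self, X) -> list[str]:
        """Class labels for new spectra under the trained discriminant."""
        return self.discriminant.classify(self.transform(X))

    def apportion(self, X_test) -> "ApportionmentResult":
        """Classify a test set and score agreement with its recorded labels."""
        scores = self.transform(X_test)
        predicted = self.discriminant.classify(scores)
        recorded = X_test.labels if isinstance(X_test, FeatureMatrix) else None
        accuracy = None
        if recorded is not None and len(recorded):
            accuracy = float(np.mean([p == r for p, r in zip(predicted, recorded)]))
        return ApportionmentResult(
            predicted=predicted, recorded=recorded, accuracy=accuracy, scores=scores
        )

    # -- cross-validation --------------------------------------------------
    def loocv(self) -> "LoocvResult":
        """Leave-one-out cross-validation with PCA and LDA refit in every fold."""
        data = self.model.data
        return loocv_accuracy(data.values, data.labels, self.k)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "PCA-LDA model summary",
            "=" * 52,
            f"training cells:        {self.training_scores.shape[0]}",
            f"classes:               {self.discriminant.class_names[0]} (+) / "
            f"{self.discriminant.class_names[1]} (-)",
            f"principal components:  {self.k}",
        ]
        for j, frac in enumerate(self.explained_variance_fraction, start=1):
            lines.append(f"  PC{j} explained variance: {100 * frac:6.1f} %")
        lines.append(
            f"  total captured:          {100 * self.explained_variance_fraction.sum():6.1f} %"
        )
        w = ", ".join(f"{v:+.4f}" for v in self.discriminant.direction)
        lines.append(f"discriminant direction (score space): [{w}]")
        lines.append(f"decision threshold:    {self.discriminant.threshold:+.6g}")
        for name, c in self.class_centroids.items():
            coords = ", ".join(f"{v:+.4g}" for v in c)
            lines.append(f"  centroid[{name}]: ({coords})")
        return "\n".join(lines)

    def feature_weights(self) -> np.ndarray:
        """Discriminant direction pulled back to the 3,000-bin feature space."""
        return self.loadings.T @ self.discriminant.direction

    def plot_scores(self, X_test=None, ax=None, path=None):
        """PC score plot of training (and optional test) cells, per class."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        names = self.discriminant.class_names
        labels = np.asarray(self.model.data.labels)
        markers = {names[0]: "s", names[1]: "o"}
        for name in names:
            pts = self.training_scores[labels == name]
            ax.scatter(pts[:, 0], pts[:, 1], marker=markers[name], facecolors="none",
                       edgecolors="C0" if name == names[0] else "k", label=f"{name} (train)")
        if X_test is not None:
            scores = self.transform(X_test)
            pred = self.discriminant.classify(scores)
            for name in names:
                pts = scores[[p == name for p in pred]]
                if len(pts):
                    ax.scatter(pts[:, 0], pts[:, 1], marker=markers[name],
                               color="C0" if name == names[0] else "k", label=f"{name} (test)")
        ax.set_xlabel("PC1 score")
        ax.set_ylabel("PC2 score" if self.k > 1 else "")
        ax.legend(fontsize=7)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "k": self.k,
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "discriminant": {
                "direction": self.discriminant.direction.tolist(),
                "threshold": self.discriminant.threshold,
                "class_names": list(self.discriminant.class_names),
            },
            "class_centroids": {k_: v.tolist() for k_, v in self.class_centroids.items()},
            "n_bins": int(self.mean.size),
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PcaLdaResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        disc = Discriminant(
            direction=np.asarray(doc["discriminant"]["direction"]),
            threshold=float(doc["discriminant"]["threshold"]),
            class_names=tuple(doc["discriminant"]["class_names"]),
        )
        return cls(
            model=None,
            k=int(doc["k"]),
            mean=np.asarray(doc["mean"]),
            loadings=np.asarray(doc["loadings"]),
            explained_variance_fraction=np.asarray(doc["explained_variance_fraction"]),
            training_scores=np.empty((0, int(doc["k"]))),
            discriminant=disc,
            class_centroids={k_: np.asarray(v) for k_, v in doc["class_centroids"].items()},
        )


@dataclass
class ApportionmentResult:
    predicted: list[str]
    recorded: list[str] | None
    accuracy: float | None
    scores: np.ndarray

    @property
    def errors(self) -> list[int]:
        """Row indices where prediction disagrees with the recorded label."""
        if self.recorded is None:
            return []
        return [i for i, (p, r) in enumerate(zip(self.predicted, self.recorded)) if p != r]


@dataclass
class LoocvResult:
    accuracy: float
    verdicts: list[bool]
    predicted: list[str]


def loocv_accuracy(X, labels: Sequence[str], k: int = 2) -> LoocvResult:
    """Leave-one-out cross-validation of the full PCA(k)+LDA pipeline.

    For every row, PCA (mean + loadings) and the discriminant are refit on the
    remaining rows only, and the held-out spectrum is projected and classified
    by that fold's model — no leakage of the held-out row into the projection.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = [str(l) for l in labels]
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 rows")
    verdicts, predicted = [], []
    for i in range(n):
        keep = np.arange(n) != i
        train_labels = [l for j, l in enumerate(labels) if j != i]
        if min(train_labels.count(c) for c in set(train_labels)) < 2:
            raise ValueError("each class needs at least 2 members in every fold")
        mean, loadings, _, scores = fit_pca(X[keep], k)
        disc = fit_lda(scores, train_labels)
        pred = disc.classify((X[i] - mean) @ loadings.T)[0]
        predicted.append(pred)
        verdicts.append(pred == labels[i])
    return LoocvResult(
        accuracy=float(np.mean(verdicts)), verdicts=verdicts, predicted=predicted
    )


def apportion(results: PcaLdaResults, X_test) -> ApportionmentResult:
    """Functional alias for :meth:`PcaLdaResults.apportion`."""
    return results.apportion(X_test)
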