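"""The two movement-intention detectors: LDA on features, template matching.

The LDA is the classical Fisher/Gaussian discriminant with pooled
within-class covariance and equal priors (classes are balanced by design of
the epoching), solved in closed form. Template matching builds the ensemble
average of the training movement epochs (the prototypical MRCP) and detects
movement when the Pearson correlation between an epoch and the template
exceeds a threshold fitted on training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LDA_RIDGE_EPS = 1e-6
COND_LIMIT = 1e8
THRESHOLD_GRID = np.round(np.linspace(-1.0, 1.0, 201), 2)


@dataclass
class LdaModel:
    weights: np.ndarray
    bias: float
    class_order: tuple[str, str] = ("noise", "movement")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not (np.all(np.isfinite(self.weights)) and np.isfinite(self.bias)):
            raise ValueError("non-finite LDA parameters")


@dataclass
class TemplateModel:
    template: np.ndarray
    threshold: float
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if np.ptp(self.template) == 0:
            raise ValueError("template is constant; correlation undefined")
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [-1, 1]")


def train_lda(X: np.ndarray, y: np.ndarray) -> LdaModel:
    """Closed-form Fisher LDA: ``w = Sigma_pooled^-1 (mu1 - mu0)``.

    The bias places the boundary at the midpoint of the class means (equal
    priors). If the pooled covariance is ill-conditioned it is ridged by
    ``eps * trace(Sigma)/d * I`` with eps = 1e-6. Decision: movement iff
    ``w.x + b > 0``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    d = X.shape[1]
    dof = max(n0 + n1 - 2, 1)
    cov = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / dof
    cov = np.atleast_2d(cov)
    if np.linalg.cond(cov) > COND_LIMIT:
        cov = cov + LDA_RIDGE_EPS * np.trace(cov) / d * np.eye(d)
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return LdaModel(weights=w, bias=b)


def lda_score(model: LdaModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({len(model.weights)})")
    return X @ model.weights + model.bias


def lda_classify(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """1 (movement) where the discriminant score is strictly positive; a
    score exactly on the boundary is called noise."""
    return (lda_score(model, X) > 0).astype(int)


def build_template(train_epochs) -> np.ndarray:
    """Pointwise mean of the training movement epochs — the ensemble-average MRCP."""
    arrays = [np.asarray(getattr(e, "samples", e), dtype=float) for e in train_epochs]
    if len(arrays) < 2:
        raise ValueError("need at least 2 movement epochs to build a template")
    return np.mean(arrays, axis=0)


def template_correlation(template: np.ndarray, epoch) -> float:
    """Pearson correlation between template and epoch (gain/offset invariant)."""
    x = np.asarray(template, dtype=float)
    y = np.asarray(getattr(epoch, "samples", epoch), dtype=float)
    if len(x) != len(y):
        raise ValueError("template and epoch lengths differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1])


def fit_threshold(correlations, labels) -> float:
    """Grid-search the correlation threshold minimising detection error.

    Candidates run from -1 to 1 in steps of 0.01; movement is called when
    ``r > threshold`` (strictly). Ties in error are broken toward the lower
    threshold, favouring sensitivity.
    """
    r = np.asarray(correlations, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit a threshold")
    pred = r[None, :] > THRESHOLD_GRID[:, None]
    errors = (pred != (y[None, :] == 1)).mean(axis=1)
    return float(THRESHOLD_GRID[int(np.argmin(errors))])


def template_classify(model: TemplateModel, epochs) -> np.ndarray:
    r = np.array([template_correlation(model.template, e) for e in epochs])
    return (r > model.threshold).astype(int)
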