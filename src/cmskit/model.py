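"""Weighted elastic-net multinomial CMS classifier.

The classifier is a 4-class multinomial logistic model with the elastic-net
penalty lambda * [ (1-alpha)/2 ||b||_2^2 + alpha ||b||_1 ] applied to a
weighted log-likelihood, mirroring the glmnet objective: weights are rescaled
to mean 1, the loss is averaged over samples, and intercepts are never
penalized.  NanoString training samples carry weight 1.5 by default while
co-training RNA-seq/microarray samples carry weight 1; lambda is chosen by
stratified k-fold cross-validation minimizing weighted misclassification
error, with ties broken toward the larger (sparser) lambda.

Prediction runs the full single-sample pipeline: optional log2 transform,
reference-quantile normalization against the model's own fixation-specific
reference, linear predictors, softmax.  A sample is assigned its argmax class
only when the maximum probability reaches the confidence threshold (default
0.6); otherwise it is left unclassified (NA).  The confidence score is the
difference between the two largest class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import CMS_CLASSES, CmskitError, ExpressionMatrix, GenePanel, LabelVector
from .normalize import ReferenceDistribution, normalize_sample_vector

# below this lambda the penalty is numerically negligible and the fit is done
# unpenalized (lbfgs), which is also the exact lambda->0 MLE limit
_LAMBDA_UNPENALIZED = 1e-8

# a standardized-scale coefficient below solver precision counts as zero when
# tallying active sets (saga at tol 1e-4 can leave ~1e-7 stragglers)
NONZERO_TOL = 1e-5

DEFAULT_ALPHA = {"FF": 0.7, "FFPE": 0.8}
DEFAULT_THRESHOLD = 0.6
DEFAULT_NANOSTRING_WEIGHT = 1.5


@dataclass
class TrainingSet:
    """Normalized panel expression + labels + per-sample weights and source tags."""

    X: ExpressionMatrix
    y: LabelVector
    weights: np.ndarray
    source: tuple[str, ...]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.source = tuple(self.source)
        if self.X.sample_ids != self.y.sample_ids:
            raise CmskitError("TrainingSet X and y sample ids differ")
        if any(l == "NA" for l in self.y.labels):
            raise CmskitError("TrainingSet labels must not contain NA")
        if len(self.weights) != self.X.n_samples or len(self.source) != self.X.n_samples:
            raise CmskitError("weights/source length does not match sample count")
        if np.any(self.weights <= 0):
            raise CmskitError("sample weights must be positive")
        bad = sorted({t for t in self.source if t not in ("nanostring", "cotraining")})
        if bad:
            raise CmskitError(f"unknown source tags: {', '.join(bad)}")


@dataclass
class CMSModel:
    panel: GenePanel
    fixation: str
    alpha: float
    lambda_: float
    intercepts: np.ndarray  # (4,)
    coefficients: np.ndarray  # (n_genes, 4)
    reference: ReferenceDistribution
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # C-contiguous so dot products accumulate identically after a
        # save/load round trip (bit-identical predictions)
        self.intercepts = np.ascontiguousarray(self.intercepts, dtype=float)
        self.coefficients = np.ascontiguousarray(self.coefficients, dtype=float)
        if not 0.0 <= self.alpha <= 1.0:
            raise CmskitError("alpha must lie in [0, 1]")
        if self.lambda_ < 0:
            raise CmskitError("lambda must be nonnegative")
        if self.fixation not in ("FF", "FFPE"):
            raise CmskitError(f"model fixation must be FF or FFPE, got {self.fixation!r}")
        if self.intercepts.shape != (4,):
            raise CmskitError("expected 4 intercepts")
        if self.coefficients.shape != (len(self.panel), 4):
            raise CmskitError(
                f"coefficient matrix shape {self.coefficients.shape} != "
                f"({len(self.panel)}, 4)"
            )


@dataclass
class Prediction:
    sample_id: str
    probs: tuple[float, float, float, float]
    label: str
    max_prob: float
    confidence: float
    argmax_tied: bool = False


def default_weights(
    source_tags, nanostring_weight: float = DEFAULT_NANOSTRING_WEIGHT
) -> np.ndarray:
    """Weight ``nanostring`` samples by ``nanostring_weight`` (default 1.5),
    co-training samples by 1."""
    if nanostring_weight <= 0:
        raise CmskitError("nanostring_weight must be positive")
    tags = list(source_tags)
    bad = sorted({t for t in tags if t not in ("nanostring", "cotraining")})
    if bad:
        raise CmskitError(f"unknown source tags: {', '.join(bad)}")
    return np.asarray(
        [nanostring_weight if t == "nanostring" else 1.0 for t in tags], dtype=float
    )


# ---------------------------------------------------------------------------
# fitting internals


def _encode_labels(labels) -> np.ndarray:
    lut = {c: k for k, c in enumerate(CMS_CLASSES)}
    return np.asarray([lut[l] for l in labels], dtype=int)


def _weighted_standardize(X: np.ndarray, w: np.ndarray):
    """Weighted per-gene centering/scaling; constant genes are zeroed out so the
    penalty drives their coefficient to 0 with no special-casing."""
    wn = w / w.sum()
    mean = X.T @ wn
    var = ((X - mean) ** 2).T @ wn
    sd = np.sqrt(var)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    return Xs, mean, sd_safe


def _lambda_max(Xs: np.ndarray, Y: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which all coefficients are zero (glmnet convention).

    With standardized X and weights rescaled to mean 1, the null-model gradient
    for gene j, class k is (1/n) sum_i w_i x_ij (y_ik - pbar_k).
    """
    n = len(w)
    wn = w / w.mean()
    pbar = (Y.T @ wn) / n
    grad = Xs.T @ (wn[:, None] * (Y - pbar)) / n
    return float(np.abs(grad).max() / max(alpha, 1e-3))


def _make_lambda_grid(
    Xs: np.ndarray, Y: np.ndarray, w: np.ndarray, alpha: float, n_lambda: int
) -> np.ndarray:
    lmax = _lambda_max(Xs, Y, w, alpha)
    n, p = Xs.shape
    ratio = 1e-4 if n > p else 1e-2
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _fit_path(
    Xs: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    seed: int,
    tol: float,
    max_iter: int,
):
    """Fit the model along a descending lambda path with warm starts.

    Returns (coefs, intercepts): lists over lambdas of (4, p) coefficient
    matrices and (4,) intercepts on the standardized scale.
    """
    n = len(y)
    wn = w / w.mean()  # glmnet rescales weights to sum to n
    coefs, intercepts = [], []
    est = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        warm_start=True,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
        fit_intercept=True,
    )
    for lam in lambdas:
        if lam <= _LAMBDA_UNPENALIZED:
            plain = LogisticRegression(
                C=np.inf, solver="lbfgs", tol=1e-10, max_iter=5000
            )
            plain.fit(Xs, y, sample_weight=wn)
            coefs.append(np.asarray(plain.coef_))
            intercepts.append(np.asarray(plain.intercept_))
            continue
        # glmnet objective: (1/n) sum w_i loss_i + lam*penalty  =>  C = 1/(n*lam)
        est.set_params(C=1.0 / (n * lam))
        est.fit(Xs, y, sample_weight=wn)
        coefs.append(est.coef_.copy())
        intercepts.append(est.intercept_.copy())
    return coefs, intercepts


def _predict_labels(Xs: np.ndarray, coef: np.ndarray, intercept: np.ndarray) -> np.ndarray:
    eta = Xs @ coef.T + intercept
    return np.argmax(eta, axis=1)


def _log_proba(Xs: np.ndarray, coef: np.ndarray, intercept: np.ndarray) -> np.ndarray:
    eta = Xs @ coef.T + intercept
    eta -= eta.max(axis=1, keepdims=True)
    return eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))


def _cross_validate(Xs, y, w, alpha, lambdas, cv_folds, seed, tol, max_iter):
    """Weighted CV misclassification error and multinomial deviance per lambda."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    err = np.zeros(len(lambdas))
    dev = np.zeros(len(lambdas))
    total_w = 0.0
    for fold, (tr, va) in enumerate(skf.split(Xs, y)):
        coefs, intercepts = _fit_path(
            Xs[tr], y[tr], w[tr], alpha, lambdas, seed + fold + 1, tol, max_iter
        )
        total_w += w[va].sum()
        for li in range(len(lambdas)):
            pred = _predict_labels(Xs[va], coefs[li], intercepts[li])
            err[li] += w[va][pred != y[va]].sum()
            logp = _log_proba(Xs[va], coefs[li], intercepts[li])
            dev[li] += -2.0 * (w[va] * logp[np.arange(len(va)), y[va]]).sum()
    return err / total_w, dev / total_w


def _select_lambda(cv_errors: np.ndarray, cv_deviances: np.ndarray) -> int:
    """Pick the lambda minimizing CV misclassification error.

    Exact ties — common when the data are separable over a stretch of the
    path, where the 0/1 loss carries no information — are broken by the
    weighted multinomial deviance, so that among equally accurate models the
    best-calibrated probabilities win; any remaining tie goes to the larger
    (sparser) lambda, i.e. the earlier index on the descending grid.
    """
    err = np.round(cv_errors, 12)
    tied = np.flatnonzero(err == err.min())
    dev = np.round(cv_deviances[tied], 12)
    return int(tied[np.argmin(dev)])


def fit(
    train: TrainingSet,
    reference: ReferenceDistribution,
    alpha: float | None = None,
    lambda_grid=None,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambda: int = 40,
    standardize: bool = True,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> CMSModel:
    """Train a fixation-specific CMS classifier.

    ``alpha`` defaults to 0.7 for FF references and 0.8 for FFPE.  When
    ``lambda_grid`` is None, a glmnet-style descending grid is derived from
    the data; lambda is then selected by stratified ``cv_folds``-fold CV
    minimizing weighted misclassification error (ties toward the larger
    lambda).  Passing a single-element grid skips CV.
    """
    fixation = reference.fixation
    if alpha is None:
        alpha = DEFAULT_ALPHA[fixation]
    if not 0.0 <= alpha <= 1.0:
        raise CmskitError("alpha must lie in [0, 1]")
    if cv_folds < 3:
        raise CmskitError("cv_folds must be >= 3")
    panel = reference.panel
    Xsub = train.X.subset_genes(panel.genes)
    X = Xsub.values.T  # samples x genes
    y = _encode_labels(train.y.labels)
    counts = np.bincount(y, minlength=4)
    absent = [CMS_CLASSES[k] for k in range(4) if counts[k] < 2]
    if absent:
        raise CmskitError(
            f"need >= 2 training samples of every class; short: {', '.join(absent)}"
        )
    w = train.weights

    if standardize:
        Xs, mean, sd = _weighted_standardize(X, w)
    else:
        Xs, mean, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])

    Y = np.eye(4)[y]
    if lambda_grid is None:
        lambdas = _make_lambda_grid(Xs, Y, w, alpha, n_lambda)
    else:
        lambdas = np.asarray(lambda_grid, dtype=float)
        if lambdas.ndim != 1 or len(lambdas) == 0:
            raise CmskitError("lambda_grid must be a nonempty vector")
        if np.any(lambdas < 0):
            raise CmskitError("lambda values must be nonnegative")
        if len(lambdas) > 1 and np.any(np.diff(lambdas) > 0):
            raise CmskitError("lambda_grid must be descending")

    cv_errors = cv_deviances = None
    if len(lambdas) > 1:
        cv_errors, cv_deviances = _cross_validate(
            Xs, y, w, alpha, lambdas, cv_folds, seed, tol, max_iter
        )
        best = _select_lambda(cv_errors, cv_deviances)
    else:
        best = 0

    coefs, intercepts = _fit_path(Xs, y, w, alpha, lambdas, seed, tol, max_iter)
    nonzero_path = [int(np.count_nonzero(np.abs(c) > NONZERO_TOL)) for c in coefs]
    coef_std = coefs[best]  # (4, p)
    inter_std = intercepts[best]  # (4,)

    # back-transform to the input scale: b = b_std / sd, b0 = b0_std - b_std . (mean/sd)
    coef_orig = coef_std / sd[None, :]
    inter_orig = inter_std - coef_std @ (mean / sd)

    meta = {
        "seed": int(seed),
        "cv_folds": int(cv_folds),
        "alpha": float(alpha),
        "standardize": bool(standardize),
        "lambda_grid": [float(v) for v in lambdas],
        "cv_errors": None if cv_errors is None else [float(v) for v in cv_errors],
        "cv_deviances": None
        if cv_deviances is None
        else [float(v) for v in cv_deviances],
        "nonzero_path": nonzero_path,
        "weight_scheme": {
            "nanostring": float(
                w[[t == "nanostring" for t in train.source]].mean()
                if "nanostring" in train.source
                else 1.0
            ),
            "cotraining": 1.0,
        },
        "n_train": int(len(y)),
    }
    return CMSModel(
        panel=panel,
        fixation=fixation,
        alpha=float(alpha),
        lambda_=float(lambdas[best]),
        intercepts=inter_orig,
        coefficients=coef_orig.T,
        reference=reference,
        training_meta=meta,
    )


# ---------------------------------------------------------------------------
# prediction


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max())
    return e / e.sum()


def predict_proba(
    model: CMSModel,
    sample: np.ndarray,
    gene_ids=None,
    perform_log2: bool = False,
    pseudocount: float = 1.0,
    impute_missing: bool = False,
) -> np.ndarray:
    """CMS1-4 probabilities for one sample of raw panel expression.

    ``perform_log2=True`` applies log2(v + pseudocount) first (for raw
    counts); already log2-transformed input takes ``perform_log2=False`` and
    is only quantile-normalized.  ``gene_ids`` defaults to the model's panel
    order.
    """
    x = np.asarray(sample, dtype=float)
    if gene_ids is None:
        gene_ids = model.panel.genes
        if len(x) != len(gene_ids):
            raise CmskitError(
                f"sample length {len(x)} != panel size {len(gene_ids)}"
            )
    if perform_log2:
        if np.any(x < 0):
            raise CmskitError("perform_log2 expects nonnegative counts")
        if pseudocount <= 0:
            raise CmskitError("pseudocount must be positive")
        x = np.log2(x + pseudocount)
    xn = normalize_sample_vector(x, gene_ids, model.reference, impute_missing)
    eta = model.intercepts + xn @ model.coefficients
    return _softmax(eta)


def classify(probs, threshold: float = DEFAULT_THRESHOLD):
    """Turn a probability vector into (label, max_prob, confidence, tie flag).

    The label is the argmax class when max_prob >= threshold, else NA.
    Confidence is top1 - top2 probability.  Argmax ties are broken by fixed
    class order CMS1 < CMS2 < CMS3 < CMS4 and flagged.
    """
    if not 0.25 < threshold <= 1.0:
        raise CmskitError(
            f"threshold must lie in (0.25, 1], got {threshold} "
            "(below 0.25 every sample is trivially classified)"
        )
    p = np.asarray(probs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise CmskitError("probs must be a valid distribution over 4 classes")
    top = int(np.argmax(p))  # first index wins ties
    srt = np.sort(p)[::-1]
    max_prob = float(srt[0])
    confidence = float(srt[0] - srt[1])
    tied = bool(np.sum(p == p[top]) > 1)
    label = CMS_CLASSES[top] if max_prob >= threshold else "NA"
    return label, max_prob, confidence, tied


def predict_matrix(
    model: CMSModel,
    matrix: ExpressionMatrix,
    perform_log2: bool | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = 1.0,
    impute_missing: bool = False,
) -> list[Prediction]:
    """Predict every sample of an expression matrix.

    ``perform_log2`` defaults to True for counts matrices and False for log2.
    """
    if perform_log2 is None:
        perform_log2 = matrix.scale == "counts"
    if perform_log2 and matrix.scale == "log2":
        raise CmskitError("perform_log2=True on an already log2-scaled matrix")
    out = []
    for j, sid in enumerate(matrix.sample_ids):
        probs = predict_proba(
            model,
            matrix.values[:, j],
            gene_ids=matrix.gene_ids,
            perform_log2=perform_log2,
            pseudocount=pseudocount,
            impute_missing=impute_missing,
        )
        label, max_prob, confidence, tied = classify(probs, threshold)
        out.append(
            Prediction(
                sample_id=sid,
                probs=tuple(float(v) for v in probs),
                label=label,
                max_prob=max_prob,
                confidence=confidence,
                argmax_tied=tied,
            )
        )
    return out


def predictions_to_labels(predictions: list[Prediction]) -> LabelVector:
    return LabelVector(
        tuple(p.sample_id for p in predictions), tuple(p.label for p in predictions)
    )
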