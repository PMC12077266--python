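"""Selection-frequency gene-panel reduction.

The candidate panel is pruned by stability selection: many resampled
elastic-net fits (default 1000) each use a random stratified 80% of the
NanoString samples plus all co-training samples, and a gene counts as
selected when any of its four class coefficients is nonzero.  Genes with low
selection frequency are dropped, the procedure repeats on the reduced panel,
and it stops when the mean held-out accuracy (on the 20% of NanoString
samples left out of each fit) falls below the best round so far by more than
a tolerance — "no drop in accuracy".

Co-training samples are never held out: they stand in for fixed auxiliary
cohorts, and only the NanoString set is split.  Lambda is fixed per round by
one stratified CV on the full pool, then reused across the repetitions of
that round (re-running CV inside every repetition would dominate the cost
without changing which genes are stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CMS_CLASSES, CmskitError, GenePanel, LabelVector
from .model import (
    NONZERO_TOL,
    TrainingSet,
    _encode_labels,
    _fit_path,
    _make_lambda_grid,
    _predict_labels,
    _weighted_standardize,
)


@dataclass
class SelectionRound:
    """One batch of resampled fits on a fixed panel."""

    panel_in: GenePanel
    n_reps: int
    train_frac: float
    frequencies: np.ndarray  # per panel gene, in [0, 1]
    mean_test_accuracy: float
    seed: int
    lambda_: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.panel_in):
            raise CmskitError("frequency vector length != panel size")
        if not 0.0 <= self.mean_test_accuracy <= 1.0:
            raise CmskitError("accuracy out of [0, 1]")


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    """Per-class random split; every class keeps >= 1 training sample and, when
    it has >= 2 members, >= 1 held-out sample."""
    train_idx, test_idx = [], []
    for k in range(4):
        members = np.flatnonzero(y == k)
        if len(members) == 0:
            continue
        members = rng.permutation(members)
        n_train = int(round(train_frac * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1) if len(members) > 1 else 1
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return np.asarray(sorted(train_idx)), np.asarray(sorted(test_idx))


def selection_round(
    nanostring: TrainingSet,
    cotraining: TrainingSet | None,
    panel: GenePanel,
    n_reps: int = 1000,
    train_frac: float = 0.8,
    alpha: float = 0.7,
    seed: int = 0,
    cv_folds: int = 10,
    tol: float = 1e-3,
    max_iter: int = 1000,
) -> SelectionRound:
    """Run ``n_reps`` resampled elastic-net fits and tally selection frequency.

    Each repetition draws a stratified ``train_frac`` split of the NanoString
    samples; the training pool is NanoString-train plus all co-training
    samples with their stored weights, and accuracy is measured on the
    held-out NanoString samples by argmax class.
    """
    if not 0.0 < train_frac < 1.0:
        raise CmskitError("train_frac must lie in (0, 1)")
    if n_reps < 1:
        raise CmskitError("n_reps must be >= 1")

    Xn = nanostring.X.subset_genes(panel.genes).values.T
    yn = _encode_labels(nanostring.y.labels)
    wn = nanostring.weights
    if cotraining is not None and cotraining.X.n_samples > 0:
        Xc = cotraining.X.subset_genes(panel.genes).values.T
        yc = _encode_labels(cotraining.y.labels)
        wc = cotraining.weights
    else:
        Xc = np.empty((0, len(panel)))
        yc = np.empty(0, dtype=int)
        wc = np.empty(0)

    # fix lambda for the round: one stratified CV on the full pool
    X_full = np.vstack([Xn, Xc])
    y_full = np.concatenate([yn, yc])
    w_full = np.concatenate([wn, wc])
    ref_model_lambda = _pick_lambda(
        X_full, y_full, w_full, alpha, seed, cv_folds, tol, max_iter
    )

    rng = np.random.default_rng(seed)
    selected = np.zeros(len(panel))
    accuracies = np.empty(n_reps)
    for r in range(n_reps):
        tr, te = _stratified_split(yn, train_frac, rng)
        X = np.vstack([Xn[tr], Xc])
        y = np.concatenate([yn[tr], yc])
        w = np.concatenate([wn[tr], wc])
        Xs, mean, sd = _weighted_standardize(X, w)
        coefs, intercepts = _fit_path(
            Xs,
            y,
            w,
            alpha,
            np.asarray([ref_model_lambda]),
            seed=int(rng.integers(2**31 - 1)),
            tol=tol,
            max_iter=max_iter,
        )
        coef, inter = coefs[0], intercepts[0]
        selected += np.any(np.abs(coef) > NONZERO_TOL, axis=0)
        Xte_s = (Xn[te] - mean) / sd
        pred = _predict_labels(Xte_s, coef, inter)
        accuracies[r] = float(np.mean(pred == yn[te])) if len(te) else np.nan
    return SelectionRound(
        panel_in=panel,
        n_reps=n_reps,
        train_frac=train_frac,
        frequencies=selected / n_reps,
        mean_test_accuracy=float(np.nanmean(accuracies)),
        seed=seed,
        lambda_=ref_model_lambda,
    )


def _pick_lambda(X, y, w, alpha, seed, cv_folds, tol, max_iter) -> float:
    from .model import _cross_validate, _select_lambda

    Xs, _, _ = _weighted_standardize(X, w)
    Y = np.eye(4)[y]
    lambdas = _make_lambda_grid(Xs, Y, w, alpha, n_lambda=30)
    err, dev = _cross_validate(Xs, y, w, alpha, lambdas, cv_folds, seed, tol, max_iter)
    return float(lambdas[_select_lambda(err, dev)])


def iterative_reduction(
    initial_panel: GenePanel,
    nanostring: TrainingSet,
    cotraining: TrainingSet | None,
    freq_cutoff: float = 0.5,
    accuracy_tol: float = 0.01,
    max_rounds: int = 10,
    n_reps: int = 1000,
    train_frac: float = 0.8,
    alpha: float = 0.7,
    seed: int = 0,
    **round_kwargs,
) -> tuple[GenePanel, list[SelectionRound]]:
    """Iteratively prune low-frequency genes until accuracy drops.

    Each round tallies selection frequencies on the current panel and prunes
    genes below ``freq_cutoff``.  When a round's mean held-out accuracy falls
    more than ``accuracy_tol`` below the best accuracy observed so far, the
    panel that entered that round is discarded and the PREVIOUS panel is
    returned.  Stops too when no gene is prunable or after ``max_rounds``.
    The audit trail records every round.
    """
    if not 0.0 <= freq_cutoff <= 1.0:
        raise CmskitError("freq_cutoff must lie in [0, 1]")
    if len(initial_panel) < 2:
        raise CmskitError("initial panel must hold >= 2 genes")
    if max_rounds < 1:
        raise CmskitError("max_rounds must be >= 1")

    trail: list[SelectionRound] = []
    panel = initial_panel
    previous = initial_panel
    best_acc = -np.inf
    for rnd in range(max_rounds):
        result = selection_round(
            nanostring,
            cotraining,
            panel,
            n_reps=n_reps,
            train_frac=train_frac,
            alpha=alpha,
            seed=seed + rnd,
            **round_kwargs,
        )
        trail.append(result)
        if result.mean_test_accuracy < best_acc - accuracy_tol:
            return previous, trail
        best_acc = max(best_acc, result.mean_test_accuracy)
        keep = [
            g
            for g, f in zip(panel.genes, result.frequencies)
            if f >= freq_cutoff
        ]
        if len(keep) == len(panel) or len(keep) < 2:
            return panel, trail
        previous = panel
        panel = GenePanel(tuple(keep), panel.fixation)
    return panel, trail
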