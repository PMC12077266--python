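"""Fixation-specific single-sample reference-quantile normalization.

Every sample — whether a co-training profile from RNA-seq/microarray or a new
sample at classification time — is aligned to a fixed target distribution
derived from fixation-matched NanoString reference profiles: the value at
ascending rank r is replaced by the r-th target quantile.  Ranks are computed
within the sample only, so the operation is single-sample, rank-preserving,
idempotent and invariant to any monotone per-sample distortion (in particular
library-size/location shifts) — which is why no mean or median centering is
applied at any point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CmskitError, ExpressionMatrix, GenePanel


@dataclass
class ReferenceDistribution:
    """Target quantiles anchoring normalization for one fixation type.

    ``target_quantiles[r]`` is the mean (or median, see ``build_reference``)
    across reference samples of each sample's r-th smallest log2 value over
    the panel genes — the standard quantile-normalization target.
    """

    fixation: str
    panel: GenePanel
    target_quantiles: np.ndarray
    n_reference_samples: int

    def __post_init__(self) -> None:
        self.target_quantiles = np.asarray(self.target_quantiles, dtype=float)
        if self.fixation not in ("FF", "FFPE"):
            raise CmskitError(f"reference fixation must be FF or FFPE, got {self.fixation!r}")
        if self.target_quantiles.ndim != 1:
            raise CmskitError("target_quantiles must be a vector")
        if len(self.target_quantiles) != len(self.panel):
            raise CmskitError(
                f"target_quantiles length {len(self.target_quantiles)} != "
                f"panel size {len(self.panel)}"
            )
        if not np.all(np.isfinite(self.target_quantiles)):
            raise CmskitError("target_quantiles must be finite")
        if np.any(np.diff(self.target_quantiles) < 0):
            raise CmskitError("target_quantiles must be sorted ascending")

    def export_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("rank\ttarget_value\n")
            for r, v in enumerate(self.target_quantiles):
                fh.write(f"{r}\t{v:.10g}\n")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(v + pseudocount) on a counts matrix; the result is tagged log2."""
    if pseudocount <= 0:
        raise CmskitError(f"pseudocount must be positive, got {pseudocount}")
    if matrix.scale != "counts":
        raise CmskitError(
            "log2_transform expects a counts matrix; data already log2-transformed "
            "should take the perform_log2=False path"
        )
    return ExpressionMatrix(
        matrix.gene_ids,
        matrix.sample_ids,
        np.log2(matrix.values + pseudocount),
        "log2",
    )


def build_reference(
    ref_profiles: ExpressionMatrix,
    panel: GenePanel,
    fixation: str,
    statistic: str = "mean",
) -> ReferenceDistribution:
    """Derive target quantiles from fixation-matched reference profiles.

    Each reference sample's panel values are sorted ascending; the target at
    rank r is the mean (default) or median across samples of the r-th order
    statistic.
    """
    if ref_profiles.scale != "log2":
        raise CmskitError("reference profiles must be on the log2 scale")
    if ref_profiles.n_samples < 2:
        raise CmskitError("need at least 2 reference samples")
    if statistic not in ("mean", "median"):
        raise CmskitError(f"unknown statistic {statistic!r}")
    sub = ref_profiles.subset_genes(panel.genes)
    sorted_cols = np.sort(sub.values, axis=0)
    agg = np.mean if statistic == "mean" else np.median
    targets = agg(sorted_cols, axis=1)
    return ReferenceDistribution(
        fixation=fixation,
        panel=panel,
        target_quantiles=targets,
        n_reference_samples=sub.n_samples,
    )


def quantile_normalize_sample(
    sample: np.ndarray,
    ref: ReferenceDistribution,
    tie_method: str = "mean",
) -> np.ndarray:
    """Replace each value by the target quantile at its within-sample rank.

    Ties receive the mean of the target quantiles over their tied rank span.
    Output order matches input gene (panel) order; no centering is applied.
    """
    if tie_method != "mean":
        raise CmskitError(f"unsupported tie_method {tie_method!r}")
    x = np.asarray(sample, dtype=float)
    targets = ref.target_quantiles
    if x.ndim != 1 or len(x) != len(targets):
        raise CmskitError(
            f"sample length {x.shape} does not match panel size {len(targets)}"
        )
    if not np.all(np.isfinite(x)):
        raise CmskitError("sample contains non-finite values")
    order = np.argsort(x, kind="stable")
    out = np.empty_like(x)
    # walk runs of equal values; each run gets the mean target over its span
    i = 0
    n = len(x)
    while i < n:
        j = i + 1
        v = x[order[i]]
        while j < n and x[order[j]] == v:
            j += 1
        if j - i == 1:
            out[order[i]] = targets[i]
        else:
            out[order[i:j]] = targets[i:j].mean()
        i = j
    return out


def align_cotraining(
    whole_tx: ExpressionMatrix, ref: ReferenceDistribution
) -> ExpressionMatrix:
    """Quantile-normalize every column of a whole-transcriptome matrix
    independently against the reference, after restricting to panel genes.

    This is the domain-adaptation step that lets RNA-seq/microarray cohorts
    co-train a NanoString-anchored model.
    """
    if whole_tx.scale != "log2":
        raise CmskitError("co-training data must be on the log2 scale")
    sub = whole_tx.subset_genes(ref.panel.genes)
    out = np.empty_like(sub.values)
    for j in range(sub.n_samples):
        out[:, j] = quantile_normalize_sample(sub.values[:, j], ref)
    return ExpressionMatrix(sub.gene_ids, sub.sample_ids, out, "log2")


def normalize_sample_vector(
    values: np.ndarray,
    gene_ids,
    ref: ReferenceDistribution,
    impute_missing: bool = False,
) -> np.ndarray:
    """Normalize one sample given as (values, gene_ids) against a reference.

    Genes absent from the sample are a hard error unless ``impute_missing`` is
    set, in which case present genes are normalized against target quantiles
    re-gridded to their count and missing genes receive the reference median
    target.  Silent imputation is opt-in because it can mask panel mismatches.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    panel = ref.panel.genes
    missing = [g for g in panel if g not in index]
    if missing and not impute_missing:
        raise CmskitError(f"genes missing from sample: {', '.join(missing)}")
    if not missing:
        vec = np.asarray([values[index[g]] for g in panel], dtype=float)
        return quantile_normalize_sample(vec, ref)
    present = [g for g in panel if g in index]
    vec = np.asarray([values[index[g]] for g in present], dtype=float)
    m = len(present)
    targets = ref.target_quantiles
    sub_targets = np.interp(
        np.linspace(0.0, len(targets) - 1.0, m), np.arange(len(targets)), targets
    )
    sub_ref = ReferenceDistribution(
        fixation=ref.fixation,
        panel=GenePanel(tuple(present), ref.panel.fixation),
        target_quantiles=sub_targets,
        n_reference_samples=ref.n_reference_samples,
    )
    norm = quantile_normalize_sample(vec, sub_ref)
    out = np.empty(len(panel), dtype=float)
    med = float(np.median(targets))
    pos = {g: i for i, g in enumerate(present)}
    for i, g in enumerate(panel):
        out[i] = norm[pos[g]] if g in pos else med
    return out
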