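"""Seeded synthetic multi-platform cohorts with known CMS labels.

The generator emulates the structure the classifier exploits in real data:
each subtype carries a disjoint block of marker genes expressed
``effect_size`` log2 units above baseline in samples of that subtype, on top
of gene-specific baselines and i.i.d. Gaussian noise on the log2 scale.
Cross-platform distribution shifts are emulated by per-sample affine or fixed
monotone-nonlinear distortions (which per-sample quantile normalization is
designed to remove), and FFPE degradation by extra noise.  A count-scale
variant (Poisson around 2^log2-mean) exercises the perform_log2 path.

Defaults follow the study design the package targets: a 134-gene candidate
panel with ~12 markers per subtype, a 2.0 log2 marker effect over a 1.0-sd
noise floor, and baselines spanning a realistic 4-12 log2 abundance range.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .io import (
    CMS_CLASSES,
    CmskitError,
    ExpressionMatrix,
    GenePanel,
    LabelVector,
    write_expression,
    write_labels,
    write_panel,
)


@dataclass
class SimulationConfig:
    n_per_class: tuple[int, int, int, int] = (100, 100, 100, 100)
    n_genes: int = 134
    n_informative_per_class: int = 12
    effect_size: float = 2.0  # log2 units added to a subtype's marker block
    noise_sd: float = 1.0  # i.i.d. Gaussian noise, log2 units
    baseline_range: tuple[float, float] = (4.0, 12.0)  # log2 abundance span
    overlap_per_class: int = 0  # markers shared with the next class (FUT8-like)
    platform_distortion: str = "none"  # none | affine | monotone-nonlinear
    fixation_noise_sd: float = 0.0  # extra noise emulating FFPE degradation
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        if len(self.n_per_class) != 4 or any(n < 0 for n in self.n_per_class):
            raise CmskitError("n_per_class must be 4 nonnegative counts")
        if self.n_genes <= 0 or self.n_informative_per_class < 0:
            raise CmskitError("gene counts must be positive")
        if self.n_informative_per_class * 4 > self.n_genes:
            raise CmskitError("informative blocks exceed n_genes")
        if self.noise_sd < 0 or self.fixation_noise_sd < 0:
            raise CmskitError("noise sds must be nonnegative")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise CmskitError("baseline_range must be (low, high)")
        if self.platform_distortion not in ("none", "affine", "monotone-nonlinear"):
            raise CmskitError(
                f"unknown platform_distortion {self.platform_distortion!r}"
            )
        if self.overlap_per_class < 0 or self.overlap_per_class > self.n_informative_per_class:
            raise CmskitError("overlap_per_class out of range")


def _gene_names(n: int) -> tuple[str, ...]:
    return tuple(f"G{i + 1:04d}" for i in range(n))


def simulate_cohort(config: SimulationConfig):
    """Draw one cohort; returns (ExpressionMatrix[log2], LabelVector, role map).

    The role map sends every gene to "noise" or to the class(es) it marks,
    e.g. "CMS2" or "CMS1+CMS2" for overlapping markers.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    n_total = sum(config.n_per_class)
    labels = []
    for k, n in enumerate(config.n_per_class):
        labels.extend([CMS_CLASSES[k]] * n)
    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n_total))

    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)
    # disjoint marker blocks at the front of the gene list, plus optional
    # overlap: the last `overlap_per_class` markers of class k also mark k+1
    block = config.n_informative_per_class
    roles: dict[str, set[str]] = {g: set() for g in genes}
    effect = np.zeros((config.n_genes, 4))
    for k in range(4):
        idx = np.arange(k * block, (k + 1) * block)
        effect[idx, k] = config.effect_size
        for i in idx:
            roles[genes[i]].add(CMS_CLASSES[k])
        if config.overlap_per_class and k < 3:
            shared = idx[block - config.overlap_per_class :]
            effect[shared, k + 1] = config.effect_size
            for i in shared:
                roles[genes[i]].add(CMS_CLASSES[k + 1])

    y = np.asarray([CMS_CLASSES.index(l) for l in labels], dtype=int)
    mean = baselines[:, None] + effect[:, y]
    total_sd = float(np.hypot(config.noise_sd, config.fixation_noise_sd))
    values = mean + rng.normal(0.0, total_sd, size=mean.shape) if total_sd > 0 else mean

    matrix = ExpressionMatrix(genes, sample_ids, np.asarray(values, dtype=float), "log2")
    if config.platform_distortion != "none":
        matrix = apply_platform_shift(
            matrix, config.platform_distortion, seed=config.seed + 1
        )
    label_vec = LabelVector(sample_ids, tuple(labels))
    role_map = {
        g: ("+".join(sorted(r)) if r else "noise") for g, r in roles.items()
    }
    return matrix, label_vec, role_map


def simulate_count_cohort(config: SimulationConfig):
    """Count-scale variant: Poisson draws around 2^log2-mean, for exercising
    the perform_log2=True path."""
    matrix, labels, roles = simulate_cohort(config)
    rng = np.random.default_rng(config.seed + 7)
    counts = rng.poisson(np.power(2.0, matrix.values)).astype(float)
    return (
        ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, counts, "counts"),
        labels,
        roles,
    )


DEFAULT_AFFINE = {"slope_range": (0.7, 1.3), "intercept_range": (-2.0, 2.0)}
# fixed strictly increasing smooth map emulating a platform with a much
# narrower dynamic range around a higher offset (hybridization-style
# saturation): values above the knot are compressed to slope - bend
DEFAULT_NONLINEAR = {"intercept": 6.0, "slope": 1.0, "bend": 0.95, "knot": 4.0}


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def apply_platform_shift(
    matrix: ExpressionMatrix,
    kind: str,
    params: dict | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Distort a log2 matrix the way a platform change would.

    ``affine`` draws a per-sample slope/intercept from the stated ranges and
    maps x -> a*x + b; ``monotone-nonlinear`` applies the fixed strictly
    increasing saturating map x -> intercept + slope*x - bend*softplus(x -
    knot) elementwise (requires bend < slope so the derivative stays
    positive).  Either way the rank order within each sample is preserved.
    """
    if matrix.scale != "log2":
        raise CmskitError("platform shifts operate on log2 matrices")
    out = matrix.values.copy()
    if kind == "affine":
        p = {**DEFAULT_AFFINE, **(params or {})}
        lo, hi = p["slope_range"]
        if lo <= 0:
            raise CmskitError("affine slopes must be positive (monotone)")
        rng = np.random.default_rng(seed)
        a = rng.uniform(lo, hi, size=matrix.n_samples)
        b = rng.uniform(*p["intercept_range"], size=matrix.n_samples)
        out = out * a[None, :] + b[None, :]
    elif kind == "monotone-nonlinear":
        p = {**DEFAULT_NONLINEAR, **(params or {})}
        if p["slope"] <= 0 or not 0 <= p["bend"] < p["slope"]:
            raise CmskitError("nonlinear map must be strictly increasing")
        out = p["intercept"] + p["slope"] * out - p["bend"] * _softplus(out - p["knot"])
    else:
        raise CmskitError(f"unknown shift kind {kind!r}")
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, out, "log2")


def export_fixture(cohort, directory: str) -> dict[str, str]:
    """Write a cohort (matrix, labels, role map) as a TSV fixture directory.

    Emits expression.tsv, labels.tsv, panel.txt and ground_truth.tsv; all
    round-trip through the io module and are byte-identical across runs with
    the same seed.
    """
    matrix, labels, roles = cohort
    if matrix.n_samples == 0 or matrix.n_genes == 0:
        raise CmskitError("refusing to export an empty cohort")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "labels": os.path.join(directory, "labels.tsv"),
        "panel": os.path.join(directory, "panel.txt"),
        "ground_truth": os.path.join(directory, "ground_truth.tsv"),
    }
    write_expression(matrix, paths["expression"])
    write_labels(labels, paths["labels"])
    write_panel(GenePanel(matrix.gene_ids, "union"), paths["panel"])
    with open(paths["ground_truth"], "w") as fh:
        fh.write("gene_id\trole\n")
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{roles[g]}\n")
    return paths
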