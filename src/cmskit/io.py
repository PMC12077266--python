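"""Plain-text readers and writers for expression matrices, panels, labels,
models and predictions.

All interchange formats are versionable text: expression matrices are TSV/CSV
with genes in rows and samples in columns, labels are two-column TSV, panels
are one gene per line, models are a single self-describing JSON document that
embeds its reference distribution, so prediction needs no side files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CMS_CLASSES: tuple[str, str, str, str] = ("CMS1", "CMS2", "CMS3", "CMS4")
LABEL_SET = CMS_CLASSES + ("NA",)

MODEL_FORMAT_VERSION = "cmskit-model-1"


class CmskitError(ValueError):
    """Base class for validation and format errors raised by this package."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise CmskitError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag.

    ``scale`` is ``"counts"`` (raw, nonnegative) or ``"log2"``.  Gene and
    sample identifiers are opaque strings, kept in parse order.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("counts", "log2"):
            raise CmskitError(f"unknown scale {self.scale!r}")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CmskitError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise CmskitError("expression values must be finite")
        if self.scale == "counts" and np.any(self.values < 0):
            raise CmskitError("counts matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order; missing genes are a hard error."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise CmskitError(f"genes missing from matrix: {', '.join(missing)}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            tuple(genes), self.sample_ids, self.values[rows, :], self.scale
        )

    def sample(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise CmskitError(f"unknown sample id {sample_id!r}") from None
        return self.values[:, j]


@dataclass(frozen=True)
class GenePanel:
    """Ordered, duplicate-free gene list tagged with the fixation type it serves."""

    genes: tuple[str, ...]
    fixation: str = "union"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        if not self.genes:
            raise CmskitError("gene panel must be nonempty")
        _check_unique(self.genes, "panel genes")
        if self.fixation not in ("FF", "FFPE", "union"):
            raise CmskitError(f"unknown fixation {self.fixation!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class LabelVector:
    """Per-sample CMS labels; ``NA`` marks unclassified/unavailable."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.labels = tuple(str(l) for l in self.labels)
        _check_unique(self.sample_ids, "sample ids")
        if len(self.sample_ids) != len(self.labels):
            raise CmskitError("sample_ids and labels differ in length")
        bad = sorted({l for l in self.labels if l not in LABEL_SET})
        if bad:
            raise CmskitError(
                f"labels outside {{CMS1..CMS4, NA}}: {', '.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(list(self.labels), index=list(self.sample_ids))


# ---------------------------------------------------------------------------
# expression matrices


def _detect_sep(path: str) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise CmskitError(f"{path}: cannot detect delimiter (expected tab or comma)")


def read_expression(path: str, scale: str) -> ExpressionMatrix:
    """Read a delimited genes-x-samples table.

    First column holds gene identifiers, header row holds sample identifiers.
    The delimiter is auto-detected (tab or comma).  Row/column order is
    preserved exactly as parsed.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, f"gene ids in {path}")
    _check_unique(sample_ids, f"sample ids in {path}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise CmskitError(
                    f"{path}: non-numeric value {raw[i, j]!r} at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values, scale)


def write_expression(matrix: ExpressionMatrix, path: str, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# panels and labels


def read_panel(path: str, fixation: str = "union") -> GenePanel:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return GenePanel(tuple(genes), fixation)


def write_panel(panel: GenePanel, path: str) -> None:
    with open(path, "w") as fh:
        for g in panel.genes:
            fh.write(g + "\n")


def read_labels(path: str) -> LabelVector:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise CmskitError(f"{path}: expected two columns (sample_id, label)")
    return LabelVector(
        tuple(df.iloc[:, 0].astype(str)), tuple(df.iloc[:, 1].astype(str))
    )


def write_labels(labels: LabelVector, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s, l in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}\t{l}\n")


# ---------------------------------------------------------------------------
# predictions


def write_predictions(predictions: Sequence, path: str) -> None:
    """Write prediction rows with >= 6 significant digits on probabilities.

    Columns: sample_id, prob_CMS1..prob_CMS4, label, max_prob, confidence.
    """
    predictions = list(predictions)
    if not predictions:
        raise CmskitError("cannot write an empty prediction list")
    cols = ["sample_id"] + [f"prob_{c}" for c in CMS_CLASSES] + [
        "label",
        "max_prob",
        "confidence",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in predictions:
            probs = "\t".join(f"{v:.9g}" for v in p.probs)
            fh.write(
                f"{p.sample_id}\t{probs}\t{p.label}\t{p.max_prob:.9g}\t"
                f"{p.confidence:.9g}\n"
            )


def read_predictions(path: str) -> list:
    from .model import Prediction  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", header=0, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        probs = tuple(float(row[f"prob_{c}"]) for c in CMS_CLASSES)
        out.append(
            Prediction(
                sample_id=str(row["sample_id"]),
                probs=probs,
                label=str(row["label"]),
                max_prob=float(row["max_prob"]),
                confidence=float(row["confidence"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# model serialization


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, indent=1)


def save_model(model, path: str) -> None:
    """Serialize a CMSModel to a single self-describing JSON file.

    The file embeds the panel, fixation tag, hyperparameters, intercepts,
    coefficients and the reference distribution; ``load_model(save_model(m))``
    reproduces predictions bit-identically (floats are written with full
    ``repr`` precision).
    """
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "panel": {"genes": list(model.panel.genes), "fixation": model.panel.fixation},
        "fixation": model.fixation,
        "alpha": float(model.alpha),
        "lambda": float(model.lambda_),
        "intercepts": [float(v) for v in model.intercepts],
        "coefficients": [[float(v) for v in row] for row in model.coefficients],
        "reference": {
            "fixation": model.reference.fixation,
            "target_quantiles": [float(v) for v in model.reference.target_quantiles],
            "n_reference_samples": int(model.reference.n_reference_samples),
        },
        "training_meta": model.training_meta,
    }
    with open(path, "w") as fh:
        fh.write(_canonical_json(doc))
        fh.write("\n")


def load_model(path: str):
    from .model import CMSModel
    from .normalize import ReferenceDistribution

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise CmskitError(f"{path}: corrupt or truncated model file ({e})") from None
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise CmskitError(
            f"{path}: model format version {version!r} does not match "
            f"expected {MODEL_FORMAT_VERSION!r}"
        )
    panel = GenePanel(tuple(doc["panel"]["genes"]), doc["panel"]["fixation"])
    reference = ReferenceDistribution(
        fixation=doc["reference"]["fixation"],
        panel=panel,
        target_quantiles=np.asarray(doc["reference"]["target_quantiles"], dtype=float),
        n_reference_samples=int(doc["reference"]["n_reference_samples"]),
    )
    return CMSModel(
        panel=panel,
        fixation=doc["fixation"],
        alpha=float(doc["alpha"]),
        lambda_=float(doc["lambda"]),
        intercepts=np.asarray(doc["intercepts"], dtype=float),
        coefficients=np.asarray(doc["coefficients"], dtype=float),
        reference=reference,
        training_meta=doc.get("training_meta", {}),
    )
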