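"""Reading, writing, centering and QC of expression compendia.

Expression matrices are genes × samples log-TPM tables.  On disk everything
is TSV: first column gene identifiers, header row sample identifiers,
floats at 6 significant digits for reproducible diffs.  Centering subtracts
each gene's mean over the reference-condition samples, so reference samples
have expression zero and every other value reads as a log fold change from
the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

__all__ = [
    "ExpressionMatrix",
    "QcReport",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "design_from_metadata",
    "center_to_reference",
    "qc_replicate_correlation",
    "qc_clustering_outliers",
]


@dataclass
class ExpressionMatrix:
    """A genes × samples log-TPM matrix with a centering flag.

    Gene and sample identifiers must be unique and values complete; both are
    enforced on construction so downstream stages can assume them.
    """

    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class QcReport:
    """Replicate-correlation and clustering-outlier QC results."""

    replicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    failing_samples: list[str] = field(default_factory=list)
    clustering_outliers: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_a": a,
                "sample_b": b,
                "pearson_r": r,
                "pass": (a not in self.failing_samples and b not in self.failing_samples),
            }
            for a, b, r in self.replicate_pairs
        ]
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "pearson_r", "pass"])


def read_expression_matrix(path: str | Path, centered: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (gene ids first column, sample header)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample identifiers in {path}: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(df, centered=centered)


def write_expression_matrix(X: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = X.data if isinstance(X, ExpressionMatrix) else X
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    required = {"condition", "replicate_group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def design_from_metadata(meta: pd.DataFrame, reference_condition: str):
    """Build a StudyDesign from a metadata table (sample_id-indexed)."""
    from .synthetic import StudyDesign

    groups: dict[str, list[str]] = {}
    for s, g in meta["replicate_group"].items():
        groups.setdefault(str(g), []).append(str(s))
    return StudyDesign(
        samples=[str(s) for s in meta.index],
        condition_of={str(s): str(c) for s, c in meta["condition"].items()},
        replicate_groups=list(groups.values()),
        reference_condition=reference_condition,
    )


def center_to_reference(
    X: ExpressionMatrix, reference_samples: list[str]
) -> ExpressionMatrix:
    """Subtract each gene's mean over the reference samples.

    Idempotent for a fixed reference set; the reference columns have
    per-gene mean exactly zero afterwards.
    """
    if not reference_samples:
        raise ValueError("reference sample set is empty")
    unknown = [s for s in reference_samples if s not in X.data.columns]
    if unknown:
        raise ValueError(f"unknown reference samples: {unknown}")
    ref_mean = X.data[list(reference_samples)].mean(axis=1)
    return ExpressionMatrix(X.data.sub(ref_mean, axis=0), centered=True)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def qc_replicate_correlation(X: ExpressionMatrix, design, min_r: float = 0.95) -> QcReport:
    """Flag samples whose within-replicate-group Pearson r falls below `min_r`.

    Genes with zero variance across all samples are excluded from the
    correlation computation (they carry no information and would not change
    r anyway unless they zero a sample's variance).  A sample with zero
    variance over the remaining genes has undefined r and fails with a note.
    """
    report = QcReport()
    values = X.data
    keep = values.std(axis=1) > 0
    if keep.sum() >= 2:  # a fully constant matrix would leave nothing
        values = values.loc[keep]
    failing: set[str] = set()
    for grp in design.replicate_groups:
        if len(grp) < 2:
            report.notes.append(f"replicate group {grp} has size 1; skipped")
            logger.info("replicate group %s has size 1; skipped", grp)
            continue
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                a, b = grp[i], grp[j]
                r = _pearson(values[a].to_numpy(), values[b].to_numpy())
                if np.isnan(r):
                    report.notes.append(f"undefined correlation for pair ({a}, {b})")
                    failing.update((a, b))
                    report.replicate_pairs.append((a, b, np.nan))
                    continue
                report.replicate_pairs.append((a, b, r))
                if r < min_r:
                    failing.update((a, b))
    report.failing_samples = sorted(failing)
    return report


def qc_clustering_outliers(X: ExpressionMatrix, cut: float = 0.3) -> list[str]:
    """Flag samples isolated by average-linkage clustering on 1 − Pearson r.

    The dendrogram is cut at height `cut`; samples falling outside the
    largest resulting cluster are reported as outliers.
    """
    n = X.shape[1]
    if n < 3:
        raise ValueError("clustering QC requires at least 3 samples")
    corr = np.corrcoef(X.values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce symmetry against fp noise
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    main = np.bincount(labels).argmax()
    return [s for s, lab in zip(X.sample_ids, labels) if lab != main]
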