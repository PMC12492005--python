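"""Robust independent-component inference of iModulons.

The decomposition X ≈ M·A is built in three stages: (1) many FastICA runs
at a given dimensionality, each returning gene-space source vectors;
(2) consensus clustering of all pooled source vectors with DBSCAN under the
sign-invariant distance d(u, v) = 1 − |Pearson(u, v)|, keeping clusters
supported by more than half of the runs; (3) dimensionality selection —
the largest candidate dimensionality whose robust components are not
dominated by single-gene components.  The final M collects the cluster
centroids (unit L2, largest-|weight| entry positive) and A is recovered by
least squares, A = M⁺·X.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IcaConfig",
    "ComponentPool",
    "RobustComponent",
    "Decomposition",
    "run_ica_once",
    "pool_and_cluster",
    "count_single_gene_components",
    "select_dimensionality",
    "decompose",
]


@dataclass
class IcaConfig:
    """Knobs for the robust-ICA procedure.

    n_runs=100 and min_support of "more than half the runs" follow standard
    consensus-ICA practice for expression compendia; eps is the DBSCAN
    radius on the 1 − |Pearson| distance.
    """

    n_runs: int = 100
    dims: list[int] | None = None          # candidate dimensionalities; None → fixed_dim
    fixed_dim: int | None = None
    eps: float = 0.1
    min_support: int | None = None         # None → ceil(n_runs/2) + 1
    base_seed: int = 0
    single_gene_fraction_max: float = 0.10
    k2_threshold: float = 550.0
    max_iter: int = 1000
    tol: float = 1e-6
    n_jobs: int = 1

    def resolved_min_support(self) -> int:
        if self.min_support is not None:
            return self.min_support
        return int(np.ceil(self.n_runs / 2)) + 1


@dataclass
class ComponentPool:
    """Gene-weight matrices from repeated ICA runs at one dimensionality."""

    runs: list[np.ndarray]
    run_seeds: list[int]
    dim: int

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty component pool")
        shapes = {r.shape for r in self.runs}
        if len(shapes) != 1 or next(iter(shapes))[1] != self.dim:
            raise ValueError(f"inconsistent run shapes {shapes} for dim {self.dim}")


@dataclass
class RobustComponent:
    weights: np.ndarray          # unit L2, largest-|weight| entry positive
    support_count: int           # number of distinct runs contributing
    orientation: int = 1         # sign applied to the raw centroid


@dataclass
class Decomposition:
    M: pd.DataFrame              # genes × iModulons
    A: pd.DataFrame              # iModulons × samples
    dim_selected: int
    diagnostics: pd.DataFrame    # per-dim robust / single-gene counts
    config: IcaConfig
    support_counts: list[int] = field(default_factory=list)


def _orient(w: np.ndarray) -> tuple[np.ndarray, int]:
    """Flip so the largest-|weight| entry is positive; return (vector, sign)."""
    sign = 1 if w[np.argmax(np.abs(w))] >= 0 else -1
    return sign * w, sign


def run_ica_once(X: ExpressionMatrix, dim: int, seed: int,
                 max_iter: int = 1000, tol: float = 1e-6) -> np.ndarray:
    """One FastICA run: gene-space sources from a centered compendium.

    Genes are treated as observations and samples as mixed signals, so the
    recovered sources are gene-weight vectors whose non-Gaussianity (a few
    heavy member genes over a normal background) drives the separation.
    Whitening is an explicit SVD projection onto the top `dim` principal
    directions — no additional mean removal, so a noiseless rank-`dim`
    compendium is decomposed within its exact column span.  Columns are
    scaled to unit L2 and oriented with their largest-|weight| entry
    positive.
    """
    if not X.centered:
        raise ValueError("expression matrix must be centered before ICA")
    n_genes, n_samples = X.shape
    if dim >= min(n_genes, n_samples):
        raise ValueError(
            f"dim={dim} must be < min(genes, samples) = {min(n_genes, n_samples)}"
        )
    U, _, _ = np.linalg.svd(X.values, full_matrices=False)
    Xw = U[:, :dim] * np.sqrt(n_genes)     # unit-variance whitened coordinates
    ica = FastICA(
        whiten=False,
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed),
    )
    S = ica.fit_transform(Xw)              # (genes, dim)
    S = S / np.linalg.norm(S, axis=0, keepdims=True)
    for j in range(dim):
        S[:, j], _ = _orient(S[:, j])
    return S


def pool_and_cluster(pool: ComponentPool, eps: float = 0.1,
                     min_support: int | None = None) -> list[RobustComponent]:
    """Consensus clustering of pooled ICA components.

    DBSCAN on the sign-invariant distance 1 − |Pearson| groups recurring
    components; a cluster becomes a RobustComponent when at least
    `min_support` distinct runs contribute to it (duplicated columns within
    one run count once).  The centroid is the mean of the sign-aligned
    members, renormalized to unit L2.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    n_runs = len(pool.runs)
    if min_support is None:
        min_support = int(np.ceil(n_runs / 2)) + 1

    cols = np.column_stack([r for r in pool.runs])       # (genes, n_runs*dim)
    run_of = np.repeat(np.arange(n_runs), pool.dim)

    centered = cols - cols.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    corr = np.abs(centered.T @ centered / (norms.T * norms))
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)

    labels = DBSCAN(eps=eps, min_samples=min_support, metric="precomputed").fit(
        dist
    ).labels_

    out: list[RobustComponent] = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        support = len(set(run_of[idx]))
        if support < min_support:
            continue
        ref = cols[:, idx[0]]
        aligned = np.empty((cols.shape[0], idx.size))
        for j, i in enumerate(idx):
            v = cols[:, i]
            aligned[:, j] = v if float(v @ ref) >= 0 else -v
        centroid = aligned.mean(axis=1)
        centroid /= np.linalg.norm(centroid)
        centroid, sign = _orient(centroid)
        out.append(RobustComponent(weights=centroid, support_count=support,
                                   orientation=sign))
    # deterministic order: by decreasing support, then by top-gene index
    out.sort(key=lambda c: (-c.support_count, int(np.argmax(np.abs(c.weights)))))
    return out


def count_single_gene_components(components: list[RobustComponent],
                                 k2_threshold: float = 550.0) -> int:
    """Number of robust components that fail to define a multi-gene module.

    A component whose membership thresholding yields at most one gene — a
    single outlier gene, or no outliers at all (a noise direction) — does
    not represent a co-regulated gene set; too high an ICA dimensionality
    produces increasingly many of these.
    """
    from .membership import compute_membership

    n = 0
    for i, comp in enumerate(components):
        im = compute_membership(
            pd.Series(comp.weights, name=f"c{i}"), k2_threshold=k2_threshold
        )
        if len(im.members) <= 1:
            n += 1
    return n


def _robust_components_at_dim(X: ExpressionMatrix, dim: int,
                              cfg: IcaConfig) -> list[RobustComponent]:
    seeds = [cfg.base_seed + i for i in range(cfg.n_runs)]
    runs = Parallel(n_jobs=cfg.n_jobs)(
        delayed(run_ica_once)(X, dim, s, cfg.max_iter, cfg.tol) for s in seeds
    )
    pool = ComponentPool(runs=list(runs), run_seeds=seeds, dim=dim)
    return pool_and_cluster(pool, eps=cfg.eps, min_support=cfg.resolved_min_support())


def select_dimensionality(
    X: ExpressionMatrix, dims: list[int], cfg: IcaConfig
) -> tuple[int, pd.DataFrame, dict[int, list[RobustComponent]], bool]:
    """Pick the largest dimensionality not dominated by single-gene components.

    Raising the ICA dimensionality splits dense components into finer ones
    until it starts shaving off single genes; the selected dim is the
    largest candidate whose single-gene fraction stays at or below
    `cfg.single_gene_fraction_max`.  Returns (dim, diagnostics table,
    per-dim robust components, warning flag).  If no candidate qualifies the
    smallest dim is returned with the warning flag set.
    """
    if not dims:
        raise ValueError("no candidate dimensionalities")
    rows = []
    comps_by_dim: dict[int, list[RobustComponent]] = {}
    for dim in sorted(dims):
        comps = _robust_components_at_dim(X, dim, cfg)
        n_single = count_single_gene_components(comps, cfg.k2_threshold)
        comps_by_dim[dim] = comps
        rows.append(
            {
                "dim": dim,
                "n_robust": len(comps),
                "n_single_gene": n_single,
                "single_gene_fraction": n_single / len(comps) if comps else np.nan,
            }
        )
        logger.info("dim=%d: %d robust components, %d single-gene", dim,
                    len(comps), n_single)
    diag = pd.DataFrame(rows)
    ok = diag[
        (diag["n_robust"] > 0)
        & (diag["single_gene_fraction"] <= cfg.single_gene_fraction_max)
    ]
    if len(ok):
        return int(ok["dim"].max()), diag, comps_by_dim, False
    logger.warning("no dimensionality met the single-gene criterion; "
                   "falling back to the smallest candidate")
    return int(min(dims)), diag, comps_by_dim, True


def decompose(X: ExpressionMatrix, cfg: IcaConfig | None = None) -> Decomposition:
    """Full robust-ICA decomposition of a centered compendium.

    Selects the dimensionality (unless `cfg.fixed_dim` is set), clusters the
    pooled runs into robust components forming M's columns, and recovers
    A = M⁺·X by least squares so that M·A is the best reconstruction in the
    Frobenius sense for the chosen M.
    """
    cfg = cfg or IcaConfig()
    if not X.centered:
        raise ValueError("expression matrix must be centered before decomposition")
    if not np.any(X.values):
        raise ValueError("degenerate input: expression matrix is identically zero")

    if cfg.fixed_dim is not None:
        dim = cfg.fixed_dim
        comps = _robust_components_at_dim(X, dim, cfg)
        n_single = count_single_gene_components(comps, cfg.k2_threshold)
        diag = pd.DataFrame(
            [{"dim": dim, "n_robust": len(comps), "n_single_gene": n_single,
              "single_gene_fraction": n_single / len(comps) if comps else np.nan}]
        )
    else:
        dims = cfg.dims if cfg.dims else [min(X.shape) // 2]
        dim, diag, comps_by_dim, _ = select_dimensionality(X, dims, cfg)
        comps = comps_by_dim[dim]

    if not comps:
        raise RuntimeError(f"no robust components found at dim={dim}")

    names = [f"IM{i + 1:02d}" for i in range(len(comps))]
    M = pd.DataFrame(
        np.column_stack([c.weights for c in comps]), index=X.gene_ids, columns=names
    )
    A = pd.DataFrame(
        np.linalg.pinv(M.to_numpy()) @ X.values, index=names, columns=X.sample_ids
    )
    return Decomposition(
        M=M, A=A, dim_selected=dim, diagnostics=diag, config=cfg,
        support_counts=[c.support_count for c in comps],
    )


def write_decomposition(dec: Decomposition, outdir: str | Path) -> None:
    """Write M.tsv, A.tsv, diagnostics.tsv and a JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dec.M.to_csv(outdir / "M.tsv", sep="\t", float_format="%.6g", index_label="gene_id")
    dec.A.to_csv(outdir / "A.tsv", sep="\t", float_format="%.6g",
                 index_label="imodulon")
    dec.diagnostics.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
    manifest = {
        "config": asdict(dec.config),
        "dim_selected": dec.dim_selected,
        "support_counts": dec.support_counts,
        "run_seeds": [dec.config.base_seed + i for i in range(dec.config.n_runs)],
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
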