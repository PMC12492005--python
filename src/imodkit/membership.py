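"""Gene membership of iModulons by iterative normality thresholding.

An iModulon's gene weights look like a handful of strongly weighted member
genes sitting on top of an approximately normal background.  Membership is
therefore decided by progressively removing the gene of largest remaining
|weight| and recomputing the D'Agostino–Pearson K² omnibus normality
statistic on what is left; once K² drops below the threshold (default 550)
the remainder is deemed background and the removed genes are the members.

The K² statistic is implemented here from the published closed forms
(D'Agostino's transformed skewness Z₁ and the Anscombe–Glynn transformed
kurtosis Z₂, with K² = Z₁² + Z₂² ~ χ²₂ under normality) because the
thresholding rule is defined directly on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IModulon",
    "EnrichmentResult",
    "dagostino_k2",
    "compute_membership",
    "enrich_against_trn",
]


@dataclass
class IModulon:
    """One component's member genes and thresholding diagnostics."""

    name: str
    weights: pd.Series                    # full signed weight vector (one M column)
    members: list                         # gene ids, in removal order
    weight_threshold: float | None        # smallest member |weight|; None if empty
    k2_at_stop: float
    degenerate: bool = False              # initial K² already below threshold
    regulator_annotation: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentResult:
    regulator: str
    overlap: int
    member_count: int
    regulon_size: int
    universe_size: int
    p_value: float
    q_value: float


def _skewness_z(g1: float, n: int) -> float:
    # D'Agostino (1970) transformed sample skewness
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (
        3.0 * (n * n + 27 * n - 70) * (n + 1) * (n + 3)
        / ((n - 2) * (n + 5) * (n + 7) * (n + 9))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    return delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))


def _kurtosis_z(b2: float, n: int) -> float:
    # Anscombe & Glynn (1983) transformed sample kurtosis (b2 = m4/m2^2)
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    x = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (
        2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2)
    )
    num = 1.0 - 2.0 / (9.0 * a)
    den = (1.0 - 2.0 / a) / (1.0 + x * math.sqrt(2.0 / (a - 4.0)))
    return (num - np.sign(den) * abs(den) ** (1.0 / 3.0)) / math.sqrt(2.0 / (9.0 * a))


def dagostino_k2(values: np.ndarray | pd.Series) -> float:
    """D'Agostino–Pearson K² omnibus normality statistic.

    K² = Z₁(skewness)² + Z₂(kurtosis)²; under normality K² ~ χ² with 2
    degrees of freedom.  Requires at least 20 values (the moment
    transformations are unreliable below) and nonzero variance.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 20:
        raise ValueError(f"K-squared needs at least 20 values, got {n}")
    m = v.mean()
    d = v - m
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("degenerate input: zero variance")
    g1 = np.mean(d**3) / m2**1.5
    b2 = np.mean(d**4) / m2**2
    z1 = _skewness_z(float(g1), n)
    z2 = _kurtosis_z(float(b2), n)
    return z1 * z1 + z2 * z2


def compute_membership(
    weights: pd.Series, k2_threshold: float = 550.0, name: str | None = None
) -> IModulon:
    """Threshold one M column into member genes by iterative outlier removal.

    The gene of largest remaining |weight| is removed one at a time (ties
    broken by gene order) and K² recomputed on the remainder; removal stops
    as soon as K² < `k2_threshold`.  The removed genes, in removal order,
    are the members, so every member |weight| is >= every non-member
    |weight|.  If the initial K² is already below threshold the component
    has no outliers: members is empty and the component is flagged
    degenerate.
    """
    weights = pd.Series(weights, dtype=float)
    name = name or str(weights.name) or "component"
    remaining = weights.copy()
    members: list[str] = []
    k2 = dagostino_k2(remaining.to_numpy())
    while k2 >= k2_threshold:
        # argmax of |weight| returns the first (gene-order) maximum on ties
        drop = remaining.abs().idxmax()
        members.append(drop)
        remaining = remaining.drop(drop)
        k2 = dagostino_k2(remaining.to_numpy())
    threshold = float(weights.loc[members].abs().min()) if members else None
    return IModulon(
        name=name,
        weights=weights,
        members=members,
        weight_threshold=threshold,
        k2_at_stop=float(k2),
        degenerate=not members,
    )


def enrich_against_trn(
    imodulon: IModulon,
    trn: dict[str, set[str]],
    universe: list[str],
) -> list[EnrichmentResult]:
    """Fisher-exact (hypergeometric upper-tail) enrichment vs known regulons.

    One 2×2 test per regulator on member × regulon within the gene
    universe; q-values by Benjamini–Hochberg across regulators; results
    sorted by p-value.  Regulon genes outside the universe are ignored.
    An empty member set yields an empty result list.
    """
    uni = set(universe)
    members = set(imodulon.members) & uni
    if set(imodulon.members) - uni:
        raise ValueError("iModulon members must be a subset of the universe")
    if not members:
        return []
    n_u, n_m = len(uni), len(members)
    rows = []
    for reg, genes in trn.items():
        regulon = set(genes) & uni
        if not regulon:
            continue
        overlap = len(members & regulon)
        p = float(hypergeom.sf(overlap - 1, n_u, len(regulon), n_m))
        rows.append((reg, overlap, len(regulon), min(p, 1.0)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            regulator=reg, overlap=ov, member_count=n_m, regulon_size=rs,
            universe_size=n_u, p_value=p, q_value=float(q),
        )
        for (reg, ov, rs, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.regulator))
    return results


def membership_table(imodulons: list[IModulon]) -> pd.DataFrame:
    """Two-column (imodulon, gene) long table of all member genes."""
    rows = [
        {"imodulon": im.name, "gene": g} for im in imodulons for g in im.members
    ]
    return pd.DataFrame(rows, columns=["imodulon", "gene"])


def read_trn(path) -> dict[str, set[str]]:
    """Read a two-column (regulator, gene) TSV into regulon sets."""
    df = pd.read_csv(path, sep="\t")
    if not {"regulator", "gene"} <= set(df.columns):
        raise ValueError("TRN file needs 'regulator' and 'gene' columns")
    out: dict[str, set[str]] = {}
    for reg, sub in df.groupby("regulator"):
        out[str(reg)] = set(map(str, sub["gene"]))
    return out
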