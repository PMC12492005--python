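"""Synthetic log-TPM compendia with planted ground truth.

Generates sparse gene-weight matrices (M), condition-structured activity
matrices (A) and noisy expression compendia X = M·A + ε with the statistical
structure that robust-ICA iModulon inference assumes: each component has a
small set of large-|weight| member genes standing out of a near-normal
background, samples come in biological-replicate pairs per condition, and
between-condition activity shifts are planted explicitly so that recovery,
membership and differential-activity calls can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "StudyDesign",
    "generate_truth",
    "generate_activities",
    "generate_paired_activities",
    "synthesize_compendium",
    "default_design",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic compendium.

    Attributes
    ----------
    true_M : (genes, k) array with unit-L2 columns.
    true_A : (k, samples) array or None until activities are generated.
    member_sets : list of arrays of member gene indices per component.
    noise_sigma : additive expression noise SD (log-TPM units).
    seed : RNG seed used for the gene-weight draw.
    """

    true_M: np.ndarray
    true_A: np.ndarray | None
    member_sets: list[np.ndarray]
    noise_sigma: float
    seed: int

    @property
    def n_genes(self) -> int:
        return self.true_M.shape[0]

    @property
    def n_components(self) -> int:
        return self.true_M.shape[1]

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]


@dataclass
class StudyDesign:
    """Sample layout: conditions, replicate groups, reference condition.

    Every sample belongs to exactly one replicate group and replicate groups
    are condition-homogeneous.  The reference condition defines expression
    zero after centering.
    """

    samples: list[str]
    condition_of: dict[str, str]
    replicate_groups: list[list[str]]
    reference_condition: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for grp in self.replicate_groups:
            if not grp:
                raise ValueError("empty replicate group")
            conds = {self.condition_of[s] for s in grp}
            if len(conds) != 1:
                raise ValueError(f"replicate group {grp} spans conditions {conds}")
            if seen & set(grp):
                raise ValueError("sample assigned to more than one replicate group")
            seen.update(grp)
        if seen != set(self.samples):
            raise ValueError("replicate groups must partition the sample set")
        if self.reference_condition not in set(self.condition_of.values()):
            raise ValueError(
                f"reference condition {self.reference_condition!r} names no sample"
            )

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            c = self.condition_of[s]
            if c not in out:
                out.append(c)
        return out

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition_of[s] == condition]

    def reference_samples(self) -> list[str]:
        return self.samples_of(self.reference_condition)

    def to_metadata(
        self, project: str = "synthetic", strain: str = "synthetic",
        temperature_c: float = 37.0,
    ) -> pd.DataFrame:
        group_of = {s: f"rg{gi:03d}" for gi, grp in enumerate(self.replicate_groups)
                    for s in grp}
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "project": project,
                "condition": [self.condition_of[s] for s in self.samples],
                "replicate_group": [group_of[s] for s in self.samples],
                "strain": strain,
                "temperature_C": temperature_c,
            }
        ).set_index("sample_id")


def default_design(
    n_conditions: int,
    replicates_per_condition: int = 2,
    reference_condition: str | None = None,
) -> StudyDesign:
    """A balanced design: `n_conditions` conditions, one replicate group each."""
    samples, condition_of, groups = [], {}, []
    conditions = [f"cond{c:02d}" for c in range(n_conditions)]
    for cond in conditions:
        grp = []
        for r in range(replicates_per_condition):
            s = f"{cond}_r{r}"
            samples.append(s)
            condition_of[s] = cond
            grp.append(s)
        groups.append(grp)
    return StudyDesign(
        samples=samples,
        condition_of=condition_of,
        replicate_groups=groups,
        reference_condition=reference_condition or conditions[0],
    )


def generate_truth(
    n_genes: int,
    n_components: int,
    members_per_component: int,
    member_weight: float = 1.0,
    background_sigma: float = 0.05,
    noise_sigma: float = 0.1,
    overlap_fraction: float = 0.0,
    positive_member_fraction: float = 1.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a sparse planted gene-weight matrix M.

    Each column has exactly `members_per_component` entries of magnitude
    ≈ `member_weight`; the remaining entries are Normal(0,
    background_sigma).  Columns are renormalized to unit L2, so members
    remain the largest-|weight| genes as long as
    member_weight > background_sigma.  Member sets are disjoint unless
    `overlap_fraction` > 0, in which case that fraction of each component's
    members (after the first) is resampled from previously used genes.

    An exact `positive_member_fraction` of each member set shares the
    component's direction (which genes carry the minority sign is random),
    and each component then receives a random global sign.  The default of
    1.0 plants single-direction modules — the textbook regulon, all
    targets moved the same way — whose weight distribution stays
    asymmetric throughout iterative outlier removal, which is what an
    omnibus-normality membership test keys on.  Lower values plant a
    repressed minority; near 0.5 the member weights become symmetric and
    membership recall degrades at fixed normality thresholds.  Components
    carry arbitrary global signs, so nothing downstream may assume
    positivity.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if members_per_component < 1:
        raise ValueError("members_per_component must be >= 1")
    if member_weight <= background_sigma:
        raise ValueError("member_weight must exceed background_sigma")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if not 0.0 <= positive_member_fraction <= 1.0:
        raise ValueError("positive_member_fraction must be in [0, 1]")
    if n_components * members_per_component > n_genes:
        raise ValueError(
            f"infeasible design: {n_components} x {members_per_component} "
            f"member genes exceed {n_genes} genes"
        )

    rng = np.random.default_rng(seed)
    M = rng.normal(0.0, background_sigma, size=(n_genes, n_components))

    perm = rng.permutation(n_genes)
    member_sets: list[np.ndarray] = []
    used: list[int] = []
    cursor = 0
    for c in range(n_components):
        n_shared = int(round(overlap_fraction * members_per_component)) if c > 0 else 0
        n_shared = min(n_shared, len(used))
        fresh = members_per_component - n_shared
        idx = list(perm[cursor : cursor + fresh])
        cursor += fresh
        if n_shared:
            idx.extend(rng.choice(used, size=n_shared, replace=False))
        idx_arr = np.asarray(sorted(idx), dtype=int)
        # fixed count of minority-sign members (which genes: random), so the
        # planted asymmetry is exact rather than a Bernoulli draw
        n_neg = int(round((1.0 - positive_member_fraction) * idx_arr.size))
        signs = np.ones(idx_arr.size)
        if n_neg:
            signs[rng.choice(idx_arr.size, size=n_neg, replace=False)] = -1.0
        signs *= rng.choice([-1.0, 1.0])  # component-level sign is arbitrary
        M[idx_arr, c] = signs * member_weight
        member_sets.append(idx_arr)
        used.extend(int(i) for i in idx_arr if i not in used)

    M /= np.linalg.norm(M, axis=0, keepdims=True)
    return SyntheticTruth(
        true_M=M,
        true_A=None,
        member_sets=member_sets,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )


def generate_activities(
    truth: SyntheticTruth,
    design: StudyDesign,
    condition_effects: dict[str, np.ndarray] | None = None,
    replicate_sigma: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw a (k, samples) activity matrix from condition offsets.

    Activity of component c in sample s is the condition offset plus
    Normal(0, replicate_sigma) biological-replicate noise.  Offsets of the
    reference condition are forced to zero so that centering to the
    reference leaves planted activities interpretable as shifts from it.
    """
    if replicate_sigma < 0:
        raise ValueError("replicate_sigma must be non-negative")
    k = truth.n_components
    effects: dict[str, np.ndarray] = {}
    for cond in design.conditions:
        vec = np.zeros(k) if condition_effects is None else np.asarray(
            condition_effects.get(cond, np.zeros(k)), dtype=float
        )
        if vec.shape != (k,):
            raise ValueError(f"condition effect for {cond!r} must have length {k}")
        effects[cond] = vec
    effects[design.reference_condition] = np.zeros(k)

    rng = np.random.default_rng(seed)
    A = np.empty((k, len(design.samples)))
    for j, s in enumerate(design.samples):
        A[:, j] = effects[design.condition_of[s]] + rng.normal(
            0.0, replicate_sigma, size=k
        )
    return A


def generate_paired_activities(
    n_components: int,
    n_groups: int,
    diff_mu: float = 0.7,
    diff_sigma: float = 0.3,
    pair_center_sigma: float = 0.5,
    condition_shifts: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, StudyDesign]:
    """Replicate-paired activities whose within-pair differences are
    exactly LogNormal(diff_mu, diff_sigma) in magnitude.

    Each replicate group is a pair; the two samples sit at center ± d/2
    where d ~ LogNormal with a random sign, so the differential-activity
    null fitted to these pairs recovers (diff_mu, diff_sigma) directly.
    Pair centers carry their own Normal(0, pair_center_sigma) baseline
    variation — batch-like noise that, unlike the antisymmetric pair
    noise, does not cancel in group means.  `condition_shifts` adds
    per-condition activity offsets (k-vectors) on top, e.g. a planted
    differential signal.  Defaults model tight biological replicates whose
    activity differences concentrate around e^diff_mu activity units with
    a ~±35% log-spread.
    """
    rng = np.random.default_rng(seed)
    design = default_design(n_groups, replicates_per_condition=2)
    k = n_components
    A = np.empty((k, 2 * n_groups))
    for g, cond in enumerate(design.conditions):
        shift = np.zeros(k)
        if condition_shifts and cond in condition_shifts:
            shift = np.asarray(condition_shifts[cond], dtype=float)
        center = shift + rng.normal(0.0, pair_center_sigma, size=k)
        d = rng.lognormal(diff_mu, diff_sigma, size=k)
        sign = rng.choice([-1.0, 1.0], size=k)
        A[:, 2 * g] = center - sign * d / 2
        A[:, 2 * g + 1] = center + sign * d / 2
    names = [f"IM{i + 1:02d}" for i in range(k)]
    return pd.DataFrame(A, index=names, columns=design.samples), design


def synthesize_compendium(
    truth: SyntheticTruth,
    activities: np.ndarray,
    design: StudyDesign,
    seed: int = 0,
) -> pd.DataFrame:
    """X = M·A + Normal(0, noise_sigma), as a genes × samples DataFrame.

    The result is an *uncentered* log-TPM-like compendium; apply
    `imodkit.io.center_to_reference` before decomposition.
    """
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (truth.n_components, len(design.samples)):
        raise ValueError(
            f"activity matrix shape {activities.shape} does not conform to "
            f"({truth.n_components}, {len(design.samples)})"
        )
    rng = np.random.default_rng(seed)
    X = truth.true_M @ activities
    if truth.noise_sigma > 0:
        X = X + rng.normal(0.0, truth.noise_sigma, size=X.shape)
    truth.true_A = activities
    return pd.DataFrame(X, index=truth.gene_ids(), columns=design.samples)
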