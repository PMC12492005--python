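"""Config-driven orchestration: simulate/load → center → QC → decompose →
membership → DiMA/EV → reports.

Every artifact is a TSV (or JSON manifest) under one output directory, the
whole run is a pure function of (inputs, config), and each stage is
resumable: when its outputs already exist and the recorded config hash
matches, the stage is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import synthetic as syn
from .activity import dima, fit_dima_null, rank_by_explained_variance
from .ica import IcaConfig, Decomposition, decompose, write_decomposition
from .membership import (IModulon, compute_membership, enrich_against_trn,
                         membership_table, read_trn)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SyntheticConfig", "run_pipeline", "load_config"]


@dataclass
class SyntheticConfig:
    """Planted-truth generation settings used when no expression path is given."""

    n_genes: int = 1000
    n_components: int = 8
    members_per_component: int = 15
    member_weight: float = 1.0
    background_sigma: float = 0.05
    noise_sigma: float = 0.1
    n_conditions: int = 20
    replicates_per_condition: int = 2
    replicate_sigma: float = 1.0
    activity_scale: float = 10.0     # SD of planted per-condition offsets
    overlap_fraction: float = 0.0


@dataclass
class PipelineConfig:
    """All pipeline knobs; the defaults form the standard analysis profile
    (100 ICA runs, >half-run support, K² threshold 550, DiMA thresholds
    |Δ| > 5 at FDR 0.1, replicate-correlation QC at r ≥ 0.95)."""

    expression_path: str | None = None
    metadata_path: str | None = None
    trn_path: str | None = None
    outdir: str = "imodkit_out"
    reference_condition: str | None = None

    ica: IcaConfig = field(default_factory=IcaConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    k2_threshold: float = 550.0
    dima_diff_threshold: float = 5.0
    dima_fdr_threshold: float = 0.1
    dima_group1_condition: str | None = None   # default: reference condition
    dima_group2_condition: str | None = None   # default: last condition
    qc_min_replicate_r: float = 0.95
    qc_cluster_cut: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k2_threshold", "dima_diff_threshold", "dima_fdr_threshold",
                     "qc_min_replicate_r", "qc_cluster_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a JSON or YAML config file into a PipelineConfig."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    ica = IcaConfig(**raw.pop("ica", {}))
    synth = SyntheticConfig(**raw.pop("synthetic", {}))
    return PipelineConfig(ica=ica, synthetic=synth, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_inputs(cfg: PipelineConfig):
    """Generate a planted-truth compendium + design from the config seed."""
    s = cfg.synthetic
    rng = np.random.default_rng(cfg.seed)
    truth = syn.generate_truth(
        n_genes=s.n_genes,
        n_components=s.n_components,
        members_per_component=s.members_per_component,
        member_weight=s.member_weight,
        background_sigma=s.background_sigma,
        noise_sigma=s.noise_sigma,
        overlap_fraction=s.overlap_fraction,
        seed=cfg.seed,
    )
    design = syn.default_design(s.n_conditions, s.replicates_per_condition)
    effects = {
        cond: rng.normal(0.0, s.activity_scale, size=s.n_components)
        for cond in design.conditions
    }
    A_true = syn.generate_activities(
        truth, design, effects, replicate_sigma=s.replicate_sigma,
        seed=cfg.seed + 1,
    )
    X = syn.synthesize_compendium(truth, A_true, design, seed=cfg.seed + 2)
    return truth, design, cio.ExpressionMatrix(X)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage, writing artifacts and a manifest under cfg.outdir."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest_path = out / "manifest.json"
    prev = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    resume_ok = prev.get("config_hash") == chash
    stages: dict[str, dict] = {}

    def fresh(*names: str) -> bool:
        done = resume_ok and all((out / n).exists() for n in names)
        if done:
            logger.info("skipping stage (outputs exist): %s", ", ".join(names))
        return not done

    truth = None
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    if cfg.expression_path:
        X = cio.read_expression_matrix(cfg.expression_path)
        meta = cio.read_metadata(cfg.metadata_path)
        if cfg.reference_condition is None:
            raise ValueError("reference_condition is required with loaded data")
        design = cio.design_from_metadata(meta, cfg.reference_condition)
    else:
        truth, design, X = simulate_inputs(cfg)
        meta = design.to_metadata()
        if fresh("expression.tsv", "metadata.tsv", "true_M.tsv", "true_A.tsv",
                 "true_members.tsv"):
            cio.write_expression_matrix(X, out / "expression.tsv")
            cio.write_metadata(meta, out / "metadata.tsv")
            pd.DataFrame(truth.true_M, index=truth.gene_ids()).to_csv(
                out / "true_M.tsv", sep="\t", float_format="%.6g",
                index_label="gene_id")
            pd.DataFrame(truth.true_A, columns=design.samples).to_csv(
                out / "true_A.tsv", sep="\t", float_format="%.6g",
                index_label="component")
            membership_rows = [
                {"component": c, "gene": truth.gene_ids()[g]}
                for c, idx in enumerate(truth.member_sets) for g in idx
            ]
            pd.DataFrame(membership_rows).to_csv(
                out / "true_members.tsv", sep="\t", index=False)
        cfg = dataclasses.replace(cfg)  # design-derived reference below
        if cfg.reference_condition is None:
            cfg.reference_condition = design.reference_condition
    stages["inputs"] = {"seconds": round(time.time() - t0, 3)}

    # --- centering + QC ---------------------------------------------------
    t0 = time.time()
    Xc = cio.center_to_reference(X, design.samples_of(cfg.reference_condition))
    if fresh("expression_centered.tsv", "qc_report.tsv"):
        cio.write_expression_matrix(Xc, out / "expression_centered.tsv")
        qc = cio.qc_replicate_correlation(X, design, min_r=cfg.qc_min_replicate_r)
        try:
            outliers = cio.qc_clustering_outliers(X, cut=cfg.qc_cluster_cut)
        except ValueError:
            outliers = []
        qc.clustering_outliers = outliers
        frame = qc.to_frame()
        frame.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        if qc.failing_samples or outliers:
            logger.warning("QC flagged samples: %s",
                           sorted({*qc.failing_samples, *outliers}))
    stages["qc"] = {"seconds": round(time.time() - t0, 3)}

    # --- decomposition ----------------------------------------------------
    t0 = time.time()
    if fresh("M.tsv", "A.tsv", "diagnostics.tsv", "run_manifest.json"):
        dec = decompose(Xc, cfg.ica)
        write_decomposition(dec, out)
    M = pd.read_csv(out / "M.tsv", sep="\t", index_col=0)
    A = pd.read_csv(out / "A.tsv", sep="\t", index_col=0)
    stages["decompose"] = {"seconds": round(time.time() - t0, 3)}

    # --- membership + enrichment -----------------------------------------
    t0 = time.time()
    imodulons = [
        compute_membership(M[c], k2_threshold=cfg.k2_threshold, name=c)
        for c in M.columns
    ]
    if fresh("members.tsv", "enrichment.tsv"):
        membership_table(imodulons).to_csv(out / "members.tsv", sep="\t",
                                           index=False)
        enr_rows = []
        if cfg.trn_path:
            trn = read_trn(cfg.trn_path)
            for im in imodulons:
                for r in enrich_against_trn(im, trn, list(M.index)):
                    enr_rows.append({"imodulon": im.name, **asdict(r)})
        pd.DataFrame(
            enr_rows,
            columns=["imodulon", "regulator", "overlap", "member_count",
                     "regulon_size", "universe_size", "p_value", "q_value"],
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    stages["membership"] = {"seconds": round(time.time() - t0, 3)}

    # --- DiMA + explained variance ---------------------------------------
    t0 = time.time()
    if fresh("dima.tsv", "explained_variance.tsv"):
        null = fit_dima_null(A, design)
        g1_cond = cfg.dima_group1_condition or cfg.reference_condition
        g2_cond = cfg.dima_group2_condition or design.conditions[-1]
        res = dima(
            A,
            design.samples_of(g1_cond),
            design.samples_of(g2_cond),
            null,
            diff_threshold=cfg.dima_diff_threshold,
            fdr_threshold=cfg.dima_fdr_threshold,
        )
        res.to_csv(out / "dima.tsv", sep="\t", index=False, float_format="%.6g")
        ev = rank_by_explained_variance(Xc, M, A)
        ev.to_csv(out / "explained_variance.tsv", sep="\t", index=False,
                  float_format="%.6g")
    stages["stats"] = {"seconds": round(time.time() - t0, 3)}

    artifacts = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": asdict(cfg),
        "config_hash": chash,
        "seeds": {
            "pipeline": cfg.seed,
            "ica_runs": [cfg.ica.base_seed + i for i in range(cfg.ica.n_runs)],
        },
        "stages": stages,
        "checksums": {name: _sha256(out / name) for name in artifacts},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out
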