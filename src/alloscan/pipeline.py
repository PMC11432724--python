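"""End-to-end orchestration: mask → plan → ensembles → classify → PCA →
correlate → network → hotspot mapping, driven by one configuration.

The external structure-prediction step is represented by a job manifest plus
an "ensemble drop directory" contract: the pipeline emits the masked FASTA
and manifest that a ColabFold-style runner would consume, and analyzes
whatever multi-model PDBs are provided — in the demo path, synthetic
multi-state ensembles with known ground truth stand in for predicted ones.

All randomness flows from the single ``seed`` in the configuration; a rerun
with the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import (
    ConformationalEnsemble,
    read_ensemble,
    write_ensemble,
    filter_by_confidence,
    merge_ensembles,
)
from .masking import (
    MaskingConfig,
    JobPlanConfig,
    generate_masked_set,
    plan_prediction_jobs,
    write_job_manifest,
)
from .synthetic import (
    ConfidenceProfile,
    MixtureSpec,
    assign_confidence,
    generate_mixture_ensemble,
    generate_reference_states,
)
from .metrics import classify_states, rmsd_profile, tm_score
from .pca import fit_reference_pca, project, state_overlap
from .correlation import contact_persistence, dcc_matrix, gc_matrix
from .network import (
    betweenness_profile,
    bridgeness_profile,
    build_network,
    detect_communities,
    export_graphml,
    map_mutations,
    shortest_paths,
)

logger = logging.getLogger("alloscan")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable).

    Defaults mirror the canonical kinase-domain setting: a 287-residue chain
    numbered 245-531, activation loop 398-421, helix-C 291-311, pLDDT filter
    at 70, nearest-state assignment below 1.5 Å, persistence 75%, hotspot
    Z >= 2, mutation proximity 5 Å.  The contact cutoff defaults to 7.5 Å
    because the ensembles here are Cα-only traces (the 5 Å side-chain
    convention is too tight for Cα distances).
    """

    run_dir: str = "alloscan_run"
    seed: int = 0
    sequence: str | None = None                 # native sequence; random if None
    sequence_fasta: str | None = None           # optional FASTA to read it from
    # synthetic ensemble conditions
    n_residues: int = 287
    first_residue_id: int = 245
    loop_span: tuple[int, int] = (154, 177)     # positional; ids 398-421 with the defaults
    n_reference_models: int = 20
    mixture_populations: dict = field(
        default_factory=lambda: {"I2": 0.82, "I1": 0.10, "active": 0.08}
    )
    n_mixture_models: int = 70
    noise_sd: float = 0.3
    n_low_confidence_models: int = 3
    ensemble_dir: str | None = None             # drop directory with predicted PDBs
    # masking / job planning
    masking_mode: str = "targeted"
    masking_regions: list = field(default_factory=lambda: [(154, 177)])
    p_min: float = 0.05
    p_max: float = 0.15
    n_masked_sequences: int = 10
    max_seqs: int = 16
    extra_seqs: int = 32
    num_recycles: int = 12
    num_seed: int = 1
    n_models: int = 5
    # thresholds
    plddt_threshold: float = 70.0
    rmsd_threshold: float = 1.5
    contact_cutoff: float = 7.5
    min_persistence: float = 0.75
    z_threshold: float = 2.0
    proximity: float = 5.0
    # regions / sites in residue-id numbering
    a_loop: tuple[int, int] = (398, 421)
    alpha_c: tuple[int, int] = (291, 311)
    mutation_sites: list = field(
        default_factory=lambda: [269, 272, 309, 320, 334, 378, 389, 401, 408, 415]
    )
    max_communities: int = 10


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML (missing keys take defaults)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    allowed = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.loop_span = tuple(cfg.loop_span)
    cfg.a_loop = tuple(cfg.a_loop)
    cfg.alpha_c = tuple(cfg.alpha_c)
    cfg.masking_regions = [tuple(r) for r in cfg.masking_regions]
    return cfg


def _native_sequence(cfg: PipelineConfig) -> str:
    if cfg.sequence:
        return cfg.sequence
    if cfg.sequence_fasta:
        from biotite.sequence.io.fasta import FastaFile

        fasta = FastaFile.read(cfg.sequence_fasta)
        return str(next(iter(fasta.items()))[1])
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000]))
    return "".join(rng.choice(list(_AA), size=cfg.n_residues))


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write a run report; returns the report dict.

    Any stage failure aborts with the stage name attached; outputs written by
    earlier stages are retained in the run directory.
    """
    run_dir = Path(cfg.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": _config_dict(cfg)}
    stage = "configuration"
    try:
        # -- masking + job planning -----------------------------------------
        stage = "masking"
        _stage(stage)
        native = _native_sequence(cfg)
        mask_cfg = MaskingConfig(
            mode=cfg.masking_mode,
            regions=cfg.masking_regions if cfg.masking_mode == "targeted" else None,
            p_min=cfg.p_min,
            p_max=cfg.p_max,
            n_sequences=cfg.n_masked_sequences,
            seed=cfg.seed,
        )
        masked = generate_masked_set(native, mask_cfg)
        job_cfg = JobPlanConfig(
            max_seqs=cfg.max_seqs,
            extra_seqs=cfg.extra_seqs,
            num_recycles=cfg.num_recycles,
            num_seed=cfg.num_seed,
            n_models=cfg.n_models,
        )
        plan = plan_prediction_jobs([f"variant_{v.index:03d}" for v in masked.variants], job_cfg)
        write_job_manifest(plan, masked, run_dir / "masked_variants.fasta")
        report["masking"] = {
            "n_variants": len(masked.variants),
            "mean_rate": float(np.mean([v.rate for v in masked.variants])),
            "outputs_per_sequence": job_cfg.outputs_per_sequence,
            "total_planned_outputs": plan.total_outputs,
        }

        # -- ensembles -------------------------------------------------------
        stage = "ensembles"
        _stage(stage)
        references = generate_reference_states(
            n_residues=cfg.n_residues,
            loop_span=cfg.loop_span,
            n_models=cfg.n_reference_models,
            noise_sd=cfg.noise_sd,
            seed=cfg.seed + 1,
            first_residue_id=cfg.first_residue_id,
        )
        for label, state in references.items():
            write_ensemble(state.ensemble, run_dir / f"reference_{label}.pdb", sidecar=True)

        if cfg.ensemble_dir:
            predicted = read_ensemble(sorted(Path(cfg.ensemble_dir).glob("*.pdb"))[0])
            true_labels = None
        else:
            spec = MixtureSpec(
                populations=dict(cfg.mixture_populations),
                n_models=cfg.n_mixture_models,
                noise_sd=cfg.noise_sd,
                seed=cfg.seed + 2,
            )
            predicted, true_labels = generate_mixture_ensemble(spec, references)
        profile = ConfidenceProfile(
            loop_span=cfg.loop_span,
            low_models=list(range(min(cfg.n_low_confidence_models, predicted.n_models))),
            seed=cfg.seed + 3,
        )
        predicted = assign_confidence(predicted, profile)
        write_ensemble(predicted, run_dir / "predicted_ensemble.pdb", sidecar=True)

        stage = "confidence filter"
        _stage(stage)
        analysis = filter_by_confidence(predicted, cfg.plddt_threshold)
        report["filter"] = {
            "n_input_models": predicted.n_models,
            "n_retained_models": analysis.n_models,
            "plddt_threshold": cfg.plddt_threshold,
        }

        # -- classification ---------------------------------------------------
        stage = "state classification"
        _stage(stage)
        refs = {label: s.ensemble for label, s in references.items()}
        cls = classify_states(analysis, refs, cfg.rmsd_threshold)
        cls.to_frame().to_csv(run_dir / "classification.csv", index=False)
        report["populations"] = cls.populations
        if true_labels is not None:
            kept = [
                lab
                for lab, keep in zip(true_labels, predicted.model_confidence() >= cfg.plddt_threshold)
                if keep
            ]
            report["true_populations"] = {
                s: kept.count(s) / len(kept) for s in sorted(set(kept))
            }
        aloop = rmsd_profile(analysis, refs["active"], report_residues=cfg.a_loop)
        pd.DataFrame({"model": range(analysis.n_models), "a_loop_rmsd_to_active": aloop}).to_csv(
            run_dir / "a_loop_rmsd.csv", index=False
        )
        score, same_fold = tm_score(analysis.coords[0], refs["active"].coords[0])
        report["tm_score_model0_vs_active"] = {"score": round(score, 4), "same_fold": bool(same_fold)}

        # -- PCA ---------------------------------------------------------------
        stage = "pca"
        _stage(stage)
        wt_merged = merge_ensembles([(refs[s], s) for s in ("active", "I1", "I2")])
        pca_model = fit_reference_pca(wt_merged, confidence_threshold=None)
        merged_all = merge_ensembles(
            [(refs[s], s) for s in ("active", "I1", "I2")] + [(analysis, "predicted")]
        )
        scores = project(merged_all, pca_model, n_components=2)
        scores.to_csv(run_dir / "pca_scores.csv", index=False)
        ref_scores = scores[scores["label"] != "predicted"]
        overlaps = state_overlap(ref_scores)
        overlaps.to_csv(run_dir / "pca_state_overlap.csv", index=False)
        report["pca"] = {
            "explained_variance_ratio_pc1": float(pca_model.explained_variance_ratio[0]),
            "explained_variance_ratio_pc2": float(pca_model.explained_variance_ratio[1]),
        }

        # -- correlations ------------------------------------------------------
        stage = "correlation"
        _stage(stage)
        dcc = dcc_matrix(analysis)
        gc = gc_matrix(analysis, estimator="gaussian")
        persistence = contact_persistence(analysis, cfg.contact_cutoff, cfg.min_persistence)
        _matrix_csv(dcc.matrix, dcc.residue_ids, run_dir / "dcc.csv")
        _matrix_csv(gc.matrix, gc.residue_ids, run_dir / "gc.csv")

        # -- network -----------------------------------------------------------
        stage = "network"
        _stage(stage)
        rin = build_network(persistence, gc)
        paths = shortest_paths(rin)
        profile_b = betweenness_profile(paths, cfg.z_threshold)
        profile_b.to_frame().to_csv(run_dir / "centrality.csv", index=False)
        partition = detect_communities(rin, max_communities=cfg.max_communities)
        bridge = bridgeness_profile(rin, partition)
        bridge.to_frame().to_csv(run_dir / "bridgeness.csv", index=False)

        rep_coords = {
            int(r): refs["active"].coords[0][i]
            for i, r in enumerate(refs["active"].residue_ids)
        }
        sites = [s for s in cfg.mutation_sites if s in set(profile_b.nodes)]
        mapping = map_mutations(sites, profile_b, rep_coords, cfg.proximity)
        mapping.table.to_csv(run_dir / "mutation_mapping.csv", index=False)
        export_graphml(rin, profile_b, partition, bridge, str(run_dir / "network.graphml"))

        report["network"] = {
            "n_nodes": rin.graph.number_of_nodes(),
            "n_edges": rin.graph.number_of_edges(),
            "hotspots": sorted(profile_b.hotspots),
            "n_communities": len(partition.communities),
            "modularity": round(partition.modularity, 4),
            "mutation_status": {
                str(row["site"]): row["status"] for _, row in mapping.table.iterrows()
            },
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (run_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _matrix_csv(matrix: np.ndarray, residue_ids: np.ndarray, path: Path) -> None:
    pd.DataFrame(matrix, index=residue_ids, columns=residue_ids).to_csv(path)


def _config_dict(cfg: PipelineConfig) -> dict:
    out = asdict(cfg)
    out["loop_span"] = list(cfg.loop_span)
    out["a_loop"] = list(cfg.a_loop)
    out["alpha_c"] = list(cfg.alpha_c)
    out["masking_regions"] = [list(r) for r in cfg.masking_regions]
    return out
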