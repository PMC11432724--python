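"""Randomized / targeted alanine sequence masking and prediction-job planning.

This is the front-end of the pipeline: it perturbs the coevolutionary signal
seen by an MSA-based structure predictor by substituting a random 5-15% of
sequence positions with alanine — either across the full sequence or only
inside targeted functional regions (e.g. a kinase activation loop) — and
enumerates the prediction outputs a shallow-MSA run would produce.  Nothing
here executes a neural network; the deliverables are FASTA inputs and a job
manifest an external ColabFold-style runner can consume.

Masking model: for each eligible position a probability p_i is drawn uniformly
from [p_min, p_max] and the residue is replaced by alanine with probability
p_i.  This per-position draw (rather than fixing one rate per sequence) is the
more explicit of the two common phrasings of the protocol; the realized
per-variant rates therefore scatter around (p_min+p_max)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from biotite.sequence.io.fasta import FastaFile

__all__ = [
    "AMINO_ACIDS",
    "MaskingConfig",
    "MaskedVariant",
    "MaskedSequenceSet",
    "JobPlanConfig",
    "PredictionJobPlan",
    "mask_sequence",
    "generate_masked_set",
    "plan_prediction_jobs",
    "write_job_manifest",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MaskingConfig:
    """Settings for alanine sequence masking.

    ``mode`` is ``"full_sequence"`` or ``"targeted"``; targeted mode requires
    ``regions``, a list of 1-based inclusive position intervals that alone are
    eligible for substitution.  ``p_min``/``p_max`` bound the per-position
    substitution probability (defaults 0.05 / 0.15).
    """

    mode: str = "full_sequence"
    regions: list[tuple[int, int]] | None = None
    p_min: float = 0.05
    p_max: float = 0.15
    n_sequences: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("full_sequence", "targeted"):
            raise ValueError(f"unknown masking mode {self.mode!r}")
        if not (0.0 <= self.p_min <= self.p_max <= 1.0):
            raise ValueError("require 0 <= p_min <= p_max <= 1")
        if self.mode == "targeted" and not self.regions:
            raise ValueError("targeted masking requires at least one region")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


@dataclass
class MaskedVariant:
    sequence: str
    positions: list[int]            # 1-based substituted positions
    identity_positions: list[int]   # subset where the native residue was already A
    rate: float                     # len(positions) / len(sequence)
    index: int


@dataclass
class MaskedSequenceSet:
    native: str
    config: MaskingConfig
    variants: list[MaskedVariant]


def _validate_sequence(native: str) -> None:
    if not native:
        raise ValueError("empty sequence")
    bad = sorted(set(native) - AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid amino-acid letters in sequence: {bad}")


def _eligible_positions(length: int, config: MaskingConfig) -> np.ndarray:
    if config.mode == "full_sequence":
        return np.arange(length)
    eligible: list[int] = []
    for lo, hi in config.regions:  # type: ignore[union-attr]
        if not (1 <= lo <= hi <= length):
            raise ValueError(f"region {lo}-{hi} outside the sequence (length {length})")
        eligible.extend(range(lo - 1, hi))
    return np.unique(np.array(eligible, dtype=int))


def mask_sequence(native: str, config: MaskingConfig, variant_index: int = 0) -> MaskedVariant:
    """Produce one masked variant, deterministic for fixed (seed, variant_index).

    Positions whose native residue is already alanine remain eligible; a draw
    there is a no-op on the sequence but is recorded as an identity
    substitution so the realized rate stays well defined.
    """
    _validate_sequence(native)
    eligible = _eligible_positions(len(native), config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, variant_index]))
    p = rng.uniform(config.p_min, config.p_max, size=eligible.size)
    hit = eligible[rng.random(eligible.size) < p]

    seq = list(native)
    positions, identity = [], []
    for i in hit:
        positions.append(int(i) + 1)
        if seq[i] == "A":
            identity.append(int(i) + 1)
        seq[i] = "A"
    return MaskedVariant(
        sequence="".join(seq),
        positions=positions,
        identity_positions=identity,
        rate=len(positions) / len(native),
        index=variant_index,
    )


def generate_masked_set(native: str, config: MaskingConfig) -> MaskedSequenceSet:
    """Generate ``config.n_sequences`` independent masked variants."""
    variants = [mask_sequence(native, config, i) for i in range(config.n_sequences)]
    return MaskedSequenceSet(native=native, config=config, variants=variants)


# ---------------------------------------------------------------------------
# Prediction-job planning
# ---------------------------------------------------------------------------

@dataclass
class JobPlanConfig:
    """Shallow-MSA prediction settings mirrored into the job manifest.

    ``max_seqs``/``extra_seqs`` are the MSA subsampling depths (default 16:32,
    the depth that maximizes ensemble diversity in practice); each of the
    ``n_models`` pretrained models emits one structure per recycle 0..
    ``num_recycles`` plus a final refined structure, per random seed.
    """

    max_seqs: int = 16
    extra_seqs: int = 32
    num_recycles: int = 12
    num_seed: int = 1
    n_models: int = 5
    use_dropout: bool = True

    def __post_init__(self) -> None:
        for name in ("max_seqs", "extra_seqs", "num_seed", "n_models"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.num_recycles < 0:
            raise ValueError("num_recycles must be >= 0")

    @property
    def subsampling(self) -> str:
        return f"{self.max_seqs}:{self.extra_seqs}"

    @property
    def outputs_per_model(self) -> int:
        # recycles 0..num_recycles plus the final refined structure
        return self.num_recycles + 2

    @property
    def outputs_per_sequence(self) -> int:
        return self.n_models * self.num_seed * self.outputs_per_model


@dataclass
class PredictionJobPlan:
    """Enumerated prediction outputs for a set of input sequences."""

    sequence_ids: list[str]
    config: JobPlanConfig
    jobs: list[dict] = field(default_factory=list)

    @property
    def total_outputs(self) -> int:
        return len(self.jobs)


def plan_prediction_jobs(sequence_ids: Sequence[str], config: JobPlanConfig) -> PredictionJobPlan:
    """Enumerate every (sequence x model x seed x recycle-or-final) output.

    With the defaults (5 models, 12 recycles, 1 seed) each model yields 14
    structures and each sequence 70 — the size of one standard run.
    """
    ids = list(sequence_ids)
    if not ids:
        raise ValueError("need at least one sequence")
    jobs = []
    for sid in ids:
        for model in range(1, config.n_models + 1):
            for seed in range(config.num_seed):
                for rec in range(config.num_recycles + 1):
                    jobs.append(
                        {"sequence": sid, "model": model, "seed": seed, "recycle": rec}
                    )
                jobs.append(
                    {"sequence": sid, "model": model, "seed": seed, "recycle": "final"}
                )
    plan = PredictionJobPlan(sequence_ids=ids, config=config, jobs=jobs)
    assert plan.total_outputs == len(ids) * config.outputs_per_sequence
    return plan


def write_job_manifest(
    plan: PredictionJobPlan,
    masked_set: MaskedSequenceSet,
    fasta_path: str | Path,
    manifest_path: str | Path | None = None,
) -> tuple[Path, Path]:
    """Write the masked variants as FASTA plus a JSON job manifest.

    One FASTA record per variant; headers carry the variant index, masking
    mode and realized substitution rate.  The manifest echoes the subsampling
    settings (e.g. ``"16:32"``) and the per-sequence output totals.
    """
    expected = [f"variant_{v.index:03d}" for v in masked_set.variants]
    if list(plan.sequence_ids) != expected:
        raise ValueError("job plan and masked set refer to different sequences")

    fasta_path = Path(fasta_path)
    fasta = FastaFile()
    for v in masked_set.variants:
        header = (
            f"variant_{v.index:03d} mode={masked_set.config.mode} "
            f"rate={v.rate:.4f} n_substitutions={len(v.positions)}"
        )
        fasta[header] = v.sequence
    fasta.write(fasta_path)

    if manifest_path is None:
        manifest_path = fasta_path.with_suffix(".manifest.json")
    manifest_path = Path(manifest_path)
    cfg = plan.config
    manifest = {
        "fasta": fasta_path.name,
        "masking": {
            "mode": masked_set.config.mode,
            "regions": masked_set.config.regions,
            "p_min": masked_set.config.p_min,
            "p_max": masked_set.config.p_max,
            "n_sequences": masked_set.config.n_sequences,
            "seed": masked_set.config.seed,
        },
        "prediction": {
            "max_seqs": cfg.max_seqs,
            "extra_seqs": cfg.extra_seqs,
            "subsampling": cfg.subsampling,
            "num_recycles": cfg.num_recycles,
            "num_seed": cfg.num_seed,
            "n_models": cfg.n_models,
            "use_dropout": cfg.use_dropout,
            "outputs_per_model": cfg.outputs_per_model,
            "outputs_per_sequence": cfg.outputs_per_sequence,
        },
        "sequences": [
            {
                "id": f"variant_{v.index:03d}",
                "substituted_positions": v.positions,
                "realized_rate": v.rate,
            }
            for v in masked_set.variants
        ],
        "total_outputs": plan.total_outputs,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return fasta_path, manifest_path
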