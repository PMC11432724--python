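"""Conformational ensembles: the in-memory container and multi-model PDB I/O.

A :class:`ConformationalEnsemble` is the currency of the whole pipeline: an
ordered set of models, each a Cα trace over a shared residue-id frame, with an
optional per-model, per-residue confidence track on the pLDDT scale (0-100,
stored in the PDB B-factor column on disk) and a provenance label per model.

Residue ids are author numbering (1-based); all intervals in this package are
1-based and inclusive at both ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger("alloscan")

__all__ = [
    "ConformationalEnsemble",
    "read_ensemble",
    "write_ensemble",
    "filter_by_confidence",
    "merge_ensembles",
]


@dataclass
class ConformationalEnsemble:
    """An ordered set of Cα-trace models over a common residue-id frame.

    Parameters
    ----------
    residue_ids : (n_residues,) int array
        Author residue numbering, strictly increasing (gaps allowed).
    coords : (n_models, n_residues, 3) float array
        Cα coordinates in Å.
    confidence : (n_models, n_residues) float array, optional
        Per-residue confidence on the pLDDT 0-100 scale.
    labels : list of str, optional
        Provenance label per model (e.g. state or method of origin).
    """

    residue_ids: np.ndarray
    coords: np.ndarray
    confidence: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_models, n_residues, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != self.residue_ids.size:
            raise ValueError(
                f"coords residue axis ({self.coords.shape[1]}) does not match "
                f"residue_ids ({self.residue_ids.size})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.coords.shape[:2]:
                raise ValueError(
                    f"confidence shape {self.confidence.shape} does not match "
                    f"models x residues {self.coords.shape[:2]}"
                )
            if np.any((self.confidence < 0) | (self.confidence > 100)):
                raise ValueError("confidence values must lie in [0, 100]")
        if not self.labels:
            self.labels = ["unlabeled"] * self.n_models
        elif len(self.labels) != self.n_models:
            raise ValueError("labels length must equal the number of models")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def model_confidence(self) -> np.ndarray:
        """Unweighted mean per-residue confidence of each model."""
        if self.confidence is None:
            raise ValueError("ensemble carries no confidence track")
        return self.confidence.mean(axis=1)

    def residue_index(self, residue_ids: Iterable[int]) -> np.ndarray:
        """Positional indices of the given residue ids (error on absent ids)."""
        wanted = np.asarray(list(residue_ids), dtype=int)
        pos = np.searchsorted(self.residue_ids, wanted)
        bad = (pos >= self.residue_ids.size) | (self.residue_ids[np.minimum(pos, self.residue_ids.size - 1)] != wanted)
        if np.any(bad):
            raise KeyError(f"residue ids not in ensemble: {wanted[bad].tolist()}")
        return pos

    def subset_residues(self, residue_ids: Iterable[int]) -> "ConformationalEnsemble":
        idx = self.residue_index(residue_ids)
        return ConformationalEnsemble(
            residue_ids=self.residue_ids[idx],
            coords=self.coords[:, idx, :],
            confidence=None if self.confidence is None else self.confidence[:, idx],
            labels=list(self.labels),
        )

    def subset_models(self, model_indices: Sequence[int]) -> "ConformationalEnsemble":
        idx = np.asarray(list(model_indices), dtype=int)
        return ConformationalEnsemble(
            residue_ids=self.residue_ids.copy(),
            coords=self.coords[idx],
            confidence=None if self.confidence is None else self.confidence[idx],
            labels=[self.labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# PDB I/O (biotite does the actual parsing/formatting)
# ---------------------------------------------------------------------------

def _model_to_atom_array(ensemble: ConformationalEnsemble, m: int) -> struc.AtomArray:
    n = ensemble.n_residues
    arr = struc.AtomArray(n)
    arr.coord = ensemble.coords[m]
    arr.res_id = ensemble.residue_ids
    arr.res_name = np.full(n, "ALA")
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.chain_id = np.full(n, "A")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation(
        "b_factor",
        ensemble.confidence[m] if ensemble.confidence is not None else np.zeros(n),
    )
    arr.set_annotation("occupancy", np.ones(n))
    return arr


def write_ensemble(ensemble: ConformationalEnsemble, path: str | Path, sidecar: bool = False) -> Path:
    """Write a multi-model PDB file (MODEL/ENDMDL records, B-factor = confidence).

    With ``sidecar=True`` a ``<path>.json`` file records the per-model labels so
    provenance survives a round trip.
    """
    path = Path(path)
    lines: list[str] = []
    for m in range(ensemble.n_models):
        single = PDBFile()
        single.set_structure(_model_to_atom_array(ensemble, m))
        lines.append(f"MODEL     {m + 1:4d}")
        lines.extend(single.lines)
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        Path(str(path) + ".json").write_text(
            json.dumps({"labels": list(ensemble.labels)}, indent=1)
        )
    return path


def read_ensemble(path: str | Path) -> ConformationalEnsemble:
    """Read a multi-model PDB file into a Cα-trace ensemble.

    One ensemble model per MODEL record (a single unnumbered model is accepted);
    the B-factor column is mapped to confidence, an all-zero column is taken to
    mean "no confidence recorded".  Residues lacking a Cα atom are dropped with
    a warning; if models disagree on the residue set, the intersection is used.
    """
    path = Path(path)
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise ValueError(f"{path}: no parsable models")

    per_model: list[dict[int, tuple[np.ndarray, float]]] = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, extra_fields=["b_factor"], altloc="first")
        ca = arr[(arr.atom_name == "CA") & ~arr.hetero]
        if ca.array_length() == 0:
            raise ValueError(f"{path}: model {m} contains no Cα atoms")
        n_res_total = len(np.unique(arr[~arr.hetero].res_id))
        if len(np.unique(ca.res_id)) < n_res_total:
            logger.warning(
                "%s model %d: %d residue(s) lack a CA atom and were dropped",
                path, m, n_res_total - len(np.unique(ca.res_id)),
            )
        table: dict[int, tuple[np.ndarray, float]] = {}
        for i in range(ca.array_length()):
            rid = int(ca.res_id[i])
            if rid not in table:  # first altloc/duplicate wins
                table[rid] = (ca.coord[i], float(ca.b_factor[i]))
        per_model.append(table)

    common = set(per_model[0])
    for table in per_model[1:]:
        common &= set(table)
    if not common:
        raise ValueError(f"{path}: models share no residues")
    if any(len(t) != len(common) for t in per_model):
        logger.warning("%s: inconsistent residue sets across models; using intersection", path)
    residue_ids = np.array(sorted(common), dtype=int)

    coords = np.empty((n_models, residue_ids.size, 3))
    bfac = np.empty((n_models, residue_ids.size))
    for m, table in enumerate(per_model):
        for j, rid in enumerate(residue_ids):
            coords[m, j], bfac[m, j] = table[rid]

    confidence = None if np.all(bfac == 0.0) else bfac
    labels: list[str] = []
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        labels = json.loads(sidecar.read_text()).get("labels", [])
        if len(labels) != n_models:
            labels = []
    return ConformationalEnsemble(residue_ids, coords, confidence, labels)


# ---------------------------------------------------------------------------
# Filtering and merging
# ---------------------------------------------------------------------------

def filter_by_confidence(
    ensemble: ConformationalEnsemble, threshold: float = 70.0
) -> ConformationalEnsemble:
    """Keep models whose mean per-residue confidence is >= ``threshold``.

    This mirrors the convention of excluding low-confidence predicted models
    (pLDDT < 70) from ensemble statistics.  Model order is preserved.  An
    ensemble without a confidence track is rejected rather than passed through.
    """
    means = ensemble.model_confidence()  # raises if confidence absent
    keep = np.flatnonzero(means >= threshold)
    if keep.size < ensemble.n_models:
        logger.info(
            "confidence filter at %.1f removed %d of %d models",
            threshold, ensemble.n_models - keep.size, ensemble.n_models,
        )
    return ensemble.subset_models(keep)


def merge_ensembles(
    items: Sequence[tuple[ConformationalEnsemble, str]],
    min_shared_fraction: float = 0.9,
) -> ConformationalEnsemble:
    """Concatenate ensembles into one, relabelling each block for provenance.

    Residue correspondence is by residue id.  If the id sets differ, the
    intersection is used provided it covers at least ``min_shared_fraction`` of
    every input's residues; otherwise the mismatch is an error.
    """
    if not items:
        raise ValueError("merge_ensembles needs at least one ensemble")
    id_sets = [set(e.residue_ids.tolist()) for e, _ in items]
    common = set.intersection(*id_sets)
    for (e, label), ids in zip(items, id_sets):
        if not common or len(common) < min_shared_fraction * len(ids):
            raise ValueError(
                f"ensemble '{label}' shares only {len(common)} of {len(ids)} "
                "residues with the others; residue frames are incompatible"
            )
    if any(len(common) != len(ids) for ids in id_sets):
        logger.warning("merging on a common intersection of %d residues", len(common))
    shared = sorted(common)

    parts = [e.subset_residues(shared) for e, _ in items]
    has_conf = all(p.confidence is not None for p in parts)
    if not has_conf and any(p.confidence is not None for p in parts):
        logger.warning("some inputs lack confidence; merged ensemble drops it")
    labels: list[str] = []
    for (_, label), part in zip(items, parts):
        labels.extend([label] * part.n_models)
    return ConformationalEnsemble(
        residue_ids=np.array(shared, dtype=int),
        coords=np.concatenate([p.coords for p in parts], axis=0),
        confidence=(
            np.concatenate([p.confidence for p in parts], axis=0) if has_conf else None
        ),
        labels=labels,
    )
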