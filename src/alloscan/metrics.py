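"""Superposition, RMSD, TM-score, state classification and density summaries.

All quantities are computed on Cα coordinates.  The reference conformation of
an ensemble is by convention its *first* model, matching the common practice of
reporting RMSD with respect to the first conformation of an NMR ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .ensemble import ConformationalEnsemble

logger = logging.getLogger("alloscan")

__all__ = [
    "SuperpositionResult",
    "StateClassification",
    "superpose",
    "rmsd",
    "rmsd_profile",
    "tm_score",
    "classify_states",
    "density_summary",
    "iterative_mean_structure",
]

#: Fixed label order used to break exact classification ties.
STATE_ORDER = ("active", "I1", "I2")


@dataclass
class SuperpositionResult:
    """A rigid-body least-squares fit (Kabsch), reflection excluded."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)
    rmsd: float               # over the fit selection, Å
    selection: np.ndarray     # indices used for the fit

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Minimizes the Cα RMSD over all rotations+translations (Kabsch algorithm via
    SVD); improper rotations (reflections) are excluded.  ``selection`` gives
    the positional indices used for the fit (default: all positions).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be (n, 3) arrays of equal shape")
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected positions")

    x = mobile[sel]
    y = reference[sel]
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinear point sets leave the rotation about the common axis undetermined
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2 or np.linalg.matrix_rank(y0, tol=1e-8) < 2:
        raise ValueError("selected positions are collinear; superposition is ill-defined")

    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    fitted = x @ rot.T + trans
    value = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=value, selection=sel)


def rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit: bool = True,
    fit_selection: np.ndarray | None = None,
    report_selection: np.ndarray | None = None,
) -> float:
    """Cα RMSD between two conformations of the same chain.

    With ``fit=True`` (default) the mobile coordinates are first superposed
    over ``fit_selection`` (default: all positions); the RMSD is then reported
    over ``report_selection`` (default: all positions).  ``fit=False`` gives
    the direct coordinate RMSD with no superposition.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if fit:
        sup = superpose(mobile, reference, fit_selection)
        mobile = sup.apply(mobile)
    rep = (
        np.arange(mobile.shape[0])
        if report_selection is None
        else np.asarray(report_selection, int)
    )
    if rep.size == 0:
        raise ValueError("empty report selection")
    diff = mobile[rep] - reference[rep]
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rmsd_profile(
    ensemble: ConformationalEnsemble,
    reference: ConformationalEnsemble | np.ndarray,
    ref_model: int = 0,
    fit_residues: tuple[int, int] | None = None,
    report_residues: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-model RMSD of an ensemble against a reference conformation.

    The reference is the ``ref_model``-th model of a reference ensemble (or a
    raw coordinate array on the same residue frame).  Each model is superposed
    over ``fit_residues`` (a 1-based inclusive residue-id interval; default all
    shared residues) and the RMSD is reported over ``report_residues`` (default
    the full chain) — e.g. a loop-restricted RMSD fits on the whole chain and
    reports on the loop.
    """
    if isinstance(reference, ConformationalEnsemble):
        shared = np.intersect1d(ensemble.residue_ids, reference.residue_ids)
        if shared.size == 0:
            raise ValueError("ensemble and reference share no residues")
        mob = ensemble.subset_residues(shared)
        ref_coords = reference.subset_residues(shared).coords[ref_model]
        ids = shared
    else:
        ref_coords = np.asarray(reference, float)
        if ref_coords.shape != (ensemble.n_residues, 3):
            raise ValueError("reference coordinate array does not match the ensemble")
        mob = ensemble
        ids = ensemble.residue_ids

    def interval_index(interval):
        if interval is None:
            return None
        lo, hi = interval
        idx = np.flatnonzero((ids >= lo) & (ids <= hi))
        if idx.size == 0:
            raise ValueError(f"no residues of the ensemble fall in {lo}-{hi}")
        return idx

    fit_idx = interval_index(fit_residues)
    rep_idx = interval_index(report_residues)
    return np.array(
        [
            rmsd(mob.coords[m], ref_coords, fit_selection=fit_idx, report_selection=rep_idx)
            for m in range(mob.n_models)
        ]
    )


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def _tm_d0(length: int) -> float:
    return max(0.5, 1.24 * np.cbrt(length - 15) - 1.8)


def _tm_from_superposition(mobile, reference, sel, d0):
    sup = superpose(mobile, reference, sel)
    d = np.linalg.norm(sup.apply(mobile) - reference, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d


def tm_score(model: np.ndarray, reference: np.ndarray, same_fold_threshold: float = 0.5):
    """Template-modeling score between two conformations of one sequence.

    TM = max over superpositions of (1/L) Σ 1 / (1 + (d_i/d0)²), with the
    length-dependent scale d0 = 1.24·(L−15)^(1/3) − 1.8 (floored at 0.5) and L
    the reference chain length.  The maximization is the standard iterative
    protocol: seed superpositions from contiguous fragments of decreasing
    length, then refine each by repeatedly re-fitting on the residues currently
    within a distance cutoff.  Residues are matched by position (same protein,
    no alignment step).

    Returns ``(score, same_fold)`` where ``same_fold`` flags score > 0.5, the
    conventional shared-fold threshold.
    """
    model = np.asarray(model, float)
    reference = np.asarray(reference, float)
    if model.shape != reference.shape:
        raise ValueError("model and reference must be residue-matched, equal length")
    n = model.shape[0]
    if n < 3:
        raise ValueError("TM-score needs at least 3 residues")
    d0 = _tm_d0(n)

    best = 0.0
    frag_lengths = []
    length = n
    while length >= 4:
        frag_lengths.append(length)
        length //= 2
    for fl in frag_lengths:
        starts = range(0, n - fl + 1, max(1, fl // 2))
        for s in starts:
            sel = np.arange(s, s + fl)
            try:
                score, d = _tm_from_superposition(model, reference, sel, d0)
            except ValueError:  # collinear fragment seed
                continue
            best = max(best, score)
            # iterative refinement on the currently well-fit residues
            for cutoff in (d0 + 1.0, d0 + 0.5, d0):
                prev_sel = None
                for _ in range(20):
                    new_sel = np.flatnonzero(d < cutoff)
                    if new_sel.size < 3 or (
                        prev_sel is not None and np.array_equal(new_sel, prev_sel)
                    ):
                        break
                    prev_sel = new_sel
                    try:
                        score, d = _tm_from_superposition(model, reference, new_sel, d0)
                    except ValueError:
                        break
                    best = max(best, score)
    if best == 0.0:
        raise ValueError("TM-score optimization found no valid superposition")
    return best, best > same_fold_threshold


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

@dataclass
class StateClassification:
    """Nearest-reference-state assignment of every model of an ensemble."""

    labels: list[str]                  # per-model assigned state or "unassigned"
    rmsd_table: pd.DataFrame           # per-model RMSD to each reference state
    populations: dict[str, float]      # fractions over all models (sum to 1)
    rmsd_threshold: float

    def to_frame(self) -> pd.DataFrame:
        out = self.rmsd_table.copy()
        out["label"] = self.labels
        return out


def _label_sort_key(label: str):
    try:
        return (0, STATE_ORDER.index(label))
    except ValueError:
        return (1, label)


def classify_states(
    ensemble: ConformationalEnsemble,
    references: dict[str, ConformationalEnsemble],
    rmsd_threshold: float = 1.5,
) -> StateClassification:
    """Label each model by its nearest reference state.

    The RMSD of every model to the first conformation of each reference
    ensemble is computed after whole-chain superposition; a model is assigned
    the nearest state only if that RMSD is below ``rmsd_threshold`` (default
    1.5 Å, the conventional "close to a state" cut), otherwise "unassigned".
    Exact ties (within 1e-9 Å) are broken in the fixed order active > I1 > I2.
    """
    if not references:
        raise ValueError("no reference states given")
    names = sorted(references, key=_label_sort_key)
    table = {name: rmsd_profile(ensemble, references[name]) for name in names}
    df = pd.DataFrame(table, columns=names)

    labels: list[str] = []
    for m in range(ensemble.n_models):
        row = df.iloc[m]
        best = float(row.min())
        if best < rmsd_threshold:
            # ties within 1e-9 resolve to the earliest name in the fixed order
            winner = next(name for name in names if row[name] <= best + 1e-9)
            labels.append(winner)
        else:
            labels.append("unassigned")
    counts = pd.Series(labels).value_counts()
    populations = {
        name: float(counts.get(name, 0)) / ensemble.n_models
        for name in [*names, "unassigned"]
    }
    return StateClassification(labels, df, populations, rmsd_threshold)


# ---------------------------------------------------------------------------
# Density summaries (pLDDT / RMSD / TM distributions)
# ---------------------------------------------------------------------------

def density_summary(values: np.ndarray, grid: np.ndarray | None = None):
    """Gaussian-kernel density estimate of a 1-D sample (Scott's bandwidth).

    Returns ``(grid, density)``.  An all-identical sample has no meaningful
    bandwidth; it yields a delta-like spike at the common value with a warning.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("density estimation needs at least 2 finite values")
    if np.ptp(values) == 0.0:
        logger.warning("all values identical; returning a degenerate delta-like density")
        v = values[0]
        if grid is None:
            grid = np.linspace(v - 1.0, v + 1.0, 201)
        density = np.zeros_like(grid, dtype=float)
        j = int(np.argmin(np.abs(grid - v)))
        step = grid[1] - grid[0] if grid.size > 1 else 1.0
        density[j] = 1.0 / step
        return grid, density
    kde = gaussian_kde(values, bw_method="scott")
    if grid is None:
        pad = 3.0 * values.std()
        grid = np.linspace(values.min() - pad, values.max() + pad, 512)
    return grid, kde(grid)


# ---------------------------------------------------------------------------
# Shared helper: iterative superposition to a converged mean structure
# ---------------------------------------------------------------------------

def iterative_mean_structure(
    coords: np.ndarray, max_iter: int = 10, tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all models onto an iteratively refined mean structure.

    Starting from the first model as reference, repeatedly (i) superpose every
    model onto the current mean and (ii) update the mean, until the mean moves
    by less than ``tol`` Å (RMS) or ``max_iter`` iterations.  A final pass
    aligns every original model onto the converged mean, so re-aligning to the
    returned mean is idempotent.

    Returns ``(aligned_coords, mean_structure)``.
    """
    coords = np.asarray(coords, float)
    n_models = coords.shape[0]
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = np.stack([superpose(coords[m], mean).apply(coords[m]) for m in range(n_models)])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    aligned = np.stack([superpose(coords[m], mean).apply(coords[m]) for m in range(n_models)])
    return aligned, mean
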