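"""Dynamic cross-correlation, generalized correlation and contact persistence.

The dynamic cross-correlation (DCC) between residues i and j is the normalized
covariance of their Cα displacement vectors over the ensemble,

    C_ij = <Δr_i · Δr_j> / sqrt(<Δr_i²> <Δr_j²>)  ∈ [-1, 1],

so that C_ii = 1.  The generalized correlation (GC) of Lange & Grubmüller maps
the mutual information I between the 3-D displacement vectors onto a
correlation-like scale,

    R(X_i, X_j) = sqrt(1 − exp(−2 I_ij / 3))  ∈ [0, 1],

capturing non-linear dependence; for jointly Gaussian motions GC is at least
the magnitude of the linear DCC.  Contact persistence is the fraction of
models in which a residue pair stays within a distance cutoff; persistent
pairs become the edges of the residue interaction network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .ensemble import ConformationalEnsemble
from .metrics import iterative_mean_structure

logger = logging.getLogger("alloscan")

__all__ = [
    "CorrelationMatrix",
    "PersistenceMatrix",
    "dcc_matrix",
    "gc_matrix",
    "contact_persistence",
    "gaussian_mutual_information",
]

_VAR_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric residue x residue correlation matrix (kind 'dcc' or 'gc')."""

    residue_ids: np.ndarray
    matrix: np.ndarray
    kind: str                      # {"dcc", "gc"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = self.residue_ids.size
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match residue ids")


@dataclass
class PersistenceMatrix:
    """Fraction of models in which each residue pair is within the cutoff."""

    residue_ids: np.ndarray
    fractions: np.ndarray
    cutoff: float
    min_fraction: float

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean contact adjacency: persistent, non-covalent pairs only."""
        adj = self.fractions >= self.min_fraction
        n = self.residue_ids.size
        # |i-j| <= 1 pairs are covalently linked, not non-covalent contacts
        seq_sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        adj &= seq_sep > 1
        return adj


def _displacements(ensemble: ConformationalEnsemble, superpose: bool) -> np.ndarray:
    coords = ensemble.coords
    if superpose:
        coords, _ = iterative_mean_structure(coords)
    return coords - coords.mean(axis=0, keepdims=True)


def dcc_matrix(ensemble: ConformationalEnsemble, superpose: bool = True) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix of Cα displacements.

    With ``superpose=True`` (default) models are first aligned to the
    iteratively refined mean structure, removing rigid-body motion; disable it
    for data already expressed in a common frame.  Residues with zero
    displacement variance get C = 0 off-diagonal (with a warning) and 1 on the
    diagonal.
    """
    if ensemble.n_models < 2:
        raise ValueError("DCC needs at least 2 models")
    disp = _displacements(ensemble, superpose)
    inner = np.einsum("mia,mja->ij", disp, disp) / ensemble.n_models
    var = np.diag(inner).copy()
    dead = var <= _VAR_TOL
    if np.any(dead):
        logger.warning("%d residue(s) have zero displacement variance; C set to 0", dead.sum())
        var[dead] = 1.0
    denom = np.sqrt(np.outer(var, var))
    c = inner / denom
    c[dead, :] = 0.0
    c[:, dead] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrelationMatrix(ensemble.residue_ids.copy(), c, "dcc", {"superposed": superpose})


# ---------------------------------------------------------------------------
# Generalized correlation
# ---------------------------------------------------------------------------

def gaussian_mutual_information(rho: float, d: int = 1) -> float:
    """Closed-form MI of two jointly Gaussian vectors with d independent
    axes, each pair correlated at ``rho``: I = −(d/2)·ln(1 − rho²)."""
    return -0.5 * d * np.log(1.0 - rho**2)


def _gaussian_mi_matrix(disp: np.ndarray) -> np.ndarray:
    """Pairwise Gaussian MI between per-residue 3-D displacement vectors."""
    n_models, n_res, _ = disp.shape
    cross = np.einsum("mia,mjb->ijab", disp, disp) / (n_models - 1)  # (N, N, 3, 3)
    marg = cross[np.arange(n_res), np.arange(n_res)]                 # (N, 3, 3)
    det_marg = np.linalg.det(marg)

    joint = np.empty((n_res, n_res, 6, 6))
    joint[:, :, :3, :3] = marg[:, None]
    joint[:, :, 3:, 3:] = marg[None, :]
    joint[:, :, :3, 3:] = cross
    joint[:, :, 3:, :3] = np.swapaxes(cross, 2, 3)
    det_joint = np.linalg.det(joint)

    prod = np.outer(det_marg, det_marg)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = 0.5 * np.log(prod / det_joint)
    mi[~np.isfinite(mi)] = np.inf  # singular joint covariance => full dependence
    bad = (det_marg <= _VAR_TOL)
    mi[bad, :] = 0.0
    mi[:, bad] = 0.0
    if np.any(bad):
        logger.warning("%d residue(s) have singular marginal covariance; R set to 0", bad.sum())
    return np.clip(mi, 0.0, None)


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Kraskov-Stögbauer-Grassberger (algorithm 1) MI estimate, nats."""
    n = x.shape[0]
    z = np.hstack([x, y])
    tree_z = cKDTree(z)
    # distance to the k-th neighbour in the joint space (Chebyshev metric)
    eps = tree_z.query(z, k=k + 1, p=np.inf)[0][:, -1]
    tree_x, tree_y = cKDTree(x), cKDTree(y)
    nx = np.array([len(tree_x.query_ball_point(x[i], eps[i] * (1 - 1e-12), p=np.inf)) - 1 for i in range(n)])
    ny = np.array([len(tree_y.query_ball_point(y[i], eps[i] * (1 - 1e-12), p=np.inf)) - 1 for i in range(n)])
    return float(digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1)))


def gc_matrix(
    ensemble: ConformationalEnsemble,
    estimator: str = "gaussian",
    superpose: bool = True,
    k: int = 4,
) -> CorrelationMatrix:
    """Generalized correlation matrix R = sqrt(1 − exp(−2 I / 3)).

    ``estimator="gaussian"`` computes the mutual information analytically from
    the 6x6 joint displacement covariance of each residue pair — robust at the
    ~70-model ensemble sizes typical of one prediction run (needs >= 5 models).
    ``estimator="knn"`` uses the Kraskov k-NN estimator (k=4 by default) and
    captures non-linear dependence, but needs >= 30 models.
    """
    if estimator == "gaussian":
        if ensemble.n_models < 5:
            raise ValueError("gaussian GC estimator needs at least 5 models")
    elif estimator == "knn":
        if ensemble.n_models < 30:
            raise ValueError("knn GC estimator needs at least 30 models")
    else:
        raise ValueError(f"unknown estimator {estimator!r} (use 'gaussian' or 'knn')")

    disp = _displacements(ensemble, superpose)
    n_res = ensemble.n_residues
    if estimator == "gaussian":
        mi = _gaussian_mi_matrix(disp)
    else:
        mi = np.zeros((n_res, n_res))
        for i in range(n_res):
            for j in range(i + 1, n_res):
                mi[i, j] = mi[j, i] = max(0.0, _ksg_mi(disp[:, i, :], disp[:, j, :], k))

    with np.errstate(over="ignore"):
        r = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        ensemble.residue_ids.copy(), r, "gc",
        {"estimator": estimator, "superposed": superpose, "k": k},
    )


# ---------------------------------------------------------------------------
# Contact persistence
# ---------------------------------------------------------------------------

def contact_persistence(
    ensemble: ConformationalEnsemble,
    cutoff: float = 5.0,
    min_fraction: float = 0.75,
) -> PersistenceMatrix:
    """Fraction of models in which each Cα pair lies within ``cutoff`` Å.

    The derived adjacency keeps pairs persistent in at least ``min_fraction``
    of the models, excluding sequence neighbours (|i−j| <= 1), which are
    covalently linked rather than non-covalent contacts.  The 5 Å default
    follows the usual side-chain contact convention; for Cα-only traces a
    7-8 Å cutoff is the common recommendation.
    """
    if ensemble.n_models < 1:
        raise ValueError("need at least one model")
    n = ensemble.n_residues
    counts = np.zeros((n, n))
    for m in range(ensemble.n_models):
        d = np.linalg.norm(
            ensemble.coords[m][:, None, :] - ensemble.coords[m][None, :, :], axis=-1
        )
        counts += d <= cutoff
    frac = counts / ensemble.n_models
    np.fill_diagonal(frac, 1.0)
    return PersistenceMatrix(ensemble.residue_ids.copy(), frac, cutoff, min_fraction)
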