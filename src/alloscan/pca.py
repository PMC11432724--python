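"""PCA of Cartesian Cα coordinates with projection onto common components.

The analysis fits principal components on a merged reference ensemble (for a
protein: the wild-type ensemble across its states), then projects any other
ensemble of the same residue frame onto those components, so experimentally
derived and predicted ensembles land in one shared coordinate system and can
be compared directly.

Rigid-body motion is removed before the covariance is formed: all models are
superposed onto an iteratively refined mean structure.  Low-confidence models
(mean pLDDT < 70) are excluded from the fit when a confidence track is
present, since partially disordered predictions would otherwise dominate the
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .ensemble import ConformationalEnsemble, filter_by_confidence
from .metrics import superpose, iterative_mean_structure

logger = logging.getLogger("alloscan")

__all__ = ["PCAModel", "fit_reference_pca", "project", "state_overlap"]


@dataclass
class PCAModel:
    """Principal components of superposed Cα coordinate fluctuations."""

    residue_ids: np.ndarray
    align_reference: np.ndarray   # (n_res, 3) structure models are superposed onto
    mean_flat: np.ndarray         # (3 n_res,) centering vector in the aligned frame
    eigenvectors: np.ndarray      # (k, 3 n_res), orthonormal rows, descending
    eigenvalues: np.ndarray       # (k,), Å², descending, non-negative
    provenance: list[str]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def fit_reference_pca(
    ensemble: ConformationalEnsemble,
    confidence_threshold: float | None = 70.0,
) -> PCAModel:
    """Fit principal components on a (merged) reference ensemble.

    Models with mean confidence below ``confidence_threshold`` are dropped
    first when the ensemble carries a confidence track (pass ``None`` to keep
    everything).  All remaining models are superposed onto the converged mean
    structure; the covariance of the flattened coordinates is then
    eigendecomposed.  Each eigenvector's sign is fixed so its largest-magnitude
    component is positive, making downstream plots reproducible.
    """
    if ensemble.confidence is not None and confidence_threshold is not None:
        ensemble = filter_by_confidence(ensemble, confidence_threshold)
    if ensemble.n_models < 3:
        raise ValueError("PCA needs at least 3 models after filtering")

    # tight convergence so the alignment reference and the score-space origin
    # coincide to well below reporting precision
    aligned, mean_structure = iterative_mean_structure(ensemble.coords, max_iter=50, tol=1e-9)
    x = aligned.reshape(ensemble.n_models, -1)
    mean_flat = x.mean(axis=0)
    xc = x - mean_flat

    # SVD of the centered data is cheaper than the full 3N x 3N covariance
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (ensemble.n_models - 1)
    eigenvectors = vt
    # deterministic sign convention
    for i in range(eigenvectors.shape[0]):
        j = int(np.argmax(np.abs(eigenvectors[i])))
        if eigenvectors[i, j] < 0:
            eigenvectors[i] *= -1.0
    return PCAModel(
        residue_ids=ensemble.residue_ids.copy(),
        align_reference=mean_structure,
        mean_flat=mean_flat,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        provenance=list(ensemble.labels),
    )


def project(
    ensemble: ConformationalEnsemble,
    model: PCAModel,
    n_components: int = 2,
) -> pd.DataFrame:
    """Project an ensemble onto the leading components of a fitted PCA model.

    Each model is superposed onto the PCA alignment reference, centered with
    the PCA mean, and projected; residue frames must match exactly.  Returns a
    DataFrame with one row per model (columns ``PC1..PCk`` plus ``label``).
    """
    if not np.array_equal(ensemble.residue_ids, model.residue_ids):
        raise ValueError("ensemble residue ids do not match the PCA model's")
    n_components = min(n_components, model.eigenvectors.shape[0])
    scores = np.empty((ensemble.n_models, n_components))
    for m in range(ensemble.n_models):
        fitted = superpose(ensemble.coords[m], model.align_reference).apply(ensemble.coords[m])
        scores[m] = model.eigenvectors[:n_components] @ (fitted.ravel() - model.mean_flat)
    out = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(n_components)])
    out["label"] = list(ensemble.labels)
    return out


def state_overlap(scores: pd.DataFrame, confidence_level: float = 0.95) -> pd.DataFrame:
    """Pairwise overlap of labelled groups in component space.

    For each ordered pair (A, B): the fraction of A's points lying inside the
    ``confidence_level`` Gaussian ellipse of B (Mahalanobis distance within
    the chi-square quantile for the score dimensionality).  Identical groups
    score ~0.95 by construction; well-separated groups score ~0.
    """
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    groups = {name: g[pc_cols].to_numpy(float) for name, g in scores.groupby("label")}
    if len(groups) < 2:
        raise ValueError("state_overlap needs at least 2 labelled groups")
    for name, pts in groups.items():
        if pts.shape[0] < 5:
            raise ValueError(f"group {name!r} has fewer than 5 points")
    q = chi2.ppf(confidence_level, df=len(pc_cols))

    rows = []
    for a, pa in groups.items():
        for b, pb in groups.items():
            if a == b:
                continue
            mu = pb.mean(axis=0)
            cov = np.cov(pb.T)
            cov = np.atleast_2d(cov)
            if np.linalg.det(cov) <= 1e-300:
                raise ValueError(f"group {b!r} has a degenerate (zero-variance) spread")
            inv = np.linalg.inv(cov)
            d2 = np.einsum("ni,ij,nj->n", pa - mu, inv, pa - mu)
            rows.append({"group": a, "reference": b, "overlap": float(np.mean(d2 <= q))})
    return pd.DataFrame(rows)
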