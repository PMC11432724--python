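"""Synthetic multi-state kinase-like ensembles and planted-correlation fixtures.

Every downstream stage of the pipeline (classification, PCA, correlation,
network analysis) is exercised on ensembles produced here, so no structure
prediction runs or database downloads are needed to test the analysis code.

The generator emulates, in idealized form, the situation of a kinase domain
observed in three conformational states: a shared Cα backbone with one loop
segment (the "activation loop" analogue) rigidly displaced per state, plus
isotropic Gaussian coordinate noise.  Chains are Cα-only traces on a smooth
helix-like parametric curve — every downstream metric operates on Cα atoms, so
side-chain realism adds nothing that these tests could detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import ConformationalEnsemble

logger = logging.getLogger("alloscan")

__all__ = [
    "ReferenceState",
    "MixtureSpec",
    "PlantedNetworkSpec",
    "ConfidenceProfile",
    "helix_backbone",
    "generate_reference_states",
    "generate_mixture_ensemble",
    "generate_correlated_ensemble",
    "assign_confidence",
    "DEFAULT_DISPLACEMENTS",
]

#: Canonical state labels, in tie-break / generation order.
STATE_LABELS = ("active", "I1", "I2")

#: Default rigid loop displacements (Å) defining the three states.  The
#: magnitudes are chosen so that, after whole-chain superposition, any two
#: state means differ by ~2-3 Å RMSD — comparable to the separation between
#: active and inactive kinase conformations — while per-model noise keeps
#: within-state RMSD well under the 1.5 Å classification cut.
DEFAULT_DISPLACEMENTS: dict[str, tuple[float, float, float]] = {
    "active": (0.0, 0.0, 0.0),
    "I1": (0.0, 8.0, 0.0),
    "I2": (8.0, 0.0, 5.0),
}


def helix_backbone(n_residues: int, first_residue_id: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Cα trace on an α-helix-like parametric curve.

    Radius 2.3 Å, 100° twist and 1.5 Å rise per residue give the canonical
    ~3.8 Å Cα-Cα spacing.  Returns ``(residue_ids, coords)``.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    i = np.arange(n_residues)
    theta = np.deg2rad(100.0) * i
    coords = np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )
    residue_ids = first_residue_id + i
    return residue_ids, coords


# ---------------------------------------------------------------------------
# Reference states
# ---------------------------------------------------------------------------

@dataclass
class ReferenceState:
    """One conformational state: a reference ensemble plus its defining loop shift."""

    label: str
    ensemble: ConformationalEnsemble
    loop_span: tuple[int, int]           # positional interval, 1-based inclusive
    displacement: np.ndarray             # loop translation vector, Å


def generate_reference_states(
    n_residues: int = 287,
    loop_span: tuple[int, int] = (154, 177),
    displacements: dict[str, tuple[float, float, float]] | None = None,
    n_models: int = 20,
    noise_sd: float = 0.3,
    seed: int = 0,
    first_residue_id: int = 1,
) -> dict[str, ReferenceState]:
    """Generate the three reference-state ensembles (active, I1, I2).

    All states share one backbone; each state rigidly translates the residues
    in ``loop_span`` (a 1-based inclusive interval of chain positions) by its
    displacement vector, then adds isotropic Gaussian noise of ``noise_sd`` Å
    per coordinate to every model.  Defaults mirror the experimental setting
    being emulated: a 287-residue kinase domain observed as 20-model ensembles
    per state, with the conformational change confined to one loop (the
    default span sits where the activation loop falls in that domain).

    Deterministic for a fixed ``seed``.
    """
    lo, hi = loop_span
    if not (1 <= lo <= hi <= n_residues):
        raise ValueError(
            f"loop_span {loop_span} outside the chain positions [1, {n_residues}]"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if displacements is None:
        displacements = DEFAULT_DISPLACEMENTS
    if set(displacements) != set(STATE_LABELS):
        raise ValueError(f"displacements must cover exactly the states {STATE_LABELS}")

    residue_ids, base = helix_backbone(n_residues, first_residue_id)
    loop_idx = np.arange(lo - 1, hi)
    rng = np.random.default_rng(seed)

    states: dict[str, ReferenceState] = {}
    for label in STATE_LABELS:
        shift = np.asarray(displacements[label], float)
        mean = base.copy()
        mean[loop_idx] += shift
        coords = mean[None, :, :] + rng.normal(0.0, noise_sd, size=(n_models, n_residues, 3))
        ens = ConformationalEnsemble(
            residue_ids=residue_ids,
            coords=coords,
            labels=[label] * n_models,
        )
        states[label] = ReferenceState(label, ens, (lo, hi), shift)
    return states


# ---------------------------------------------------------------------------
# Mixture ensembles (population-shift ground truth)
# ---------------------------------------------------------------------------

@dataclass
class MixtureSpec:
    """A state mixture with known populations — ground truth for recovery tests.

    The default ``n_models`` of 70 mirrors the output size of one prediction
    run (5 models x 14 recycled structures).
    """

    populations: dict[str, float]
    n_models: int = 70
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1 (got {total})")
        if any(not (0.0 <= p <= 1.0) for p in self.populations.values()):
            raise ValueError("population fractions must lie in [0, 1]")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def generate_mixture_ensemble(
    spec: MixtureSpec, references: dict[str, ReferenceState]
) -> tuple[ConformationalEnsemble, list[str]]:
    """Draw a labelled mixture ensemble from reference states.

    Each model slot samples a state from ``spec.populations``, picks one model
    of that state's reference ensemble uniformly, and adds fresh isotropic
    noise of ``spec.noise_sd`` Å.  Returns the ensemble together with the true
    per-model state labels (also stored as the ensemble's provenance labels).
    """
    missing = [s for s in spec.populations if s not in references]
    if missing:
        raise ValueError(f"missing reference state(s): {missing}")
    labels_pool = sorted(spec.populations, key=lambda s: STATE_LABELS.index(s) if s in STATE_LABELS else 99)
    probs = np.array([spec.populations[s] for s in labels_pool])
    rng = np.random.default_rng(spec.seed)

    first = references[labels_pool[0]].ensemble
    coords = np.empty((spec.n_models, first.n_residues, 3))
    labels: list[str] = []
    for i in range(spec.n_models):
        state = labels_pool[rng.choice(len(labels_pool), p=probs)]
        ref = references[state].ensemble
        m = int(rng.integers(ref.n_models))
        coords[i] = ref.coords[m] + rng.normal(0.0, spec.noise_sd, size=(first.n_residues, 3))
        labels.append(state)
    ens = ConformationalEnsemble(first.residue_ids.copy(), coords, labels=list(labels))
    return ens, labels


# ---------------------------------------------------------------------------
# Planted-correlation / planted-bridge ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlantedNetworkSpec:
    """Blueprint for an ensemble with planted motion communities and bridges.

    Nodes (residues) are split into consecutive blocks (``community_sizes``);
    displacement correlations are ``intra_corr`` within a block, ``inter_corr``
    across blocks, and ``bridge_corr`` between a bridge node and members of the
    two blocks it joins.  Geometrically each block is a compact cluster with
    contacts inside the block only; every node listed in ``bridge_nodes``
    (0-based global index) is repositioned between its own block and the next
    one so it is the sole contact path joining them.
    """

    community_sizes: list[int]
    bridge_nodes: list[int] = field(default_factory=list)
    intra_corr: float = 0.5
    inter_corr: float = 0.0
    bridge_corr: float = 0.3
    amplitude: float = 0.3   # displacement SD per coordinate, Å

    def __post_init__(self) -> None:
        n = sum(self.community_sizes)
        for c in (self.intra_corr, self.inter_corr, self.bridge_corr):
            if not (0.0 <= c < 1.0):
                raise ValueError("correlation levels must lie in [0, 1)")
        for b in self.bridge_nodes:
            if not (0 <= b < n):
                raise ValueError(f"bridge node {b} outside the node set (0..{n - 1})")

    @property
    def n_nodes(self) -> int:
        return sum(self.community_sizes)

    def community_of(self, node: int) -> int:
        edge = 0
        for k, size in enumerate(self.community_sizes):
            edge += size
            if node < edge:
                return k
        raise ValueError(node)

    def membership(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.community_sizes)), self.community_sizes)


def _cluster_layout(spec: PlantedNetworkSpec, spacing: float = 3.0, gap: float = 6.0) -> np.ndarray:
    """Place each community on a compact 3-D grid; clusters in a row along x.

    With 3.0 Å grid spacing the axis (3.0 Å) and face-diagonal (4.24 Å)
    neighbours sit safely inside the conventional 5 Å contact cutoff while the
    cube diagonal (5.20 Å) stays outside it, so every cluster is densely
    connected through non-covalent (non-consecutive-index) contacts even
    though consecutive-index pairs are excluded downstream.  Facing planes of
    consecutive clusters are ``gap`` Å apart: no direct cluster-to-cluster
    contact.
    """
    coords = np.zeros((spec.n_nodes, 3))
    x_offset = 0.0
    node = 0
    for size in spec.community_sizes:
        side = int(np.ceil(size ** (1.0 / 3.0)))
        positions = []
        for j in range(size):
            ix, rem = divmod(j, side * side)
            iy, iz = divmod(rem, side)
            positions.append((ix, iy, iz))
        positions = np.array(positions, float) * spacing
        extent = positions[:, 0].max()
        positions[:, 0] += x_offset
        coords[node : node + size] = positions
        node += size
        x_offset += extent + gap
    return coords


def _place_bridges(spec: PlantedNetworkSpec, coords: np.ndarray) -> None:
    """Move each bridge node to the midpoint between its block and the next.

    The bridge sits at the midpoint of the closest facing node pair, half the
    inter-cluster gap (3 Å) from each facing plane: within contact range of
    the aligned node and its in-plane axis neighbours on *both* sides, while
    the clusters themselves stay out of direct contact.  Every inter-cluster
    path therefore runs through the bridge node, which spreads its traffic
    over several anchors per side — the bridge, not any single anchor, ends
    up the most central node.
    """
    membership = spec.membership()
    for b in spec.bridge_nodes:
        own = spec.community_of(b)
        if own >= len(spec.community_sizes) - 1:
            raise ValueError(
                f"bridge node {b} lies in the last community and has no neighbour to bridge"
            )
        nxt = own + 1

        members_own = [i for i in np.flatnonzero(membership == own) if abs(i - b) > 1]
        members_nxt = [i for i in np.flatnonzero(membership == nxt) if abs(i - b) > 1]
        if not members_own or not members_nxt:
            raise ValueError(f"communities around bridge {b} too small to anchor it")
        # anchors = the closest facing pair, so the bridge midpoint lands within
        # contact range of exactly one node on each side
        a_own, a_next = min(
            ((i, j) for i in members_own for j in members_nxt),
            key=lambda ij: float(np.linalg.norm(coords[ij[0]] - coords[ij[1]])),
        )
        coords[b] = 0.5 * (coords[a_own] + coords[a_next])


def _planted_correlation(spec: PlantedNetworkSpec) -> np.ndarray:
    membership = spec.membership()
    same = membership[:, None] == membership[None, :]
    corr = np.where(same, spec.intra_corr, spec.inter_corr)
    for b in spec.bridge_nodes:
        own = spec.community_of(b)
        linked = (membership == own) | (membership == own + 1)
        corr[b, linked] = spec.bridge_corr
        corr[linked, b] = spec.bridge_corr
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_correlated_ensemble(
    spec: PlantedNetworkSpec, n_models: int = 500, seed: int = 0
) -> ConformationalEnsemble:
    """Ensemble whose per-residue displacements follow the planted correlations.

    Displacements are drawn per coordinate axis from N(0, amplitude² · Σ) with
    Σ the planted correlation matrix, so the dynamic cross-correlation of the
    generated motions equals the planted levels in expectation.  The rigid
    geometry guarantees persistent contacts within communities and through the
    bridge nodes only.  The implied covariance must be positive semi-definite;
    violations are rejected with a diagnostic.
    """
    corr = _planted_correlation(spec)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-8:
        # name the offending block to make the failure actionable
        membership = spec.membership()
        culprit = "full matrix"
        for k in range(len(spec.community_sizes)):
            block = corr[np.ix_(membership == k, membership == k)]
            if np.linalg.eigvalsh(block).min() < -1e-8:
                culprit = f"community {k} block"
                break
        raise ValueError(
            f"planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g}; offending part: {culprit})"
        )

    coords0 = _cluster_layout(spec)
    _place_bridges(spec, coords0)

    # symmetric square root handles the PSD-but-singular case cleanly
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(seed)
    disp = np.einsum(
        "ij,mja->mia", root, rng.normal(size=(n_models, spec.n_nodes, 3))
    ) * spec.amplitude
    coords = coords0[None, :, :] + disp
    return ConformationalEnsemble(
        residue_ids=np.arange(1, spec.n_nodes + 1),
        coords=coords,
        labels=["planted"] * n_models,
    )


# ---------------------------------------------------------------------------
# Confidence tracks
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceProfile:
    """Per-residue confidence layout on the pLDDT 0-100 scale.

    Core residues draw uniformly from ``core_range`` (default 80-100) and loop
    residues from ``loop_range`` (default 65-85, the moderately-reduced band
    typical of flexible activation loops).  Models listed in ``low_models``
    instead draw all residues from ``low_range`` (default 40-60), giving a
    known count of models whose mean falls below the conventional 70 filter.
    """

    core_range: tuple[float, float] = (80.0, 100.0)
    loop_span: tuple[int, int] | None = None   # positional, 1-based inclusive
    loop_range: tuple[float, float] = (65.0, 85.0)
    low_models: list[int] = field(default_factory=list)
    low_range: tuple[float, float] = (40.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.core_range, self.loop_range, self.low_range):
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"confidence range ({lo}, {hi}) outside [0, 100]")


def assign_confidence(
    ensemble: ConformationalEnsemble, profile: ConfidenceProfile
) -> ConformationalEnsemble:
    """Return a copy of the ensemble with a synthetic confidence track attached.

    Values are rounded to 2 decimals so a round trip through the PDB B-factor
    column (fixed 2-decimal field) is lossless.
    """
    rng = np.random.default_rng(profile.seed)
    n_models, n_res = ensemble.n_models, ensemble.n_residues
    conf = rng.uniform(*profile.core_range, size=(n_models, n_res))
    if profile.loop_span is not None:
        lo, hi = profile.loop_span
        if not (1 <= lo <= hi <= n_res):
            raise ValueError(f"loop_span {profile.loop_span} outside [1, {n_res}]")
        conf[:, lo - 1 : hi] = rng.uniform(*profile.loop_range, size=(n_models, hi - lo + 1))
    for m in profile.low_models:
        if not (0 <= m < n_models):
            raise ValueError(f"low_models index {m} outside the ensemble")
        conf[m] = rng.uniform(*profile.low_range, size=n_res)
    conf = np.round(conf, 2)
    return ConformationalEnsemble(
        residue_ids=ensemble.residue_ids.copy(),
        coords=ensemble.coords.copy(),
        confidence=conf,
        labels=list(ensemble.labels),
    )
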