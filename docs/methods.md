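# Methods

This note records the models, estimators and numerical conventions behind
`alloscan`, the design choices made where the design was genuinely open, and
what the synthetic study conditions do and do not establish about real data.

## Sequence masking model

Masking operates per position: for each eligible position `i` a probability
`p_i ~ U(p_min, p_max)` is drawn (defaults 0.05 and 0.15) and the residue is
replaced by alanine with probability `p_i`. The protocol is sometimes phrased
instead as "substitute 5–15% of the residues", i.e. a rate drawn per
sequence; the two differ in the variance of realized rates (per-position
draws concentrate the rate near the 10% midpoint, a per-sequence rate spreads
it across the whole band). We adopt the per-position form as the more
explicit description and record the realized rate of every variant so users
can see the distribution they actually got. Positions whose native residue
is already alanine remain eligible; a draw there changes nothing but is
recorded as an identity substitution, keeping the rate accounting exact.
Targeted mode restricts eligibility to user intervals (1-based, inclusive —
the convention for every interval in this package). Ten variants per run is
the default (typical practice is ~10–50).

Job planning is pure arithmetic: each of `n_models` (default 5) pretrained
model heads emits one structure per recycle `0..num_recycles` plus a final
refined structure, per random seed — `num_recycles + 2` structures per model,
70 per sequence at the defaults (12 recycles, 1 seed). The MSA subsampling
depths `max_seqs:extra_seqs` (default `16:32`, the depth that maximizes
ensemble diversity in practice) are not used in any computation here; they
are provenance echoed into the manifest for the external runner.

## Ensembles, confidence, classification

An ensemble is an ordered set of Cα-trace models over one residue-id frame;
correspondence across ensembles is by author residue id, never by sequence
alignment, since all ensembles in scope share a single numbering frame.
Model-level confidence is the unweighted mean of per-residue values (the
aggregation is a community convention; nothing downstream is sensitive to
mean-vs-median at the 70 threshold given the bimodal tracks we generate).
On disk, confidence lives in the PDB B-factor column (2 decimals); an
all-zero column reads back as "no confidence recorded" rather than as
confidence 0.

Superposition is a Kabsch least-squares fit with reflections excluded;
collinear selections are rejected as ill-posed. RMSD against a reference
state uses the *first* model of the reference ensemble, the usual convention
for NMR-style ensembles; region-restricted RMSD fits on the whole chain and
reports on the region (both selections configurable). The activation-loop
interval defaults to 398–421 in the kinase numbering frame; figure
conventions elsewhere occasionally use 395–421, so the interval is a
parameter. TM-score uses reference length for `d0` and the standard
iterative protocol (fragment-seeded superpositions of decreasing length,
refined on the residues within a distance cutoff); same-sequence pairs need
no alignment step. Classification assigns each model to its nearest
reference state only when that RMSD is below the threshold (default 1.5 Å),
else "unassigned"; exact ties (1e-9 Å) break in the fixed order
active > I1 > I2.

## PCA

Rigid-body motion is removed by superposing all models onto an iteratively
refined mean structure (tolerance 1e-9 Å RMS on the mean, ≤ 50 iterations,
with a final pass onto the converged mean so re-alignment is idempotent);
the covariance of the flattened Cα coordinates is then eigendecomposed (via
SVD of the centered data matrix). The superposition scheme is our own
declared choice — published descriptions of this analysis typically do not
state one. Eigenvector signs are fixed (largest-magnitude component
positive) for reproducible plots; two components are reported by default.
Models with mean confidence < 70 are excluded from fits when a confidence
track is present. Pairwise state overlap in score space is the fraction of
one group's points inside the 95% Gaussian ellipse of the other
(chi-square quantile on the Mahalanobis distance).

## Correlations

The dynamic cross-correlation is the normalized form
`C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)` — the square root in the
denominator is required for `C_ii = 1` (renderings that drop it are treated
as typographical). Displacements are taken about the ensemble mean after the
same iterative superposition as PCA; superposition can be disabled for data
already expressed in a common frame (the planted-correlation fixtures are,
by construction — removing a fitted rigid transform from data with no
rigid-body motion would only leak common-mode variance into spurious
anticorrelations). Zero-variance residues get `C = 0` off-diagonal with a
warning.

The generalized correlation is `R = sqrt(1 − exp(−2 I_ij / d))` with `d = 3`
(per-residue 3-D displacement vectors) and `I_ij` the mutual information.
Two estimators are provided, since the literature on this coefficient names
none: an analytic-Gaussian estimator (MI from the 6×6 joint displacement
covariance; default, robust at the ~70-model size of one prediction run,
minimum 5 models) and a Kraskov k-NN estimator (k = 4, minimum 30 models),
which captures non-linear dependence but carries a downward finite-sample
bias in six dimensions — at n = 600 it recovers a planted R = 0.5 to within
~0.1. For jointly Gaussian motions GC ≥ |DCC| up to sampling noise, which
the tests exploit as a cross-check.

Contact persistence is the fraction of models with a Cα–Cα distance within
the cutoff; network edges require persistence ≥ 0.75. The 5 Å default
follows the side-chain contact convention; because every ensemble in scope
is a Cα-only trace, the pipeline configuration defaults to 7.5 Å (the usual
Cα-contact recommendation is 7–8 Å) while all library signatures keep 5 Å.
Sequence neighbours (|i−j| ≤ 1) are excluded from adjacency: covalently
linked, not non-covalent contacts.

## Networks

Edge weights are communication distances `w_ij = −log R_ij`; `R` at or above
1 is clamped to `1 − 1e-12` (weight floor 1e-12, keeping Floyd–Warshall
strictly positive), `R = 0` contacts are dropped with a warning (infinite
distance). All-pairs distances and shortest-path multiplicities come from a
vectorized Floyd–Warshall sweep; co-optimal paths are counted with a 1e-9
tolerance on length equality, ties never broken. Betweenness is the raw sum
`C_b(n_i) = Σ_{j<k} g_jk(i)/g_jk` over connected pairs with endpoints
excluded, per component (the treatment of disconnected graphs is our
declared choice); no normalization is applied because the Z-score
`Z_k = (C_k − C̄)/σ` over all nodes makes scale irrelevant, and `Z ≥ 2`
calls the hotspot set. If all centralities are equal (σ = 0), all Z are 0
and no hotspot is called.

Communities come from Girvan–Newman removal of the maximal
weighted-shortest-path edge-betweenness edge, keeping the partition of
maximal Newman modularity along the dendrogram, including the trivial single
community; modularity is evaluated on the unweighted topology, since the
distance-like edge weights are not affinities. `max_communities` truncates
the dendrogram on large graphs (the pipeline uses 10).

Bridgeness follows the Rao–Stirling-style reading
`G_i = Σ_{J≠I} δ_iJ · l_IJ`: the sum runs over communities `J` foreign to
node i's community `I`; `δ_iJ` is 1 iff i has at least one edge into `J`
(an indicator, not an edge count — "1 if there is a link"); and
`l_IJ = 1/(#edges between I and J)` is the effective inter-community
distance. Printed renderings of this sum are garbled in places; this
interpretation matches the accompanying prose and is stated here
prominently. A community pair with zero connecting edges contributes
nothing. Mutation-site mapping uses the Cα coordinates of the first model of
the designated representative ensemble (consistent with the RMSD reference
convention): a site is `direct_hotspot` if it is in the hotspot set,
`proximal` if its nearest hotspot is within 5 Å, else `distal`.

## Synthetic study conditions

The generator emulates the experimental setting the analyses are aimed at:

- **Reference states** — a 287-residue Cα-only chain (the kinase-domain
  span) on a smooth helix-like parametric curve, observed as 20-model
  ensembles per state; the three states share the backbone except one loop
  interval (default 24 residues, sitting where the activation loop falls in
  the 245-based numbering frame) rigidly translated per state, plus
  isotropic Gaussian noise (default 0.3 Å per coordinate). Displacement
  magnitudes (8–9 Å on the loop) put superposed inter-state RMSDs at
  ~2–3 Å, comparable to active-vs-inactive kinase separations, while
  within-state RMSD stays well under the 1.5 Å assignment rule. Cα-only
  geometry is sufficient because every downstream metric is computed on Cα
  atoms; side-chain realism could not change any tested quantity.
- **Mixtures** — models drawn from the reference states with specified
  populations (default {I2 0.82, I1 0.10, active 0.08}, the emulated
  state-switching mutant; 70 models, one prediction run's worth) with fresh
  noise and the true labels retained.
- **Confidence tracks** — core residues 80–100, loop residues 65–85 (the
  moderately reduced band typical of flexible activation loops), designated
  low-confidence models 40–60 so the pLDDT < 70 filter removes a known
  count.
- **Planted networks** — communities laid out as compact 3-Å grids (axis and
  face-diagonal contacts inside 5 Å, cube diagonal outside), consecutive
  clusters 6 Å apart so only a repositioned bridge node — placed midway
  between the closest facing node pair, in contact range of a few nodes on
  each side — connects them; displacements drawn per axis from a Gaussian
  with the planted block-correlation structure (equal per-axis correlation
  makes the expected DCC equal the planted level exactly). Positive
  semi-definiteness of the implied covariance is checked and violations
  rejected with a block diagnostic.

Noise is isotropic Gaussian per atom — the simplest model satisfying the
assumptions the DCC/PCA analyses exploit. One seed argument per operation,
no global random state; fixed seeds give byte-identical outputs.

What passing these conditions does *not* show: real predicted ensembles have
correlated, anisotropic errors, partially disordered termini, non-rigid
state differences and confidence tracks correlated with local error, none of
which the generator produces. The synthetic results validate the estimators
and the plumbing, not the biological claims one would make on real
ensembles.

## Problem sizes and degenerate inputs

Test and demo problem sizes are chosen as the smallest at which each
statistical check is well powered: 80-residue chains for classification and
PCA unit tests, 1000-model mixtures for population recovery (3 binomial SD),
500-model ensembles for correlation recovery (±0.1 on DCC), 24–42-node
planted networks for community/bridgeness recovery, ≤ 8-node graphs for the
exhaustive betweenness oracle. The full 287-residue pipeline runs in ~20 s.

Degenerate inputs are handled explicitly rather than silently: empty
ensembles, missing confidence, collinear superposition selections, all-equal
density samples (delta-like output with a warning), zero-variance
correlation residues, σ = 0 centrality profiles, communities without
external links, and non-PSD planted covariances all either warn with a
defined result or raise a named error.

## Known limitations

- The predictor itself is out of scope by design; the front-end stops at
  FASTA + manifest and the back-end starts at multi-model PDB.
- TM-score here assumes identical sequences (position-matched residues); it
  is not an alignment-based comparator for different proteins.
- Girvan–Newman with weighted edge betweenness is O(E²·V log V)-ish;
  networks much beyond ~10³ edges need the `max_communities` truncation.
- The k-NN MI estimator's finite-sample bias makes the Gaussian estimator
  the better default at the ensemble sizes this workflow produces.
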