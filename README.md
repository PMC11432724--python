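# alloscan

Alanine sequence-masking front-end and conformational-ensemble analysis
back-end for multi-state protein structure prediction workflows.

AlphaFold2-style predictors are biased toward a protein's thermodynamically
dominant conformation. For switch-like proteins — the canonical case being a
kinase domain that exchanges between an active state and two inactive states
(I1, I2) — a practical workaround is to perturb the coevolutionary signal the
predictor sees: substitute a random 5–15% of sequence positions with alanine
(across the full sequence, or targeted to regions such as the activation
loop), build a shallow MSA for each masked variant, and predict with few
recycled structures per model. The resulting ensembles can then be mined for
population shifts between states, for correlated motions, and for the network
hotspots through which allosteric mutations act.

`alloscan` implements everything around the (external, GPU-bound) predictor:

**Front-end** — randomized/targeted alanine masking and job planning:

- per-position substitution with probability `p_i ~ U(p_min, p_max)`
  (defaults 0.05–0.15), full-sequence or region-targeted;
- enumeration of prediction outputs: `n_models × num_seed × (num_recycles + 2)`
  structures per sequence (5 × 1 × 14 = 70 with the defaults), with the MSA
  subsampling depths (`max_seqs:extra_seqs`, default `16:32`) echoed into a
  JSON manifest plus a FASTA of the masked variants.

**Back-end** — ensemble analysis on multi-model PDB files (per-residue
confidence in the B-factor column):

- confidence (pLDDT) filtering at a mean-per-model threshold (default 70);
- Kabsch superposition, whole-chain and region-restricted RMSD, TM-score
  (`d0 = 1.24·(L−15)^{1/3} − 1.8`, floored at 0.5), and nearest-reference
  state classification with an RMSD < 1.5 Å assignment rule;
- PCA of Cartesian Cα coordinates on a merged reference ensemble, with
  projection of any other ensemble onto those common components;
- dynamic cross-correlation `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)` and the
  Lange–Grubmüller generalized correlation `R = √(1 − e^{−2I/3})` from the
  mutual information of 3-D residue displacements;
- residue interaction networks: edges between residues within 5 Å in ≥ 75% of
  models, weighted `w_ij = −log R_ij`; Floyd–Warshall all-pairs shortest
  paths with path counting; betweenness `C_b(n_i) = Σ_{j<k} g_jk(i)/g_jk`;
  Z-scored hotspot calling (`Z ≥ 2`); Girvan–Newman communities with
  modularity selection; Rao–Stirling-style bridgeness
  `G_i = Σ_{J≠I} δ_iJ · l_IJ`, `l_IJ = 1/(#edges between I and J)`; and
  mapping of mutation sites to hotspots (direct / proximal < 5 Å / distal).

A first-class synthetic-data module generates multi-state kinase-like
ensembles (shared backbone, one rigidly displaced loop per state, isotropic
noise), labelled state mixtures, confidence tracks, and planted-correlation /
planted-bridge ensembles, so the entire pipeline is testable without GPU
inference or structure downloads.

## Worked example

The demo pipeline emulates a state-switching double mutant whose ensemble is
~82% in the fully-closed inactive I2 state: it generates three 20-model
reference ensembles and a 70-model "predicted" mixture (the size of one
5-model × 14-recycle run), filters at pLDDT 70, classifies, runs PCA and the
network analysis, and writes every table under the run directory:

```bash
alloscan run --run-dir demo_run --seed 1
```

prints (abridged):

```json
{
 "populations": {"active": 0.0448, "I1": 0.1045, "I2": 0.8507, "unassigned": 0.0},
 "hotspots": [281, 285, 289, 293, 301, 305, 309, ..., 483, 487],
 "n_communities": 10
}
```

Three of the 70 models are constructed with mean confidence below 70 and are
removed by the filter; the classified populations of the remaining 67 models
(85.1% I2, 10.4% I1, 4.5% active) recover the planted mixture exactly — every
retained model is assigned its true state, so the residual deviation from
82/10/8 is binomial sampling noise in the mixture draw. `report.json` also
records the TM-score of the first retained model against the active reference
(0.98, same fold), the variance shares of the leading principal components
(0.56 / 0.34 — the two loop-displacement directions separating the three
states), and the mutation mapping: with this synthetic geometry the R-spine
analogue site 309 lands directly on a hotspot and 320/334 fall within 5 Å of
one.

Per-stage commands (`alloscan mask`, `alloscan analyze-ensemble`,
`alloscan rin`) expose the same functionality on your own FASTA/PDB inputs;
the library API (`import alloscan`) is documented in the module docstrings.

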