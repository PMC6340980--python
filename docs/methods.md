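# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of `lpifkl`, in the spirit of a model
reference rather than a tutorial.

## Problem setting and assumptions

Interactions are a binary m×n adjacency **F** over registered lncRNAs and
proteins; unobserved pairs are treated as presumed negatives (the
semi-supervised convention for sparse interaction networks), so a "0" means
"not known to interact", not "known not to interact". All matrices are dense
double precision; identifier order is frozen when the interaction edge list
is read (first appearance) and indexes every downstream matrix axis.

Held-out evaluation works through a mask on the adjacency: masked positions
read as 0 in every training view. All quantities that depend on the training
labels — the two interaction-profile kernels, the fusion target Y, the fitted
smoothers — are recomputed from the masked view inside each fold, so the
hidden values cannot influence any kernel, weight or prediction (this is
asserted bit-exactly in the test suite).

## Kernels

* **Interaction profile (GIP).** K(a,b) = exp(−σ‖F_a−F_b‖²) over rows
  (lncRNAs) or columns (proteins) of the masked adjacency, σ = 1 by default.
  A `normalize_sigma` flag divides σ by the mean squared profile norm — the
  common variant that keeps the effective bandwidth scale-free — but the raw
  σ = 1 form is the default.
* **Sequence alignment (SW).** Normalised local alignment score
  SW(a,b)/√(SW(a,a)·SW(b,b)). Scoring defaults: RNA match +5 / mismatch −4,
  protein BLOSUM62, affine gaps costing 10 + 0.5·(L−1) for a gap of length L
  (EMBOSS-water-style defaults); all configurable. Scores come from
  Biopython's `PairwiseAligner`; the test suite checks them cell-for-cell
  against an independent Gotoh dynamic-programming implementation. The
  wildcard residue N never matches anything, so an all-wildcard sequence has
  zero self-score and is rejected with its identifier.
* **Sequence features (SF).** lncRNAs: 64 overlapping 3-mer frequencies over
  {A,C,G,U} (windows containing a wildcard are skipped; counts divided by
  d−2), L2-normalised — the natural 4-letter analogue of the conjoint-triad
  descriptor. Proteins: Pse-PSSM with lag ξ = 1 — each profile column is
  standardised across positions (constant columns become zero), and the
  feature is the 20 column means followed by 20 lag-1 mean squared
  differences, L2-normalised. Note the means of standardised columns vanish
  by construction, so with this definition the discriminative content lies in
  the lag terms. When no alignment-derived PSSM file is supplied, a
  sequence-only synthetic surrogate profile is used: position h's scores are
  the BLOSUM62 row of residue h. Both feature sets feed an RBF kernel with
  γ = 1; features are unit-norm first so that a unit bandwidth is
  scale-meaningful across feature types.
* **Expression (EXP).** RBF (γ = 1) over L2-normalised per-cell-type
  expression vectors (dimension 24 by default).
* **GO.** Jaccard index of exact GO term-identifier sets. Proteins with empty
  sets get neutral rows (0 off-diagonal, 1 diagonal). The package also exposes
  the stricter positional "common terms" relation between annotation vectors —
  two vectors share terms only when identical position by position — which is
  the sparse matching rule the set-based kernel inherits its intent from.

Normalised-alignment and Jaccard matrices are not guaranteed positive
semidefinite; they pass through eigenvalue clipping at 0 (a PSD input passes
through unchanged to 1e-10) before cosine normalisation to unit diagonal.
GIP/RBF kernels are PSD by construction. Molecules missing one modality get
neutral rows in that kernel; fusion weights are global per space, so missing
data dilutes a kernel rather than invalidating it.

## Fast kernel learning

Weights minimise ‖Σ w_a K_a − Y‖²_F + λ‖w‖² subject to Σ w_a = 1, with
Y = F·Fᵀ (lncRNA side) or Fᵀ·F (protein side) — the Gram matrix of training
interaction profiles, the standard kernel–target-alignment choice for
bipartite data, dimensionally consistent with the kernels it aligns. Y is not
normalised by default (a flag is unnecessary since callers can pass any
target). λ defaults to 10⁴; as λ → ∞ the weights provably approach uniform
1/J (asserted at λ = 10¹²).

The equality-constrained quadratic program is solved exactly through its KKT
linear system. Non-negativity (on by default — convex combinations of PSD
kernels stay PSD, and negative kernel weights are hard to interpret) is
enforced, when the KKT optimum leaves the simplex, by exact minimisation over
the probability simplex via active-set enumeration: with J ≤ 4 kernels all 2^J
sign patterns are checked, which is cheap and returns the true constrained
minimiser rather than a clipped approximation. The solver is verified against
a 0.001-step dense simplex grid. An `--allow-negative-weights`-style escape
hatch (`project_simplex=False`) returns the equality-only optimum.

Kernels enter the alignment QP after PSD repair and cosine normalisation;
otherwise the trace inner products are dominated by whichever kernel happens
to have the largest diagonal.

## Kronecker kernel ridge regression

The production path is the closed form
F* = K_lnc(K_lnc+λ_l I)⁻¹ F (K_pro+λ_p I)⁻¹ K_pro, evaluated through one
eigendecomposition per kernel; a (λ_l, λ_p) grid sweep then costs only
diagonal rescalings, which the grid-search routine exploits. Two equivalent
routes exist as oracles: the two-step view (row smoother, then column
smoother) and the vectorised Kronecker form. For the latter, the pairwise
kernel Ξ = (K_pro⊗K_lnc)(λ_lλ_p I + λ_p I⊗K_lnc + λ_l K_pro⊗I)⁻¹ defines
the ridge smoother vec(F*) = Ξ(Ξ+I)⁻¹vec(F); expanding Ξ(Ξ+I)⁻¹ gives
(K_pro⊗K_lnc)(K_pro⊗K_lnc + λ_p I⊗K_lnc + λ_l K_pro⊗I + λ_lλ_p I)⁻¹, which
factorises into the closed form — so the three routes are one predictor, and
the suite checks them against each other at 1e-6/1e-8 on random problems.
The Kronecker operator is materialised only for m·n ≤ 2000. An iterative
fixed-point treatment of the same objective exists in the literature; the
closed form is exact, so no iteration is used.

Defaults λ_l = λ_p = 1 — the neutral unit-ridge setting for unit-diagonal
kernels. On the synthetic benchmark the metrics are flat across the whole
2⁻⁷…2⁷ grid, so the default is not load-bearing; `grid_search` selects by
pooled CV AUPR with ties broken toward the smaller λ_l then λ_p (smaller
regularisers keep the linear systems better conditioned and match the
convention that cheaper settings win ties). The default grid is logarithmic
2⁻⁷…2⁷ per side, covering both very weak and very strong shrinkage.

## Evaluation protocols

* **5-fold CV:** positive pairs are partitioned (seeded permutation,
  round-robin, fold sizes within 1); each fold's positives are masked, GIP
  kernels and fusion weights rebuilt, and the masked positives scored against
  *all* zero pairs. Curves and headline metrics are pooled across folds;
  per-fold values are also reported.
* **Local LOOCV:** one protein's entire column is masked and rescored;
  (score, label) pairs are pooled over proteins, and per-protein descending
  rankings are emitted for case-study-style top-k tables.
* **Metrics:** AUC via midranks (tied pairs count ½), checked exactly against
  a brute-force pairwise counting oracle; AUPR by trapezoidal integration of
  the precision–recall points at all distinct thresholds, anchoring the
  recall-0 endpoint at the precision of the highest threshold. These
  definitions are deterministic and library-independent.

## Synthetic data generator

The generator emulates the statistical structure the kernels assume — similar
molecules share interaction partners — with a planted one-to-one block model:
lncRNAs and proteins are assigned (balanced, seeded) to k latent blocks;
interactions are Bernoulli(p_in) within matched blocks and Bernoulli(p_out)
otherwise; sequences are per-position mutated copies of block template
sequences; expression profiles are block means plus Gaussian noise; GO sets
are sampled from block-specific pools plus a shared pool with cross-block
contamination at the noise rate. Defaults: m = 200, n = 30, k = 4,
p_in = 0.3, p_out = 0.02, sequence lengths 60–120, expression dimension 24,
8 pool + 4 shared GO terms, noise 0.05 — sized so every kernel carries
signal, the positive rate (≈9%) is realistically sparse, and a full CV run
completes in seconds. Generation is bit-reproducible from the spec, and a
`degrade` operation removes a modality for a seeded subset of molecules to
exercise missing-data handling.

What the generator does *not* emulate: real sequence composition and length
distributions, correlated expression programs, GO term hierarchy and
annotation depth, and — importantly — any interaction structure finer than
the blocks. Given the blocks, interactions are drawn independently, so a
held-out pair is statistically independent of the training data within its
block cell. The Bayes-optimal ranking is therefore the block rule, whose
expected pooled CV AUC at the default rates is

    [W₊·O₋ + ½(W₊·W₋ + O₊·O₋)] / (P·N) ≈ 0.8205

(W₊ = 0.075 within-block positives, W₋ = 0.175, O₊ = 0.015, O₋ = 0.735,
P = 0.09, N = 0.91). Scoring with the ground-truth block indicator lands at
0.80–0.83 across seeds, and the full pipeline matches it — i.e. passing tests
show the pipeline extracts essentially all plantable signal, not that it
would reach any particular AUC on real data, where finer-than-block structure
exists and the interaction-profile kernel can exploit it.

## Numerical choices and degenerate inputs

* Kernels are symmetrised (½(K+Kᵀ)) on construction and checked symmetric to
  1e-8; eigen-decompositions use the symmetric solver.
* Cosine normalisation leaves zero-diagonal rows as zeros and sets their
  diagonal to 1 (neutral-row convention shared with missing modalities).
* Zero feature vectors stay zero under L2 normalisation (short sequences,
  constant PSSM profiles), yielding kernel value exp(−‖x_b‖²) against others.
* The wildcard policy is loss-tracking: off-alphabet residues become N/X and
  are counted in a load report.
* An all-zero training adjacency is rejected (there is no target to align
  kernels to, and nothing to smooth).
* Duplicate interaction pairs collapse to one with a warning; fold assignment
  requires at least as many positives as folds.
* Seeds: one integer seed drives the generator and one drives fold
  assignment; identical seeds reproduce every output file byte-for-byte.

## Limitations

* Fusion weights are global per space; per-row (locally weighted) kernel
  learning is out of scope.
* Zero-shot prediction is one-sided (new protein against known lncRNAs or
  vice versa); simultaneously-new pairs only compose the two smoothers and
  are unvalidated.
* The GO kernel is flat term overlap; no ontology-graph semantic similarity.
* PSI-BLAST profiles are read but never computed; absent profiles fall back
  to the BLOSUM62 surrogate, which carries strictly less information.
* The synthetic benchmark bounds achievable ranking quality by construction
  (see above); conclusions about absolute real-data performance require real
  data.
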