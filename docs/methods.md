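# Methods

## Fluctuation profiles

The core statistic is the per-residue root mean square fluctuation of
Cα positions about the ensemble mean, with the *population* divisor M
(the average runs over the whole ensemble, not an M−1 sample
correction):

RMSF_i = sqrt( (1/M) Σ_j ‖x_ij − ⟨x_i⟩‖² ), coordinates in Å.

The residue-averaged RMSF ("average displacement per residue") is used
as the scalar measure of an ensemble's variability and as the
stratification variable in benchmark summaries. We use this single
definition both for reporting an ensemble's variability and for the
low/high split; a pairwise inter-model RMSD would be an alternative
reading but is monotonically related for near-Gaussian ensembles and
would complicate the ≤/> threshold semantics.

## Superposition

RMSF is meaningful only after global rotation and translation are
removed. `kabsch` solves the weighted orthogonal Procrustes problem by
SVD of the weighted covariance, with the standard sign correction of the
smallest singular direction so the result is always a proper rotation
(mirror inputs yield the best proper fit, never a reflection).
(Near-)collinear point sets leave the rotation underdetermined and are
rejected; so are fewer than 3 points.

`superpose_ensemble` iterates: align every conformer to a reference
(initially the first conformer), recompute the mean structure, realign
to the mean, until the RMSD between successive means falls below `tol`
(default 1e-4 Å) or `max_iter` (default 50) is reached. Non-convergence
is reported, not raised. Two weighting modes:

* `uniform` — plain least squares; the summed squared residual about the
  mean is non-increasing over iterations (each half-step minimizes it).
* `inverse_variance` (default) — after each iteration residue weights
  are set to 1/(v_i + ε) with v_i the residue's current mean-square
  deviation about the mean and ε = 1e-6 Å² a regularizer. This
  down-weights mobile residues so rigid cores dominate the frame — the
  qualitative behaviour of maximum-likelihood superposition tools — 
  without the full hierarchical variance model such tools estimate.
  Exact reproduction of any particular ML implementation is not
  attempted; with typical ensembles the two modes agree on the RMSF
  profile shape to within a few percent.

## Profile comparison

Residues are matched by identity (chain, author residue number,
insertion code); unmatched residues are dropped and counted. A
`renumber` fallback pairs residues by rank order when numbering schemes
differ. Spearman's r_s is computed as the Pearson correlation of
midranks (fractional ranks on ties); with no ties this is exactly
1 − 6Σd²/(n(n²−1)). Constant input makes the coefficient undefined; we
return NaN, never 0, because "no monotone association measurable" and
"measured zero association" are different findings. The profile RMSD is
computed on unscaled profiles — amplitude disagreement is precisely what
it is meant to detect — and no terminal trimming or smoothing is
applied.

## Benchmark aggregation

One record per protein: r_s and profile RMSD per method pair, plus the
reference-ensemble variability. Means are taken pairwise over the
records where a field is present (method pairs are independent columns;
listwise deletion would throw away data). SDs use the sample (n−1)
estimator, conventional for ± reporting; at benchmark sizes (n ≈ 140)
the n vs n−1 difference is far below reporting precision. The
low-variability subset is inclusive (≤ 1 Å by default); the poor subset
is strict (prediction-vs-reference r_s < 0.5). Text reports round to 2
decimals; CSV/JSON carry full precision.

## GNM predictor

The Gaussian network model provides the single-structure baseline:
Γ_ij = −1 for residue pairs within a cutoff (default 7.3 Å, the
conventional Cα contact distance), diagonal set for zero row sums.
Relative mean-square fluctuations are the diagonal of the pseudo-inverse
of Γ, computed by eigendecomposition with eigenvalues below 1e-10 of the
largest treated as the rigid-body zero mode; a connected contact graph
must have exactly one. A disconnected graph is an error (per-component
profiles are defined only up to independent shifts). The isotropic GNM
is used rather than a 3N×3N anisotropic model because downstream
comparisons are rank-based: only relative magnitudes matter. The
`scale_to` option rescales the profile so its mean equals a chosen
average displacement, for amplitude-comparable RMSD values.

## Synthetic data

`make_ensemble` emulates an NMR-like ensemble: an idealized backbone
(straight chain at 3.8 Å spacing, or a helix with 2.3 Å radius, 1.5 Å
rise and 100° twist per residue, giving ≈3.8 Å Cα–Cα distances) plus
independent isotropic Gaussian displacements with per-residue per-axis
SD σ_i, each model then subjected to a random rigid transform (axis
uniform on the sphere, angle uniform up to 30° and translation up to
5 Å by default) so superposition is genuinely exercised. The RMSF of
the pre-jitter coordinates is returned as an oracle — what a perfect
superposition would measure. Under this model E[RMSF²] = 3σ²(1 − 1/M),
which the pipeline reproduces within Monte-Carlo tolerance.

Named σ shapes: `flat`; `terminal-ramp`, base + amp·exp(−d/width) with
d the distance to the nearer terminus (floppy tails, strictly monotone
toward the core so the rank structure stays informative — an exactly
flat core would cap any estimator's achievable rank correlation through
tie dilution); `loop-bump`, a mid-chain Gaussian bump. Displacements are
independent across residues; correlated collective motions are out of
scope, so recovery tests validate the estimator, not realism of protein
dynamics — real ensembles add covariance, anisotropy and missing
residues that these generators deliberately omit.

`make_benchmark_table` constructs a per-protein table whose summary
statistics are known *exactly*: proteins are partitioned into
poor-prediction and ordinary groups within each variability subset,
group means are solved so the requested overall and subset means hold,
and within-group spreads use deterministic mean/SD-exact patterns (a
skewed-linspace family, standardized) chosen so every value respects
its range constraints ([−1, 1] for correlations, the poor threshold for
the defining column). The seed only shuffles row order and protein
names. Defaults encode the reference benchmark's structure: 140
proteins, 60/80 split at 1 Å, overall means 0.72 (SD 0.15) and 0.64
(SD 0.23), high-subset means 0.78/0.69, a 10-protein poor subset
(9 of them low-variability) with means 0.35/0.26, and mean variability
1.68 Å with values spanning ≈0.2–12 Å. Low-subset means are implied by
weighted recombination (0.64 and ≈0.57) rather than set independently.
Companion columns not constrained by these targets (prediction-vs-MD
correlations, profile RMSDs) are filled with plausible covarying values
and are not asserted on.

## I/O conventions

PDB reading goes through gemmi: ATOM records only, atom name CA,
standard amino acids, altloc blank/'A' kept. Residues absent from any
model are dropped by across-model intersection (with warnings), since a
per-residue ensemble average needs every residue in every model; how
ragged models should best be handled is genuinely open, and
intersection is the conservative choice. Author numbering and
first-model order are preserved. The writer emits fixed-width Cα-only
records and always wraps conformers in MODEL/ENDMDL — including M=1 —
so written files round-trip as ensembles (coordinates to 0.001 Å, the
PDB column precision). Profiles are CSV with columns
`chain,seq_num,icode,res_name,rmsf`.

## Problem sizes and determinism

Every stochastic computation takes an explicit integer seed and is
bit-reproducible. Recovery studies use 200 replicates of N=100, M=50
ensembles; Monte-Carlo calibration uses M=500, N=100 — sizes chosen to
put sampling error well below the 5–10% effects being checked while the
whole suite runs in seconds.

## Known limitations

* No mmCIF or compressed-trajectory input; multi-model PDB only.
* Ensembles are Cα-only; no side-chain or all-atom fluctuations.
* The inverse-variance mode approximates, but is not, a full
  maximum-likelihood superposition.
* GNM assumes a connected contact graph and a single dominant zero
  mode; multi-chain complexes with gaps need a larger cutoff or
  per-chain treatment.
* The synthetic generators produce uncorrelated, isotropic
  fluctuations; agreement there does not certify behaviour on ensembles
  with strongly collective motions.
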