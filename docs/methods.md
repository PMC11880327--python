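# Methods

This note documents the models, conventions and numerical choices behind
`tcrloops`, and what the synthetic-data tests do and do not demonstrate
about real structural data.

## IMGT numbering and region definitions

All structures are consumed already IMGT-numbered (residue sequence number
= IMGT position, PDB insertion-code field = IMGT insertion code); the
package never computes numbering from sequence. Loops and anchors are
defined on IMGT positions, inclusive on both ends: CDR1 loop 28–38
(anchors 22–27 and 39–44), CDR2 loop 57–65 (anchors 51–56 and 66–71),
CDR3 loop 106–117 (anchors 100–105 and 118–123). CDR3 length variation is
absorbed at the loop centre: insertion codes ascend after position 111
(111, 111A, 111B, …) and descend before position 112 (…, 112B, 112A,
112). This is the only ordering consistent with the IMGT gap-filling
scheme and is property-tested against an enumeration oracle. Short loops
drop central positions symmetrically, the N-terminal half keeping the
extra residue on odd lengths.

Chains are identified by an explicit `chain_map` (file chain id → alpha /
beta), never inferred from sequence. Files with several models expose one
model at a time; selecting among multiple complete copies is left to the
caller.

## Loop distances

The distance between two conformations of the same region is computed by
(1) matching anchor backbone atoms by (IMGT position, insertion code,
atom name), (2) least-squares rigid superposition (Kabsch SVD, proper
rotation enforced) of the mobile anchors onto the reference anchors, and
(3) RMSD over matched loop backbone atoms under that transform. Loop
atoms never influence the fit. Atoms absent in either partner are dropped
pairwise; a region with a missing anchor atom is flagged *degraded*
rather than rejected, and superposition errors out only below three
common anchor atoms (the rigid fit is then underdetermined). All
distances are in Å; internal floating-point comparisons use an absolute
tolerance of 1e-9.

For loops of unequal residue count, each loop's ordered backbone trace
(N, CA, C, O per residue, canonical residue order; complete backbones
required) is interpolated per Cartesian coordinate by a natural cubic
spline with knots at the 4L atoms, parameterised by knot index normalised
to [0, 1]. Both splines are evaluated at M = 4·max(Lₐ, L_b) uniform
parameters and the RMS point-to-point distance taken. Because the uniform
grid coincides with the knots when lengths agree, the up-sampled distance
*equals* plain RMSD at equal lengths by construction (asserted to 1e-9
over randomized fixtures). At unequal lengths the value is grid-dependent
at the ~1% level; a dense-resampling check (1000 samples) bounds the
discrepancy on smooth traces.

## Greedy threshold clustering

A single pass in item order: each unassigned item seeds a cluster and
absorbs every *later* unassigned item whose distance to the seed is
strictly below τ. The output therefore partitions the items, every
non-seed member lies within τ of its seed, and the result depends on item
order; callers pass an explicitly ordered id list (the pipeline uses
lexicographic id order and logs it). Equivalence with a literal
transcription of the published pseudocode is asserted over hundreds of
random matrices. Cluster count is non-increasing in τ (property-tested).
τ = 0 is accepted and degenerates to all singletons, which keeps
identity-threshold scans defined at the 100% identity boundary.

Structural censuses use τ = 1 Å; V/J coherence uses τ = 2 Å on CDR3
loops grouped by (V, J) gene pairing, counting only pairings with at
least five structures, and reports the fraction of pairings whose loops
form a single cluster.

## Sequence identity

Identity is the score of a global alignment with unit match reward and no
mismatch or gap penalties, normalised by the longer sequence length. With
those scores the optimal alignment value is exactly the longest-common-
subsequence length, so the numerator is computed by LCS dynamic
programming; only the score is used, making ties among co-optimal
alignments irrelevant. Tests verify exhaustive agreement with a
general-purpose global aligner configured with the same scores. Sequence
distances are d = 1 − identity.

The default "small residue" set for composition profiles is
{G, A, S, C, P, T}; the boundary of "small" is genuinely conventional, so
the set is a parameter and is reported with every fraction. Positional
profiles are emitted as position-frequency matrices (the input a logo
renderer consumes) with Shannon entropy in bits.

## Benchmark statistics

Per-record region RMSDs: CDRs anchor-aligned as above (spline up-sampled
if a predicted loop's length disagrees with the reference); framework and
whole-chain values after a whole-chain backbone superposition, the
framework being every IMGT position outside the three loop ranges (the
complement convention — the alternative of superposing on framework only
is switchable in principle but not the default). Failed cells are
recorded as missing, excluded pairwise, and counted in every summary.

Sub-threshold counting uses strict `<` ("sub-2 Å"). The model-comparison
t statistic is implemented verbatim as t = |μ₁ − μ₂| / √((σ₁² + σ₂²)/N)
with sample variances (ddof 1) and two-tailed p = 2·sf(t, N − 1). This
pools by the common sample size with N − 1 degrees of freedom, which is
*not* Welch's unequal-variance test; a standard Welch option exists
behind a flag for comparison but is never the default, because the
pooled form is the statistic this analysis ecosystem reports.
Identity–RMSD trends report Pearson correlations overall and stratified
at identity 0.65, flagging (not raising on) zero-variance strata. t-SNE
embeddings (perplexity 10, precomputed distances, fixed seed) are
visualisation-only: cluster labels are always the greedy-clustering
output passed through, never re-derived from the embedding.

## Synthetic repertoires

The generator's purpose is exact, controllable ground truth, not
stereochemical realism. All records share one fixed framework scaffold
per chain (constant coordinates and sequence), so anchor superposition
between any two records is exact and planted distances are controlled.
Loops are smooth sine-bump arcs between the flanking anchor CA positions;
backbone atoms are placed at fixed plausible-magnitude offsets around
each CA. No forcefield or sterics are involved — every analysis under
test is purely geometric.

Regimes per region and chain:

* **K ≥ 1 planted clusters** (canonical CDR1/CDR2 behaviour): K centroid
  arcs accepted only if all pairwise centroid distances (measured with
  the package's own distance, up-sampled across lengths) reach
  `cluster_separation`; members are assigned by balanced shuffled
  round-robin, so every planted cluster is realised whenever
  n_records ≥ K and census recovery is exact. Member loops are the
  centroid plus isotropic Gaussian noise; `noise_radius` is the RMS
  per-atom displacement, so two members of one cluster sit ≈ √2 ×
  noise_radius apart in RMSD. Defaults: CDR1 K = 6, CDR2 K = 4,
  noise 0.3 Å, separation 4 Å.
* **K = 0, diffuse** (CDR3 behaviour): a fresh random arc per record;
  at τ = 1 Å nearly every loop is its own cluster.
* **V/J coherence mode** (CDR3 only, per chain): records are assigned
  (V, J) pairings round-robin over the vocabulary product; each pairing
  is coherent (one conformation) with probability equal to the target
  coherence, otherwise split evenly across two well-separated
  conformations. The measured single-cluster fraction is then a binomial
  draw around the target — recovery is asserted within three binomial
  standard errors. The alpha/beta calibration targets used in the
  acceptance run are 0.44 and 0.22.

Sequences are per-cluster random consensi mutated at `seq_mutation_rate`
(default 0.1) per position; framework sequence is constant. Default loop
length distributions (CDR1 6–7, CDR2 5–6, CDR3 10–15 peaked at 12) match
typical TCR loop-length ranges. Generation is bit-reproducible from
(config, seed).

`generate_identity_rmsd_pairs` plants an exact population Pearson
correlation: identity is uniform on [0.20, 0.95] and RMSD a linear
response plus independent uniform noise, with slope and noise width
solved so the population PCC equals the target and both marginals stay
bounded (identity ⊂ [0, 1], RMSD ≥ 0). An earlier truncated-Gaussian
construction was replaced because truncation attenuated the planted
correlation by ~2%.

`perturb_record` rigidly translates one loop so its anchor-aligned RMSD
to the original is exactly the requested displacement — the fixture
factory behind the benchmark arithmetic tests.

### What passing tests show — and don't

Synthetic repertoires have exact anchors, isotropic noise, single-arc
cluster geometry and random sequences. Passing recovery tests therefore
demonstrates the *correctness of the measurement chain* (extraction →
superposition → distance → clustering → statistics), not that real CDR
loops cluster this cleanly: real data have correlated backbone noise,
anchor flexibility, length-dependent RMSD baselines and
sequence–structure coupling the generator does not model. Quantities
tied to real repertoires (cluster censuses of deposited prediction sets,
observed coherence of real gene pairings) additionally depend on item
order and sampling and are reproduced only up to that variation.

## Problem sizes

The default test and acceptance runs use desk-scale problems chosen to
make the statistics sharp: 20-record repertoires across K = 1..10 (100
seeds) for census recovery; 4000-record repertoires giving 800 gene
pairings of five structures for the coherence fractions (binomial SE
≈ 1.8 points); 10,000 pairs for correlation recovery; 45-record fixtures
for the benchmark arithmetic; 200–500 random fixtures/matrices for the
geometry and clustering oracles.
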