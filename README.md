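# tcrloops

Structural diversity analysis of T-cell receptor (TCR) CDR loops.

TCRs recognise peptide–MHC through six hypervariable loops (CDR1–3 on the
alpha and beta variable domains). CDR1/2 are germline-encoded and fall into
recurrent *canonical* conformations; CDR3 spans the V(D)J junction and is
far more diverse. `tcrloops` implements the quantitative machinery used to
study this structural landscape and to benchmark structure predictors on
it:

* **IMGT-numbered structure I/O** — read/write PDB files whose residue
  numbers follow the IMGT scheme (the STCRDab convention), extract loops
  and their flanking anchors:

  | Region | Anchor positions | Loop positions |
  |--------|------------------|----------------|
  | CDR1   | 22–27, 39–44     | 28–38          |
  | CDR2   | 51–56, 66–71     | 57–65          |
  | CDR3   | 100–105, 118–123 | 106–117        |

* **Anchor-aligned backbone RMSD** — least-squares (Kabsch) superposition
  on anchor backbone atoms (N, Cα, C, O), RMSD measured over loop atoms
  with no re-fitting; loops of unequal length are compared by natural
  cubic-spline resampling of both backbone traces at M = 4·max(Lₐ, L_b)
  points, calibrated so the distance equals plain RMSD at equal lengths.

* **Greedy threshold clustering** — single-pass clustering of a pairwise
  distance matrix D at radius τ: each unassigned item seeds a cluster and
  absorbs every later unassigned item j with D(seed, j) < τ. Used for
  conformational censuses (τ = 1 Å), sequence-identity clustering
  (d = 1 − identity), and V/J-gene structural coherence (τ = 2 Å, gene
  pairings with ≥ 5 structures).

* **Sequence metrics** — gap-penalty-free global-alignment identity
  (numerator = longest common subsequence, denominator = longer length),
  identity-threshold cluster scans, per-position composition/entropy
  profiles and small-residue fractions.

* **Benchmark statistics** — per-record, per-region RMSD tables
  (FW/CDR1/CDR2/CDR3/whole chain × alpha/beta), sub-threshold counts,
  two-model quadrant classification, best-of-ensemble rates, the pooled
  two-tailed t-test `t = |μ₁ − μ₂| / √((σ₁² + σ₂²)/N)` with
  `p = 2·sf(t, N − 1)`, identity–RMSD trend stratification and t-SNE
  embeddings of precomputed distance matrices (perplexity 10,
  visualisation only).

* **Synthetic repertoires** — a generator of IMGT-numbered paired
  alpha/beta structures with *planted* ground truth: K conformational
  clusters per region (K = 0 → diffuse), Gaussian coordinate noise,
  tunable V/J→structure coherence and a tunable identity–RMSD
  correlation, so every analysis stage is testable end to end without
  external data.

## Worked example

```python
from tcrloops import (GeneratorConfig, generate_repertoire, extract_loops,
                      pairwise_distance_matrix, greedy_cluster, cluster_census)

records, truth = generate_repertoire(GeneratorConfig(n_records=60, seed=11))
for region in ("CDR1", "CDR2", "CDR3"):
    loops = extract_loops(records, "alpha", region)
    matrix = pairwise_distance_matrix(loops, ids=[r.record_id for r in records])
    census = cluster_census(greedy_cluster(matrix, tau=1.0))
    planted = len(set(truth.labels["alpha"][region]) - {-1}) or "diffuse"
    print(f"{region}-alpha: {census.count:3d} clusters of {len(records)} loops "
          f"(planted: {planted}; singleton fraction {census.singleton_fraction:.2f})")
```

prints

```
CDR1-alpha:   6 clusters of 60 loops (planted: 6; singleton fraction 0.00)
CDR2-alpha:   4 clusters of 60 loops (planted: 4; singleton fraction 0.00)
CDR3-alpha:  56 clusters of 60 loops (planted: diffuse; singleton fraction 0.88)
```

(output of `examples/03_greedy_clustering.py`): the greedy census
recovers the planted canonical CDR1/CDR2 forms exactly, while the diffuse
CDR3 yields nearly one cluster per loop — the signature of a
non-canonical loop. The `examples/` directory holds one short script per
capability (RMSD, spline up-sampling, clustering, sequence scans,
benchmarking, VJ coherence), each printing the numbers it computes and a
line on what they mean.

A thin CLI wraps the same library for shell use:

```bash
tcrloops synth --n-records 100 --outdir out
tcrloops cluster --input-dir out/synthetic --chain alpha --region CDR1 --tau 1.0 --outdir out
tcrloops vj-coherence --input-dir out/synthetic --tau 2.0 --min-group 5 --outdir out
```

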