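# Methods

## Model and procedure

`sigmatch` compares transcriptional responses through rank statistics alone.
The pipeline has four stages, each consuming only the previous stage's
output:

1. **Rank-list construction.** An experiment/control pair of positive,
   linear-scale intensities over a common probe universe of size N is turned
   into a probe rank list (PRL), a strict permutation with rank 1 the most
   upregulated probe. Both samples are clamped from below at the *primary
   threshold* — the 25th percentile of the pooled 2N intensities — before the
   experiment-to-control ratio is taken, which suppresses unstable fold
   changes driven by small denominators. Probes are sorted by clamped ratio
   descending. Clamping collapses all low-intensity probes into a ratio-1
   block; that block is re-ranked using ratios of the *original* intensities
   clamped at the *secondary threshold* (primary/10), which restores
   resolution among weakly expressed probes without letting them reach the
   extremes of the list.
2. **Consensus merging.** Replicate PRLs of one condition are aggregated by
   hierarchical majority voting: the two closest lists under the Spearman
   footrule distance are replaced by their Borda (mean-rank) merge, repeating
   until one list remains. Footrule is a true metric on permutations and
   Borda merging is commutative and idempotent, which makes the scheme
   order-invariant whenever the pairwise distances are distinct.
3. **Distance.** Each condition PRL yields a signature: its top-n and
   bottom-n probes. A gene set's enrichment score (ES) in a reference PRL is
   the signed maximum deviation from zero of the running sum that gains 1/n
   at hits and loses 1/(N−n) at misses; the sum returns to zero at rank N
   and ES ∈ [−1, 1]. A signature's two-sided score is
   (ES_up − ES_down)/2, and the distance between PRLs A and B is
   d(A,B) = 1 − (ES_AB + ES_BA)/2 ∈ [0, 2]. For unrelated lists both
   two-sided scores are centred on zero, so d concentrates around 1.
4. **Reporting.** Perturbations are sorted by ascending distance to the
   query condition; the distance matrix is clustered by average linkage
   (UPGMA) on the precomputed dissimilarities.

## Assumptions

- Intensities are positive, finite and on a linear scale; log-scale data
  must be exponentiated first, since quartile clamping and ratios are only
  meaningful on linear values. This is enforced at every input boundary.
- All PRLs entering a merge or a distance share one probe universe. Probe
  harmonisation (`harmonize_probes`, intersection of probe sets sorted
  ascending) runs once, before any rank list is built.
- Replicates of one condition measure the same underlying response; the
  merge scheme is majority voting, not outlier detection.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| signature size n | 250 | probes taken from each end of a PRL; must satisfy 2n ≤ N. The distance is insensitive to n over a broad range; 250 is the conventional choice for ~22k-probe arrays. |
| primary threshold | pooled 25th percentile | quantile convention: linear interpolation between order statistics (numpy default). Any fixed convention preserves the method; this one is reproducible everywhere. |
| secondary threshold | primary/10 | fixed by construction. |
| ratio-1 detection | relative tolerance 1e-12 | clamping creates exact ties; the tolerance only guards against representation noise in rescaled inputs. |

Simulation defaults (the study conditions the tests measure under): 2000
probes, 1 disease + 20 perturbation conditions, 3 replicate pairs each,
planted up/down sets of 100 probes, 4-fold change, multiplicative
log-normal noise with σ = 0.2, designated-perturbation overlap 0.8,
baseline intensities log-normal(μ=6, σ=1). The baseline spread places a
substantial fraction of intensities below the pooled lower quartile, so
both clamping branches are exercised in every simulated pair.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical shape the method assumes —
positive skewed intensities, paired case/control design, planted
directional regulation of controllable overlap, multiplicative noise — and
is fully deterministic under one integer seed (numpy PCG64 via
SeedSequence spawning). It does not emulate probe-level annotation,
normalisation artifacts, batch effects, correlated probe blocks, or
cross-platform effects; passing the recovery tests demonstrates that the
pipeline detects shared regulation under the stated noise model, not that
it is robust to every failure mode of real microarray data.

Decoy perturbations draw their planted sets from the probes not planted in
the disease, independently per decoy; two decoys may therefore overlap each
other (mutual disjointness cannot fit 19 × 200 planted probes in a
2000-probe universe) but never the disease's sets, which is the property
the ranking experiment needs. At overlap 0 the designated perturbation is
drawn exactly like a decoy, making its rank exchangeable — the basis of the
uniformity test.

## Numerical choices

- **ES tie rule.** If the extreme positive and negative deviations of the
  running sum tie in magnitude, the positive one is returned; ties are
  measure-zero but determinism requires a rule.
- **Two-sided combination.** (ES_up − ES_down)/2 always, with no zeroing of
  same-signed components; the variant that zeroes same-sign cases exists in
  the literature but the unzeroed rule is what the arithmetic of the
  reference results requires.
- **Tie-breaks.** Every residual tie (rank-list build, Borda scores, ranking
  table, equally close merge pairs) resolves by identifier ascending, so
  every stage is deterministic and two runs with the same seed are
  byte-identical.
- **Merge weighting.** A merged PRL carries no extra weight in later
  footrule comparisons (unweighted agglomeration, the simplest reading of
  the scheme); the merge trace records every step so a weighted variant can
  be compared later.
- **Serialisation.** All artifacts are plain TSV; distances are written with
  12 significant digits (round-trip relative error ≤ 5e-12), ranks exactly.
  The run manifest stores the configuration and SHA-256 hashes of the
  artifacts and deliberately contains no timestamps.
- **Degenerate inputs.** Identical experiment and control samples produce
  the lexicographic ordering (every ratio is 1 at both thresholds);
  constant-intensity samples are valid (quartile = the constant); rank
  lists shorter than 4 probes, non-positive intensities, 2n > N signatures
  and mismatched universes are rejected with explicit errors.

## Problem sizes used in the test suite

Deterministic fixtures use 4–1000 probes. The recovery-power experiment
runs the full pipeline (63 rank lists of 2000 probes, 21 merges, a 21×21
distance matrix) for 100 seeds at overlap 0.8 and 200 seeds at overlap 0,
at signature size 100 — about two minutes in total on one core. The
published-arithmetic check in `scripts/acceptance.py` is instantaneous: the
four per-direction enrichment scores it combines are printed inputs, and
the package recomputes the two-sided scores and the distance from them.

## Known limitations

- Probe→gene mapping, GEO/SOFT ingestion and platform annotation are out of
  scope; inputs are delimited text over an already harmonised probe space.
- The method compares bulk rank profiles; single-cell sparsity (zero
  inflation) would break the positivity assumption and needs upstream
  handling.
- No significance estimate accompanies a distance: the pipeline ranks, it
  does not test. A permutation null for ES could be added, but distances
  near 1 should simply be read as "unrelated".
- Average linkage for the clustergram is a convention, not a claim; only
  the qualitative block structure of the distance matrix is meaningful.
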