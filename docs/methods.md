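# Methods

`dockrank` implements the consensus stage of a docking-based virtual
screen: several scoring functions each rank the same compound library,
and a single consensus ranking is sought that is as close as possible to
all of them. The package also provides the evaluation machinery (nDCG
against an activity reference, detection-rate enrichment) and a generic
3D pharmacophore pre-filter.

## Rank model

Items are opaque string ids. A ranking is a total order with 1-based
ranks, rank 1 best. Scores convert to ranks deterministically: sort by
score in the declared direction, ties broken by ascending item id.
Average ranks are deliberately not used — the footrule objective and the
permutation sampler both require total orders, and the tie rule makes
every run reproducible. Docking energies and EC50-style potencies both
default to lower-is-better.

## Distances and the aggregation objective

For rankings L1, L2 over a common universe,

    S(L1, L2)  = Σ_t |r_L1(t) − r_L2(t)|                       (footrule)
    WS(L1, L2) = Σ_t |M(r_L1(t)) − M(r_L2(t))| · |r_L1(t) − r_L2(t)|

and the consensus objective for weighted input lists is
Φ(δ) = Σ_i w_i · d(δ, L_i), minimized over permutations δ.

The importance function M is not fixed by the method's definition, so two
conventions are shipped:

* `linear_rank` (default): M(r) = (n − r + 1)/n, parameter-free and
  top-weighted. Note that then |ΔM| = |Δr|/n, so each WS term is
  (Δr)²/n — the weighted footrule with linear-rank importance is a
  Spearman-ρ-type (squared-difference) criterion. Its exact minimizer is
  the mean-rank (Borda) ordering, which is why this metric is the default
  for the scorer-subset sweep: squared rank differences both emphasize
  top-of-list agreement and average away independent scorer noise.
* `normalized_score`: M is the min-max normalized raw score within each
  list (1 = best). Requires scores on both lists; constant scores give a
  constant M and a vanishing distance, which is reported as 0 rather than
  an error.

Partial (top-k) lists: in `assign_k_plus_1` mode an item missing from a
list receives rank k+1 there (the standard top-k footrule convention) and
importance 0; `strict` mode (default) rejects universe mismatches.

All distances are exact sums of products of small integers and ratios in
double precision; no tolerances are needed.

## Consensus search

`aggregate_ce` is a cross-entropy Monte Carlo search over permutations.
An n×n item-by-position probability matrix P starts uniform. Each
iteration draws `n_samples` permutations position by position (column
distribution renormalized over unused items, with a 1e-12 probability
floor so no cell becomes absorbing), evaluates Φ for all of them,
selects the ⌈ρ·n_samples⌉ best as the elite, and updates
P ← (1−w)·P + w·(elite frequency matrix). The search stops after
`max_iterations` or when the incumbent best Φ has not improved for
`stagnation_limit` iterations.

Defaults: n_samples = max(200, 10n), ρ = 0.1, w = 0.25,
max_iterations = 100, stagnation_limit = 15. A seed is mandatory and the
entire run — sampling, trace, result — is bitwise reproducible from it.

Two design points matter in practice:

* The returned permutation is the best ever *sampled* (the incumbent),
  not a mode of P, guarding against smoothing-induced drift.
* The incumbent is finished with a deterministic best-improvement
  pairwise-swap descent (each swap changes only two items' terms of Φ, so
  it is O(m) to evaluate). This memetic refinement is essential at
  realistic scale: at n = 107 the raw sampler's incumbent sits far above
  the true optimum, while the polished result matches the exact
  assignment-problem optimum on every synthetic ensemble we generate.
  The refinement can only lower Φ and can never pass below the global
  optimum, so oracle comparisons remain valid.

Because Φ decomposes as Σ_t cost(t, position(t)) for both metrics, the
exact consensus is a minimum-cost bipartite assignment. The test suite
uses `scipy.optimize.linear_sum_assignment` as an independent oracle for
this; the shipped aggregator is the cross-entropy search, kept because it
extends to objectives that do not decompose. `aggregate_brute_force`
(n ≤ 8) is the second, enumeration-based oracle, returning the
lexicographically smallest optimal permutation.

Aggregation with `normalized_score` weighting is rejected: a sampled
candidate carries no raw scores to normalize.

## Evaluation

DCG at cutoff p is rel_1 + Σ_{i=2..p} rel_i / log2(i) (log base 2,
position 1 undiscounted); nDCG_p divides by the ideal (relevance-sorted)
DCG_p. The headline scalar comparing a candidate against a reference is
the arithmetic mean of nDCG_p over all cutoffs p = 1..n; single-cutoff
reporting (`--at-p`) is available. Relevance conventions: `linear`
(default, rel = n − r_ref + 1, parameter-free), `exponential`
(rel = 2^(1−r), kept finite for long lists), and `binary` (activity ≤
threshold, mirroring a 10 µM active/inactive split). The replication
harness sweeps conventions because published nDCG values are sensitive to
this choice and the original convention is not stated.

`subset_sweep` evaluates every non-empty scorer subset (singletons
directly, larger subsets via the consensus search, each with a sub-seed
derived from the base seed) and sorts by mean nDCG. `detection_rate`
takes the top max(1, ⌊f·n⌋) items and reports the fraction carrying a
positive label; the floor convention makes the top decile of a 305-item
list exactly 30 items.

## Synthetic ensembles

The generator plants the statistical structure the complementarity
argument assumes: latent affinity u_t ~ N(0,1); scorer k emits
s_k(t) = −α_k u_t + β_g η_g(t) + σ_k ε_kt (lower is better); the
reference ranks by u with an EC50-like activity 10^(−u). Scorers sharing
a redundancy group g load on the same noise η_g — near-duplicate views
whose errors correlate.

The canonical study condition (`complementary_plus_redundant_spec`) uses
n = 107 items (the size of the EC50-ranked benchmark the method was
demonstrated on), three complementary scorers (α = 0.5, independent unit
noise — a scorer-affinity correlation of ≈ 0.45, matching how weakly
individual docking scores track measured affinity) and one redundant
near-duplicate of the third (shared-noise weight 0.9, private sd 0.45,
total noise ≈ 1.0, error correlation ≈ 0.8). Under these conditions the
consensus of the complementary trio reliably outperforms the best single
scorer, and full-sweep winners tend to exclude the redundant pair — the
qualitative phenomenon the consensus-docking argument predicts. The
generator emulates rank structure only: it does not reproduce the numeric
distributions of real docking scores, so passing tests demonstrate the
statistical logic of consensus ranking, not docking accuracy on real
proteins.

## Pharmacophore engine

A model is a set of typed feature spheres (types Hyd, Acc, Acc2, Don,
Don2, ARO; Acc2/Don2 are projected acceptor/donor variants that also
accept plain Acc/Don points) plus excluded-volume spheres, with a
partial-match threshold that defaults to all features and can never drop
below 3 (the minimum for a meaningful rigid 3D superposition).

Matching searches injective, type-compatible assignments of detected
feature points to model features, pruned by pairwise distance
compatibility (|d_points − d_model| ≤ tol_i + tol_j) — an efficiency
device only; acceptance is defined by the post-superposition test: after
least-squares rigid superposition (Kabsch, proper rotations only) every
assigned point must lie within its feature's tolerance sphere and no
heavy atom may fall strictly inside an excluded volume. Hydrogens are
ignored in the volume test because SDF inputs often leave them implicit.
Among accepting assignments the largest, then lowest-RMSD one wins.
Matching is therefore invariant under rigid motion and atom reordering of
the conformer. Near-collinear point sets make the fitted rotation
ill-conditioned about the line axis; the sphere test remains valid but
the excluded-volume verdict can depend on the arbitrary axis choice, so
models should use non-degenerate feature geometry.

Feature detection is rule-based (SMARTS per type; defaults cover
donors, acceptors and aliphatic/aromatic hydrophobes; aromatic rings
yield an ARO point at the ring centroid). Conformers for SMILES inputs
are generated with fixed-seed ETKDG (default 20 conformers); abstract
point-set molecules bypass chemistry entirely for matcher tests.

The bundled five-feature template reproduces the published model's
feature-type signature (Hyd|Acc, Acc|Acc2|Don2, Hyd|Acc2, Hyd|Acc,
ARO|Hyd, 8 excluded volumes) but its geometry is a synthetic placeholder:
the original coordinates were never published. The placeholder is
deliberately irregular — no non-identity permutation of its features
superposes onto it within tolerance (minimum non-identity residual
3.6 Å against 1.0 Å tolerances) — so fixture decoys cannot be rescued by
an alternative assignment. Published screening statistics that depend on
the original geometry (sensitivity/specificity, the 305-of-820 pass
count) are consequently out of reach by construction and are not claimed.

Fixture libraries plant hits (one compatible point per feature, jittered
within 0.5·min_tol/√k of the center so the Kabsch fit provably accepts,
then rigidly moved) and three decoy classes: an incompatible point type,
a point displaced beyond any distance-compatible assignment, and a valid
geometry with a heavy atom planted at an excluded-volume center.

## Problem sizes and numerical choices

The test suite and the acceptance script run: 200 random small ensembles
(n = 3..7) for oracle agreement; 1000 random triples (n ≤ 12) for metric
axioms; 25 replicates of the 107-item, 4-scorer synthetic benchmark
(15-subset sweep each); one 107-item, 4-list scale check; and a
100-molecule fixture screen. These sizes were chosen to exercise the
paper-scale regime while keeping a full run in minutes on one CPU.
Floating-point comparisons against enumeration oracles use 1e-9 absolute
slack; distance computations themselves are exact in double precision.

## Known limitations

* The aggregator requires full permutations of a common universe; top-k
  inputs are supported in the distances but must be completed or
  restricted before aggregation.
* Mean-over-cutoffs nDCG is one convention among several; published
  single-number nDCG values cannot be pinned without knowing the original
  relevance convention, which is why the replication harness reports all
  conventions side by side and never asserts a match.
* The pharmacophore engine ships no receptor-derived model: building one
  from protein-ligand complexes (the elucidation step) is out of scope.
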