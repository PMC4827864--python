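# Methods

This note documents the models, statistics and design choices behind
`ompbarrel`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## The shuffle-null comparison score

The homology statistic is a Monte-Carlo standardization of the global
alignment score. For sequences *a*, *b*:

1. compute the optimal Needleman–Wunsch score `S(a, b)` under BLOSUM62
   with affine gaps — gap creation 8, gap extension 2, a gap of length *g*
   costing `8 + 2(g − 1)`, end gaps penalized;
2. draw `N` replicate pairs by independently permuting the residues of
   each sequence (Fisher–Yates under one seeded generator; permuting only
   one sequence is available as an option) and re-score each;
3. report `z = (S − m̂) / ŝ`, with `m̂`, `ŝ` the sample mean and sample
   (n−1) standard deviation of the replicate scores.

Shuffling preserves composition exactly, so the null is conditioned on
the composition of the two specific sequences. That is the point of the
statistic: membrane proteins are strongly biased toward hydrophobic
residues, which inflates raw alignment scores and database E-values
computed under average-composition models, but cannot inflate *z*. The
package's null-calibration benchmark draws unrelated 200-mers with 70% of
their mass on I/L/V/F and finds the statistic centered (mean *z* ≈ 0.07
at 1000 pairs) with no pair anywhere near the evidence threshold.

**Evidence rule.** Homology is asserted when *z* exceeds 12 SD over
comparable segments of at least 60 residues (`SegmentRule`). Both
constants are the field's conventional choices for this statistic; the
12 SD bound corresponds to a nominal Gaussian tail probability far below
any plausible database-scale multiple-testing burden, which buys
robustness against the right-skew that the true null score distribution
shows. The rule is deliberately conservative: the skew means nominal
12 SD is not a literal probability statement.

Comparable segments are obtained by trimming alignment *ends only*
(never central columns): among all end-trims leaving at least 60 residues
in each de-gapped segment, the trim maximizing (identity columns − gap
columns) is chosen, ties going to the wider, then left-most window.

Degenerate nulls (zero variance, e.g. homopolymers) yield a flagged
result with `z = NaN` rather than an exception.

The number of shuffles defaults to 2000. The z estimate's relative error
scales as `(2N)^(-1/2)`, so 2000 shuffles give ~1.6% precision; where the
package runs thousands of comparisons in its benchmark battery it uses
200–500 shuffles (2.2–5% precision), which is irrelevant against the
12 SD decision margin. The protein-pair counts, seed counts and barrel
counts used by each benchmark are in `ompbarrel/benchmarks.py` and were
chosen so the whole battery runs in minutes on one CPU.

## Transitive homology and superfamilies

Homology is transitive: if A~B, B~C, C~D are each established, A~D holds
regardless of the direct A–D score. `verify_chain` evaluates an A–B–C–D
chain by aligning each linked pair, extracting the best comparable
segment, and computing the shuffle score; the chain is accepted when all
three links strictly exceed 12 SD. A direct A–D comparison reaching the
threshold short-circuits the chain (reported with method `direct`).
Intermediates are selected automatically as the top-k (default 10)
cross-family Smith–Waterman candidates, replacing the manual candidate
picking the procedure traditionally involved.

Superfamily assignment is the transitive closure: families are nodes,
accepted chains/edges connect them, and connected components (via
networkx) are labelled SFI, SFII, … in decreasing size order. Families
without accepted evidence have status `no evidence` — the pipeline never
claims non-membership, because failure to detect homology is not evidence
of its absence.

The iterative family-expansion step emulates profile-search gathering
locally: iteration 1 collects database sequences with local-alignment
E-value ≤ 1e-4 against the seed, iteration 2 re-searches with each
gathered member at 1e-6. E-values use Karlin–Altschul statistics,
`E = K·m·n·exp(−λS)`, with gapped λ and K frozen from the NCBI BLAST
tables for the configured matrix/gap combination (for BLOSUM62 with this
package's 8/2 convention: λ = 0.201, K = 0.012). This is a simplification
of true PSSM iteration; it reproduces the gather-then-tighten behavior,
not position-specific scoring.

## Score-based trees

Protein-level distances come from all-vs-all local alignment:
`b = (λS − ln K)/ln 2` (bits), then
`d(i,j) = 1 − b(i,j)/min(b(i,i), b(j,j))`, clipped to [0, 1], with
non-positive scores saturating at 1. Trees are neighbor-joining
(dendropy), with negative branch lengths floored at zero and the deficit
moved to the sister branch.

Support comes from a majority-rule (>50%) consensus of 100 replicate
trees. The published score-tree programs do not document their replicate
unit, so replicate generation here is this package's own, pluggable
choice: each taxon's *score profile* is its distance vector to all taxa;
a replicate resamples, with replacement, which taxa serve as profile
coordinates and uses mean profile dissimilarity `mean_r |d(i,r) − d(j,r)|`
as the replicate distance. Relationships supported across the whole
profile survive every resampling; those resting on few coordinates lose
support. A `strategy="none"` control makes all replicates identical
(supports 100), and leaf order is canonicalized so the consensus is
invariant to input order.

Family-level trees use the **net divergence** between families: the 10%
two-sided trimmed mean of cross-family member distances minus the average
of the two mean within-family distances, floored at zero (so duplicated
families sit at distance zero). Replicates resample members within each
family. At least 5 members per family are recommended — accuracy measurably
degrades with single representatives — and sparser families are flagged
with a warning but retained.

The MSA baseline (`msa_tree`) aligns with MAFFT and applies NJ to
alignment p-distances. On low-divergence families it agrees with the
score route at the family level; at high divergence with hairpin
gain/loss it loses family monophyly measurably faster than the
score-based tree (the benchmark counts monophyletic families over seeded
replicates, e.g. 46 vs 40 of 50). The gap is smaller than older
progressive aligners would show: MAFFT is a far stronger aligner than the
tools that originally motivated score-based trees.

## Topology profiles and the strand caller

Per alignment column the profile reports: mean windowed Kyte–Doolittle
hydropathy over non-gap rows (window 9, odd); mean windowed hydrophobic
moment `|Σ h_k e^{iδk}|/W` at δ = 180° (the β-strand periodicity — one
residue per strand "rung"; 100° serves for helices); and conservation as
1 − normalized Shannon entropy of the column. Columns under 50% residue
occupancy are masked for strand calling. The 180° moment is computed with
exact ±1 alternation so the caller is exactly mirror-symmetric under
sequence reversal.

The strand caller is intentionally simple (an HMM was deliberately not
built): a 10-residue window scores
`moment₁₈₀ + max(0, mean hydropathy)`; windows at or above a fixed
threshold are accepted greedily by descending score, subject to
non-overlap with at least a 3-residue (turn-like) separation, ties
resolved by distance from the sequence center (mirror-invariant). The
threshold (0.9) and separation (3) were calibrated once against the
synthetic generator — true-strand windows score ≈ 2.2 on average, loop
windows ≈ 0.45 — and are stored as named constants. On the generator's
8–28-strand barrels the caller reaches ~84% residue-level recall with
family-modal counts within ±2 of truth.

Single-protein topology prediction is intrinsically noisy; the headline
operation is therefore the family consensus — the modal strand count over
members — which averages out per-protein errors. Family tallies of modal
counts feed topology-distribution summaries.

## Hairpin repeat scanning

Hairpin units pair consecutive strands — by default the disjoint tiling
(1,2), (3,4), …, matching the tandem-hairpin amplification model — and
span strand *k* through strand *k+1* including the connecting turn
(strand+turn windows, one of two defensible unit definitions). Unit pairs
are compared with the shuffle statistic on a *local* alignment with gap
creation reduced to 4 (units are short); each hit reports *z* and the
empirical p-value `(1 + #{null ≥ obs})/(N + 1)`. Units are far below
60 residues, so hits are never labelled "homology established" — the
12 SD rule is reserved for full-length segments. The empirical p is not
comparable to HMM–HMM repeat-detection P-values; it is a plain
composition-conditioned exceedance probability.

**A caveat the simulation surfaced.** Architecturally periodic but
*unrelated* hairpins — independent strands, same amphipathic alternation —
score systematically above the shuffle null (z ≈ 2–6), because the
shuffle destroys the very periodicity both units share. This is the
convergent-similarity problem for short membrane-embedded segments in
miniature, and it is why the scan's output is ranked evidence, not a
homology verdict. The null-calibration benchmark therefore uses i.i.d.
sequence with barrel-like *composition* (no planted periodicity), which
isolates the statistic's intrinsic false-positive rate (clean at
p < 0.001); on structured-but-unamplified barrels the scan reports
elevated but non-top-ranked pairs, and amplified units still outrank that
background decisively.

## The synthetic generator

`simulate` produces β-barrel-like families with exact ground truth:

* **Architecture.** 4–14 hairpins (8–28 strands); strands of 10 residues
  alternating membrane-facing hydrophobic and pore-facing polar positions,
  with a 15% chance per position of escaping its class (real strands are
  imperfectly amphipathic); turns of 3–6 and loops of 5–14 polar-rich
  residues; an N-terminal leader. Protein lengths land in the realistic
  150–1400 aa span and grow with strand count.
* **Amplification.** Optionally one hairpin is copied into *n* tandem
  positions with per-copy divergence (default benchmark: 4 copies at 30%),
  emulating the proposed ancestral amplification of a two-strand unit.
* **Evolution.** Members evolve independently from the ancestor:
  substitutions are BLOSUM62-weighted (`P(a→b) ∝ exp(0.32·s(a,b))`),
  strand positions substitute within their physicochemical class at 0.7×
  the loop rate (purifying selection; this is what makes conservation
  peaks co-locate with strands, as real family profiles show), and indels
  (geometric lengths, mean ≈ 3) are confined to loops — so strand
  coordinates survive evolution exactly and every member carries exact
  topology ground truth. A hairpin-turnover mode deletes or duplicates
  whole hairpins to emulate strand-number evolution.
* **Calibration.** Divergence is user-specified as expected percent
  identity (how practitioners reason), realized by bisection on the
  per-site substitution probability against measured global-alignment
  identity (denominator: shorter sequence). Unattainable targets (below
  the generator's identity floor of roughly 20%, set by the conserved
  strand architecture) raise an error. Same seed ⇒ byte-identical output.
* **Superfamilies.** Ancestors evolve down a binary guide tree with a
  per-edge identity target; leaf families are then expanded. The guide
  tree, membership and strand coordinates are emitted as ground truth.

**What the generator does not emulate** — and hence what green tests do
not certify about real data: real substitution heterogeneity across sites
and lineages (no rate variation beyond the strand/loop split), domain
fusions and passenger domains (the multi-domain autotransporter problem),
signal peptides, fragmentary database sequences, non-β-barrel members
mixed into families, and realistic loop-length evolution. The generator's
families are also phylogenetically "clean" (star-like within families),
which favors every tree method; relative comparisons between methods are
meaningful, absolute accuracies are optimistic.

## Benchmark study conditions

The validation battery (`ompbarrel.benchmarks`, also run by
`scripts/acceptance.py`) uses these fixed conditions:

* null calibration: 1000 unrelated biased-composition 200-mer pairs,
  200 shuffles each;
* chain recovery: 20 seeds; hub family with two ends at 30% expected
  identity from the hub (just above the divergence floor; links calibrate
  to ≈ 18–20 SD, direct end-to-end ≈ 6–10 SD), members at 85% within
  identity, 500 shuffles;
* partition recovery: 20 seeds; two independent 3-family superfamilies
  (guide `((A,B),C)`, branch identity 65% — every within-superfamily pair
  detectably homologous, since the most distant pairs span three tree
  edges — 4 members at 70%), top-2 bridge candidates per family pair,
  500 shuffles;
* tree recovery: 10 seeds; 5-family guide `(((A,B),C),(D,E))` at branch
  identity 50%, 5 members at 55%, 100 consensus replicates; the MSA
  contrast uses branch identity 25%, members at 25% with hairpin turnover
  3 and indel rate 0.08;
* strand caller: 50 barrels cycling 8–28 strands, family-modal counts
  from 5 members at 60% identity;
* repeat scan: 20 amplified barrels (4 × one hairpin at 30% divergence)
  and 40 i.i.d. composition-matched null sequences, 1000 shuffles.

## Known limitations

* The Karlin–Altschul table covers the shipped matrix/gap combinations
  only; other combinations need user-supplied parameters (the code fails
  with an instructive error rather than guessing).
* The family-expansion step is a local-search emulation of iterative
  profile searching, not a PSSM method; its sensitivity on real databases
  will be lower.
* The strand caller is a windowed heuristic calibrated on the generator;
  on real sequences it is a rough topology sketch, and only the
  family-consensus count should be trusted.
* Consensus supports are conditional on the package's replicate scheme;
  they are comparable within this package, not across bootstrap flavors.
* The shuffle statistic conditions on composition but not on periodicity;
  for short membrane-embedded segments, convergent architectural
  similarity can produce elevated scores (see the repeat-scan caveat).
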