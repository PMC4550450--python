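# Methods

## Substitution model and distances

The amino-acid model is the Dayhoff-1978 empirical matrix: symmetric
exchangeabilities `S` (the canonical integer table) and equilibrium
frequencies `π`. The rate matrix is `Q_ij = S_ij π_j` off the diagonal,
diagonal set for zero row sums, scaled so `−Σ_i π_i Q_ii = 1`; distances are
therefore in expected substitutions per site. Transition matrices
`P(t) = exp(Qt)` are computed once per `t` by eigendecomposition of the
`√π`-symmetrized rate matrix (cached), with rows clipped to `[0, 1]` and
renormalized against rounding error; this agrees with scaling-and-squaring
matrix exponentials to ~1e-15.

The **p-distance** of a sequence pair is the fraction of differing residues
over pairwise-complete sites: any site where either sequence has a gap or
an ambiguous `X` is excluded for that pair only ("pairwise deletion"). The
**Dayhoff distance** maximizes the two-sequence likelihood
`Σ C_ij log(π_i P_ij(t))` over `t ∈ [1e-6, 10]`, where `C` is the 20×20
site-pattern count matrix of the pair. `C` is symmetrized (`C + Cᵀ`) before
optimization — by time reversibility this shifts the log-likelihood by a
constant, leaves the optimum unchanged, and makes `d(a,b) == d(b,a)`
bit-for-bit. The optimum is bracketed by a 50-point log-spaced grid and
refined by Brent's method (xtol 1e-7); identical pairs return exactly 0; a
likelihood still rising at the upper bound (saturation) returns the cap
`d_max = 10`.

Two calibration facts worth knowing:

* The estimator is consistent — maximizing over the *expected* pattern
  counts recovers the generating `t` to six decimals — but the sampling
  distribution at 219 sites is discrete. At `t = 0.05` (≈10.6 expected
  differences) the sample median of a few hundred replicates sits close to
  the atoms at 10 vs 11 observed differences, so small-batch medians can
  sit several percent below `t` even though the large-sample median bias is
  ≈0.15%.
* `d ≥ p` is a rule of thumb, not a theorem: the likelihood of *unchanged*
  sites depends on their residue composition, so a pair whose conserved
  sites are rich in fast-exchanging residues can have an ML optimum
  slightly below its p-distance (observed undercuts are ≤ ~1.5e-3 at low
  divergence). The two metrics coincide closely below 0.20 and diverge
  substantially above it, which is why downstream summaries use the ML
  distance.

Equilibrium frequencies come from the model, not the data pair; this keeps
the distance symmetric and matches common practice. No among-site rate
heterogeneity is modelled; no other empirical matrices are bundled, though
`SubstitutionModel.from_exchangeabilities` accepts any reversible model.

## NUMT screening, translation, representatives

Translation uses the invertebrate mitochondrial code (NCBI table 5;
configurable). QC translates all three reading frames, picks the frame with
the fewest stop codons (ties → lowest frame index), and passes a record only
if that frame is stop-free and spans at least 150 complete codons (default;
the minimum length is exposed because real barcode sets contain fragments).
Codons containing any non-ACGT symbol translate to `X`. One representative
per BIN is chosen among QC-passing records by (longest sequence, fewest
ambiguous bases, lexicographically smallest record id) — the last key makes
selection order-independent. Records failing QC are excluded from
representative selection; voucher-backed failures remain available to the
indel support pool, mirroring the asymmetry between trace-validated records
and unverifiable mined ones.

## Consensus frame and alignment

Every representative protein is aligned pairwise against a class-wide
consensus rather than through a progressive multiple alignment: COI proteins
are near-fixed length, and a fixed reference frame makes indel coordinates
deterministic and reproducible. Scores are half-bit log-odds from the
package's own model at 250 PAM (`2·log2(P_ij(2.5)/π_j)`, symmetric by
reversibility); gaps are affine with open 10, extend 1 (a gap of length L
costs `10 + L`), and the global Needleman–Wunsch/Gotoh optimization is
delegated to biopython's `PairwiseAligner` (verified against a brute-force
DP oracle in the tests). Alignments scoring below a configurable floor are
flagged unalignable and excluded with a warning.

The consensus is bootstrapped: the seed is the column majority over all
full-frame (219-residue) sequences — anchoring at the standard barcode
length rather than the modal length keeps coordinates stable even when
deletion-bearing clades dominate a sample — followed by two align-and-
rebuild iterations. The second iteration matters: the seed majority is
computed from indel-free sequences only and can deviate from the ancestral
residue at near-tied sites, which occasionally shifts gap placements;
re-aligning against the full-sample consensus removes most of these.
Consensus sites are numbered 1–219 and never renumbered; insertions are
recorded as "after site s". Ties in the per-column majority go to the
alphabetically first residue; all-gap columns stay gaps.

## Hierarchical distance summaries

Per order: **Order Distance** averages each BIN's distance to the outgroup
first within families, then (unweighted) across families — so species-rich
families do not dominate. **Family Distance** is, per family, the mean
distance between its BINs and the BINs of every other named family in the
same order, averaged unweighted across families; it is undefined for
single-family orders. **BIN Distance** is the mean within-family BIN-pair
distance, undefined for single-BIN families. **Overall Distance** is the
mean of the three and is reported only when all three exist. Records with
an empty family name are excluded from family averaging but their outgroup
distances are reported under an empty label. Standard errors are the sample
SD over the values averaged at each level (family values for order-level
metrics; within-family pairs for a family's BIN Distance) divided by √n;
n = 1 yields NA. Reported tables round to 3 decimals, round-half-even.

The rank-elevation sensitivity test (`elevate_rank`) relabels every genus
of one order as a family (BINs with no genus keep their family) and recomputes
the summaries; an order with one genus per family is invariant under it.

## Indels and origin counting

Indel events are keyed by (kind, start site, length) in consensus
coordinates; deletions at neighbouring sites are distinct events. Maximal
interior gap runs in a row are deletions; terminal runs are treated as
missing data (truncated sequences), not deletions. Validation keeps an
event if it has ≥ 2 supporting records spanning two records of one family
or two families, or if its sole member is voucher-backed. Region
classification assigns each event the label of the (1-based, inclusive,
non-overlapping) interval containing its start site.

The guide tree expands an order-level backbone topology (Newick, a packaged
published-topology default for arachnid orders; any backbone can be
supplied) into family → genus → BIN polytomies from the taxonomy table.
Origins per event are counted by a binary-character parsimony DP over the
(possibly multifurcating) tree: for each node and state the DP carries the
lexicographic minimum of (total changes, 0→1 gains), with the root fixed at
absence; the reported count is the gains of that optimum — i.e. among all
most-parsimonious reconstructions, the one with fewest independent gains.
Polytomies from unresolved taxonomy can only merge gains, so counts are
lower bounds ("at least N origins"). The DP equals exhaustive enumeration
of ancestral states on all trees small enough to enumerate.

## Statistics

Regressions are ordinary least squares with two-sided slope *t*-tests on
n−2 degrees of freedom; incomplete pairs are dropped; no multiple-testing
correction is applied. The two-sample contrast is Welch's *t* with
Satterthwaite degrees of freedom — chosen over the pooled test because
group variances at the family level differ several-fold; both groups
constant with equal means returns t = 0, p = 1.

## The simulator

`simulate_dataset` emulates a curated barcode dataset with known truth. Its
defaults are the package's study conditions:

* **Sites**: 219 codons; root protein drawn from π.
* **Tree**: root at height `tree_height` (default 0.15 expected
  substitutions/site at rate 1, placing outgroup and within-order
  divergences in the 0.05–0.6 range real class-level barcode data shows).
  The outgroup hangs from the root on a branch of length `tree_height`;
  each order's stem attaches at 0.6 of the height; family splits at
  U(0.25, 0.55) of the height; genus splits at U(0.3, 0.6) of the family
  height; BINs are tips. Every branch inside an order is multiplied by the
  order's `rate_multiplier`, so within-order distances scale exactly with
  it and outgroup distances increase monotonically in it.
* **Sequences**: site-wise CTMC sampling from `P(branch length)`;
  back-translation draws uniformly among table-5 synonymous codons;
  `ambiguous_base_rate` of nucleotides become N; `numt_fraction` adds
  frameshifted (1-nt insertion) duplicates of random BINs flagged as mined;
  about two-thirds of records are flagged voucher.
* **Indels**: deletions only (insertions are vanishingly rare in real COI),
  Poisson per branch at `indel_rate · branch length · 219`, length uniform
  1–5, inherited by all descendants. Placement is rejected near sequence
  ends, within 3 sites of an existing deletion on the lineage, where
  flanking residues would make the gap placement ambiguous, or where the
  two-residue flanking windows have substituted away from the root state;
  those windows are additionally held fixed in the descendant clade. These
  identifiability constraints are what make the injected registry exactly
  recoverable; the truth bundle also carries each leaf's exact root-frame
  alignment, and recall is defined against it. Through the *estimated*
  consensus alignment, recovery of exact coordinates is ≈98% under default
  conditions (the residue-level consensus occasionally differs from the
  ancestral state next to an event); the per-row gap *count* is still
  recovered exactly for well-separated deletions.
* **Randomness**: one seed stream for global draws plus one spawned
  sub-stream per order, so editing one order's parameters does not perturb
  the others. Identical configurations produce byte-identical outputs.

What the simulator does *not* emulate: BIN-clustering itself (BIN ids are
assigned by construction), rate variation across sites, codon usage bias,
sequencing error beyond uniform N's, within-BIN haplotype variation, and
fragmentary sequences. Passing tests on simulated data therefore certify
the pipeline's machinery — selection, alignment, distance estimation,
aggregation, parsimony — under a clean generative model, not the curation
judgement real barcode datasets require.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
hundreds of random pairs for distance properties, 200 replicates per level
for estimator calibration, 20 pipeline replicates of 3 orders × 20 BINs for
rate-structure recovery, and a bundled 33-BIN fixture for end-to-end
regression. These sizes give stable Monte-Carlo summaries for every check
while keeping a full run in minutes on one core; the library itself has no
such limits (the distance stage is O(n²) pairwise fits of ~milliseconds
each).
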