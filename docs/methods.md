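# Methods

This note documents the models, algorithms and design choices behind
`chimeradx`, and what the synthetic study conditions do and do not show.

## The question and the overall procedure

A two-domain protein is suspected to be a chimera: domain A vertically
inherited within eukaryotes, domain B acquired from bacteria by
horizontal transfer into a germ-line genome. The diagnosis rests on
three converging signals, computed by independent stages:

1. the taxonomic provenance of database hits along the protein
   (sliding-window profile search): windows in domain A should hit
   eukaryotes, windows in domain B bacteria;
2. similarity-network affinity: the focal domain-B sequences connect to
   bacterial, not eukaryotic, nodes at a 30% identity threshold;
3. phylogenetic placement: the focal domain-B clade branches *inside*
   the bacterial family (nested), not as its sister group, and
   constraining eukaryote monophyly significantly worsens the
   likelihood (SOWH test).

A `nested_in` call is only reported when the SOWH test supports it;
nested placement whose constrained alternative is not significantly
worse is demoted to `unresolved`.

## Substitution models

`SubstitutionModel` is a reversible 20-state CTMC: symmetric
exchangeabilities S, equilibrium frequencies π, rate matrix
Q_ij = S_ij π_j scaled to one expected substitution per site per unit
branch length. Across-site rate variation uses the discrete-gamma
approximation with equal-probability categories represented by their
conditional means (category rates average exactly 1). Two canonical
models ship: **LG** (published empirical exchangeabilities and
frequencies; `+F` variant substitutes observed frequencies) with default
gamma shape 1.0 and 4 categories, and **Poisson** (equal rates, equal
frequencies), kept because several closed forms exist for it — e.g. the
two-taxon divergence (19/20)(1 − e^(−(20/19)t)) and the off-diagonal
transition probability (1/20)(1 − e^(−(20/19)t)) used in the tests.

## Likelihood engine and tree search

Likelihoods are computed by Felsenstein pruning over site patterns
(unique columns, weighted), with per-node rescaling and accumulated log
factors against underflow; gaps and `X` are missing data (all-ones
partials). Branch lengths are optimized one edge at a time: with the
eigendecomposition of Q, the site likelihood along an edge is a short
exponential sum in the branch length, so after one postorder (lower
partials) and one preorder (upper messages) pass, each univariate
optimization costs a few small matrix-vector products. The optimizer is
Newton–Raphson on that exponential sum with a bounded-Brent fallback,
and a guard keeps the best length vector seen, so the reported
likelihood never decreases. Branch lengths live in [1e-8, 20].

Tree search is NNI hill-climbing from a stepwise-addition start (taxon
order seeded); candidate moves are scored by re-optimizing only the
central edge, the best improving move is accepted, and all branch
lengths are re-fit after each acceptance. The stop rule is no move
improving lnL by more than 1e-4. SPR-type moves are deliberately out of
scope at these problem sizes; correctness is asserted against
exhaustive-topology and exhaustive-state oracles on small instances, not
against any external program's output. The pipeline runs two
independent starts per tree and keeps the better optimum.

Constraints are sets of bipartitions (from a possibly multifurcating
constraint tree, restricted to the tips present); a candidate tree
complies when it displays all of them. Constrained search rejects
non-compliant NNI moves and uses a compliance-checked stepwise start.

### SOWH test

δ = lnL(unconstrained ML) − lnL(constrained ML). Null replicates are
simulated on the constrained ML tree under the fitted model; both
searches re-run per replicate (warm-started from the constrained
topology, sharing the initial branch-length fit); p uses the +1/+1
estimator so p is never 0. The adaptive stopping rule of SOWH
implementations that tune the replicate count is not reproduced; the
replicate count is fixed by configuration. With n replicates the
smallest attainable p is 1/(n+1) — at the pipeline's reduced setting of
20 replicates a rejection at α = 0.05 therefore requires zero
exceedances.

## Profile search and E-values

Profiles are per-column log-odds scores (bits): column frequencies are
background-proportional pseudocount mixtures
(counts + w·background)/(n + w), w = 1.0 by default; scores are floored
at −30 bits; columns under 50% occupancy are excluded so gap-dominated
regions do not dilute the model; `X` scores 0 everywhere. This is a
deliberate reduction of a profile HMM: the discovery logic needs
rankings and hit envelopes, not forward-algorithm posteriors, so match
columns plus affine gap penalties (4.0 / 0.5 bits) suffice. Local
scoring is Smith–Waterman-style with deterministic smallest-start
tie-breaking.

E-values are calibrated per profile by fitting a Gumbel law (scipy MLE)
to maximal local scores on residue-shuffled decoys sampled from the
database (length distribution matched); E(s) = N·P(max ≥ s) for a
database of N records. This reproduces E-value *semantics*; absolute
agreement with any specific search program is not a goal.

The provenance profile slides a 60-column window (step configurable,
1 by default; the pipeline uses 6 for speed) along the family alignment,
builds and calibrates a profile per window, searches the database at
E ≤ 0.01 and bins hits as Bacteria / Archaea / Virus / Eukaryota-focal /
Eukaryota-other. The "bacterial-majority signal" reported per window is
a strict majority among **non-focal** hits with at least 3 hits in the
window: the provenance question is where a region's *other* relatives
come from, and a demand of three hits keeps single stray hits from
counting as a signal.

## Discovery

A sequence is an architecture hit when profile A and profile B both hit
it at E ≤ 0.01 with the A envelope strictly N-terminal and
non-overlapping (overlaps are logged and skipped, not errors); nothing
is demanded of the linker, which in real chimeras is fast-evolving and
disordered. Manual curation of the original workflow is replaced by
this automatic rule for reproducibility. Each round rebuilds profiles
from the grown alignments (new members are added via profile alignment,
insert states dropped); convergence is id-set stability, so the
accepted set grows monotonically to a fixed point.

## Similarity networks

Edges join sequences whose global-alignment identity (matches over
doubly-ungapped columns) reaches 0.30. Network alignments use stiff gap
penalties (open 40, extend 4, BLOSUM62): the compared domain families
are indel-poor, and permissive gaps would let the aligner cherry-pick
matching columns between *unrelated* sequences of unequal length,
inflating their apparent identity to ~25% and blurring the family
boundary the 30% threshold is meant to detect. The raw score is stored
on each edge so score-based thresholds remain possible. Components are
reported largest-first; the web-service score-to-identity conversion of
the original workflow is replaced by thresholding identity directly.

## Synthetic scenarios (what the generator emulates)

The generator emulates a mixed-taxonomy protein database at desk scale:

* **domain A family**: a eukaryote Yule tree (8 taxa, root-to-tip height
  0.4 substitutions/site) with the fusion clade (4 taxa, height 0.12)
  grafted inside it, plus a 3-taxon bacterial outgroup clade across a
  0.6 + 0.3 stem — the handful of distant prokaryotic relatives such a
  family typically has, and the tree's root;
* **domain B family**: a bacterial Yule tree (8 taxa, height 0.4) with a
  2-taxon archaeal clade branching next to it (stem 0.45) as a
  prokaryote outgroup, and a 4-taxon eukaryotic subclade across
  0.15 + 0.45 stems (the distant eukaryotic relatives that make a
  eukaryote-monophyly constraint meaningful — kept close enough that
  their placement is well resolved, since an unresolvable subclade makes
  the monophyly constraint free to satisfy and the SOWH test powerless);
* **chimera scenario**: the fusion clade's domain B is grafted onto an
  internal, non-root-adjacent branch of the bacterial tree (stem 0.08):
  properly nested within bacteria — subtrees above and below — which is
  the transfer signature;
* **null (vertical) scenario**: it attaches sister to the eukaryotic
  subclade across a 2.8 stem — under vertical descent the fusion
  lineage split from those relatives at the root of the family, so the
  long stem *is* the null hypothesis (and places bacteria beyond
  window-profile reach, as a vertically inherited domain's windows
  show no bacterial signal);
* **fusion proteins**: M + domainA + linker + domainB. The linker
  evolves at 3× the baseline rate with per-lineage lengths drawn from
  30–80 residues (deletions restricted to the linker; domains are
  indel-free so window coordinates stay exact). Domain lengths default
  to 100 and 190 residues;
* **background**: i.i.d. draws from the model's equilibrium frequencies,
  80–250 residues, random domains of life;
* **transcripts**: each fusion gene's CDS (random synonymous codons)
  embedded in random UTRs on a random strand, validated so the longest
  ORF of the six-frame translation recovers the protein exactly.

One integer seed is split hierarchically into per-stage child seeds in a
fixed, documented order (`_child_seeds`), so every run is reproducible.

The generator's default model is LG + gamma with **shape 4** (milder
site-rate heterogeneity than the inference default of shape 1). This is
a study condition, chosen because under shape-1 heterogeneity the
slowest sites keep remote homologs detectable at essentially any usable
distance — short conserved cores score E < 1e-4 at patristic distance
3.4 — so no geometry can make "family boundaries" meaningful at desk
scale. With shape 4 the detection cliffs are sharp: whole-domain
profiles (100–190 columns) reach the outgroup clades while 60-residue
windows see only same-clade relatives, which is precisely the regime the
provenance computation discriminates in.

Stem lengths were calibrated once against these cliffs (window reach vs
whole-domain reach) and then frozen; they are configuration fields, not
tuned per run.

**What passing does not show.** Real databases have non-uniform
composition biases, alignment error from heterogeneous domain
boundaries, gene prediction noise, and genuinely absent homologs rather
than distance-saturated ones; the generator models none of these. The
synthetic scenarios establish that the pipeline's logic and statistics
behave correctly when its assumptions hold — not that the assumptions
hold for any particular real dataset.

## Pipeline defaults and reduced settings

The pipeline defaults to LG+F with 2 gamma categories (shape 1.0),
E ≤ 0.01 throughout, 100 decoys per calibration, window step 5, SOWH on
the putative HGT domain only (`sowh_mode: nested_only`) with 100
replicates. Batch experiments (the acceptance script and the
calibration tests) use reduced settings — 20 SOWH replicates, 1 rate
category, window step 6, no bootstrap — chosen as the smallest sizes at
which every decision in the pipeline is still exercised; the methods
and thresholds are identical at all sizes.

## Numerical conventions

* Residue coordinates are 1-based inclusive everywhere.
* DP tie-breaking: match > consuming the first sequence (or profile
  column) > consuming the second; local alignments prefer the smallest
  start. All outputs are bit-stable for fixed inputs.
* Occupancy trimming keeps columns with non-gap fraction ≥ the
  threshold (inclusive at the boundary, 0.70 by default).
* The longest-ORF rule requires an initiator methionine and breaks ties
  by frame order then leftmost position; a database with no M-initiated
  open frame yields an empty, flagged result rather than an error.
* Duplicate residue strings are merged into one record with unioned
  provenance; conflicting taxonomy labels merge to `Unknown` with a
  warning, and the merge is idempotent.
* Report JSON is sorted-key, fixed-precision; identical configuration
  and seed reproduce it byte for byte.

## Known limitations

* NNI-only search can miss optima that require SPR moves; mitigated by
  two starts and warm-started SOWH replicates, and irrelevant at oracle
  sizes where correctness is proven exhaustively.
* Gumbel calibration from 100–200 decoys extrapolates the tail; E-values
  far below ~1e-3 are order-of-magnitude statements.
* The profile is not a full Plan-7 HMM: no insert-state emissions, no
  glocal mode, no posterior decoding.
* Saturated placements (e.g. the null scenario's long fusion stem) are
  reported as `unresolved`/`outgroup_to` rather than resolved — by
  design, since a confident wrong call is worse than an abstention.
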