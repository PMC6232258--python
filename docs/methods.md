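# Methods

## Scope and model overview

`symgras` re-implements, as a tested library, a phylogenomic screening
procedure for the GRAS transcription-factor subfamilies acting downstream
of the common symbiotic pathway (NSP1, NSP2, RAM1, RAD1). The procedure
has four parts: (1) a profile HMM per subfamily, estimated from a curated
seed alignment cropped to the GRAS domain; (2) an acceptance cutoff per
subfamily anchored on a labeled reference gene phylogeny; (3) per-sequence
classification from the cutoffs; (4) tabulation of per-species copy
numbers and reconstruction of lineage-specific losses and expansions on a
species tree. A synthetic-data generator provides fully labeled inputs so
every stage is testable without genome downloads.

## Profile HMMs

Architecture: one match/insert/delete node per conserved seed-alignment
column (Krogh-style), with all nine within-node transitions permitted
(M/I/D each to M/I/D of the next node). Allowing I→D and D→I keeps
estimation honest for seed rows in which an insertion is immediately
followed by a deletion; the more common plan7 restriction would force an
arbitrary rerouting of such counts.

Match columns are those whose gap fraction is at most
`match_column_gap_threshold` (default 0.5). Estimation uses uniform row
weights, gap-aware emission counts (a gap contributes nothing), and
Laplace pseudocounts with weight 1 against a uniform background by
default. `background_scaled` pseudocounts and an alignment-derived
background are available; all choices are recorded in the model file for
provenance. `X` residues occupy their state for transition counting but
add no emission counts, and score zero bits at scoring time (background
emission). B/Z/U are mapped to D/E/C on input with a warning.

Scoring is *glocal*: the model is traversed begin to end while sequence
flanks are absorbed by flanking insert states that emit the background
distribution, so flank emissions cancel in the log-odds and flank
transitions are scored at zero bits. This is a deliberate divergence from
hmmsearch's default local mode: the seed alignments are already cropped to
the domain, so a hit is expected to span the whole model. Consequently the
bit scores are *not* numerically comparable to HMMER's, and no such
agreement is asserted anywhere; the classification procedure only
compares scores to cutoffs derived from the same scoring function.

All probability arithmetic is in log2 space (no scaling-factor variant).
The within-position delete chain is vectorized with a prefix
log-sum-exp/max transform; when a transition probability is exactly zero
(hand-built models) the code falls back to an explicit loop, since the
cumulative-sum trick breaks down at −∞. The forward recursion is checked
against an independent brute-force enumeration of every state path (all
entry/exit points × all core paths) on models with ≤ 3 match states, to
1e-9 in log space. Viterbi ties are broken preferring match > delete >
insert, and among tied end positions the earliest with a match-state exit,
making the returned path deterministic. An empty sequence is a scoring
error: a zero-length candidate is meaningless for domain detection.

Model files use a versioned plain-text key/value dialect (`symgras-hmm/1`)
with all tables at 12 significant digits; reading genuine HMMER3 `.hmm`
files is explicitly not supported.

## Clade-anchored cutoffs

For each subfamily clade on the (outgroup-rooted) reference gene tree:

* *basalmost members* — the clade members in the child subtree of the
  clade MRCA containing the fewest members, a proxy for the
  earliest-diverging lineage; ties return the union of tied children.
  This operationalizes a concept the source procedure leaves informal.
* *nearest outside clade* — the leaves of the MRCA's sister group,
  excluding outgroup leaves used for rooting.
* the cutoff is the arithmetic midpoint of the minimum basal score and
  the maximum outside score ("between these values" admits any point;
  the midpoint maximizes the margin to both anchors), and the overlap
  flag is raised exactly when the basal minimum does not exceed the
  outside maximum.

When a cutoff overlaps, the clade is merged with the subfamily owning the
plurality of its nearest-outside leaves and a joint cutoff is derived for
the union clade, scored by the best of the component models — the
RAM1/RAD1 pattern, in which the two member lists largely overlap and the
clades are treated jointly. Merging runs to a fixpoint with a small
safety bound. Cutoffs are derived in a single pass; no iterative
re-derivation after classification is performed. Non-monophyletic clade
definitions warn and proceed on the MRCA-subtree members, since manually
curated clades can be slightly inconsistent with the tree.

## Classification

A sequence's score under a (possibly merged) cutoff is the maximum of its
component-model scores. Passing no cutoff gives `unassigned`; passing
several, the highest score wins and the ambiguity flag is raised when the
margin over the runner-up is below `ambiguity_margin` (default 2 bits).
A merged RAM1+RAD1 hit is resolved to the better-scoring component unless
the component margin is itself below the threshold, in which case the
merged label is retained with the flag set — the reference procedure
resolved such cases by joint phylogenetic analysis, which this package
approximates by flagging rather than silently forcing a label. One label
per sequence; multi-domain proteins are out of scope.

Copy counting is per retained sequence id: sequences removed as exact
duplicates during curation are restored through the dedupe map, each
under its own species code. No other isoform collapsing is attempted.

## Loss and expansion reconstruction

Presence/absence is reconstructed under Dollo parsimony: each subfamily
is gained at most once. By default the root is treated as carrying every
subfamily observed in at least one leaf (the land-plant-ancestor
assumption); `root_state="infer"` instead places the gain on the MRCA of
the present leaves and counts it in the cost. Losses are placed on the
shallowest (rootmost) branches whose entire subtree lacks the subfamily,
which both minimizes the number of losses and fixes the placement among
co-optimal solutions.

Copy numbers are reconstructed by Sankoff parsimony over states
`0..max(observed)` with unit cost per copy step and regain from zero
forbidden (the Dollo constraint at copy-number level). Branches that gain
copies emit *expansion* events (duplications), branches dropping to zero
*loss*, other decreases *contraction*. Backtrace ties prefer the child
state differing most from the parent (placing the change on the rootward
branch, consistent with the Dollo placement rule), then the smaller
state; the exact number of co-optimal ancestral labelings is computed by
a counting dynamic program and reported. The implementation is verified
against exhaustive enumeration of all ancestral labelings on trees with
≤ 8 leaves and counts ≤ 4.

Absences observed only in transcriptome data are soft evidence — absence
of a transcript need not mean absence of the gene. Such cells can be
treated as missing data (`transcriptome_absence_as_missing`): the leaf is
marginalized in both reconstructions and never used to justify a loss.
The event report annotates every transcriptome-only absence as
inconclusive regardless of that flag.

On the schematic five-lineage bryophyte example (hornworts, liverworts,
*Takakia*, *Sphagnum*, crown-group mosses) the topology is an input like
any other tree — the branching order of the basal moss lineages is
debated, so nothing is hard-coded outside test fixtures. Note that with
the *Takakia* complement (NSP1=2, RAM1=2, RAD1=3) copy-number parsimony
necessarily infers *Takakia*-branch expansions alongside the Bryophytina
NSP1 expansion; reports on this fixture therefore list both.

## Synthetic data generator

The generator instantiates exactly the structure the classifier assumes:

* a rooted binary species tree from a pure-birth process, leaves named by
  generated five-letter species codes; branch lengths are decorative
  (the analysis is topology-driven);
* per-subfamily profiles: each column mixes the uniform background with a
  one-hot distribution on a column-specific consensus residue, with
  weight `conservation / (1 + conservation)` (default conservation 9,
  i.e. 90% consensus mass — a strongly conserved domain). This
  parameterization realizes both stated limit cases exactly (0 =
  background, ∞ = degenerate columns);
* gene histories from a single copy at the root, with per-branch loss and
  duplication probabilities (defaults 0.05 each, giving a handful of
  events on a 20-species tree). At most one duplication per copy per
  branch, and a duplicated daughter is not exposed to loss on the branch
  it arose on. A subfamily left with fewer than two surviving copies is
  re-simulated with fresh draws — the dataset conditions on the family
  being observable (a seed alignment needs at least two rows); retry
  counts are recorded in the manifest;
* sequences emitted column-wise from the subfamily profile, with
  per-branch substitution noise (default 0.03 per column per branch)
  accumulated along each copy's lineage, and indels applied at emission
  (default rate 0.01 per column). The true alignment is therefore known
  by construction; seed alignments keep the core columns (deletions as
  gaps, insertions dropped) for a deterministic subset of up to 12
  members;
* decoys drawn from the background with the domain's length distribution,
  so rejection is non-trivial in composition and length;
* an outgroup pair (named GAI/RGA after the DELLA proteins conventionally
  used for rooting) from an independent fifth profile, attached basally
  to the combined reference gene tree.

Defaults (20 species, 4 subfamilies, 5 decoys per species, 120-column
domain) are the study conditions used by the acceptance checks. What the
generator does **not** emulate: empirical substitution models (JTT etc.),
site-rate heterogeneity beyond profile conservation, alignment error
(seed alignments are exact), fragmentary transcripts, and genuinely
convergent subfamilies. Passing tests therefore demonstrate correctness
of the machinery and recoverability under the stated model, not
performance on real proteomes, where alignment quality and partial
sequences dominate difficulty.

## Pipeline and determinism

The pipeline runs dedupe → HMM build → scoring → outgroup rooting →
cutoff derivation (with merging) → classification → copy matrix → Dollo +
Sankoff → event report, writing every intermediate as FASTA/TSV/Newick
plus a YAML manifest (config echo, package version, seed, per-stage
counts). Outputs contain no timestamps; identical config + seed reproduce
every file byte-for-byte. Any stage error aborts with a stage-named
message, retains earlier outputs and records the failed stage in the
manifest.

## Problem sizes used in the checks

The shipped checks use sizes chosen for exhaustive verifiability:
forward-oracle comparisons on models with ≤ 3 match states and all 340
sequences of length ≤ 4 over a 4-letter alphabet; Sankoff-oracle
comparisons on 100 random 8-leaf trees (5^7 ancestral labelings each);
end-to-end recovery on the default 20-species dataset plus 200 replicated
gene-content histories for loss-branch recovery. The full suite runs in
well under a minute of compute per stage on one CPU.

## Known limitations

* Bit scores are internally consistent but not HMMER-comparable (glocal
  mode, different pseudocounts); cutoffs must come from the same scorer.
* No E-values, no multi-domain envelopes, no MSV/SSV-style filters: the
  procedure consumes only scores relative to clade-derived cutoffs.
* "Basalmost" via the smaller-child convention is a topology-only proxy;
  with branch lengths available one could anchor on divergence instead.
* Dollo excludes horizontal transfer and regain; the copy model treats
  every copy step as unit cost, ignoring the possibility of single
  events adding several copies (tandem arrays, WGD).
* Tree inference, alignment construction and model selection are inputs,
  not products, of this package.
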