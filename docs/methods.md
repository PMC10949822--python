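# Methods

## Problem and model

A causal loop diagram (CLD) is a directed graph G = (V, E) with a polarity
function σ : E → {+1, −1}. Given k community CLDs describing the same
outcome, the package estimates their common core in three stages:
canonicalisation of variable names, merging into a signed count matrix,
and paring via DEMATEL importance ranking. The result is a small summary
CLD plus a ranking table, with every intermediate artifact exposed.

The procedure assumes the communities map a *shared* problem space: the
summary is only meaningful when the constituent diagrams are comparable
in scope and vocabulary. It also treats every community equally — a link
is weighted only by how many communities drew it, not by who drew it or
how strongly they believe it.

## Variable identity and vocabulary

Variable identity is case-insensitive after whitespace collapsing;
original casing is kept for display (community-entered names are
inconsistently cased, and silently distinguishing `Mental Health` from
`mental health` would corrupt every downstream count). The vocabulary is
deliberately a flat raw → canonical table rather than any clustering: the
semantic judgment of which names denote the same construct is made by
human reviewers; the package applies it, audits every rename/fusion/
collapse, and refuses to guess. Chained mappings (a → b, b → c) are
invalid so application is idempotent. `suggest_synonyms` ranks candidate
pairs by `difflib.SequenceMatcher` ratio on normalised labels (default
advisory floor 0.8) — a cheap, dependency-free normalized edit-similarity
that is good at catching the spelling variants and word re-orderings that
actually occur; it deliberately knows nothing about semantics.

Fusion can create parallel links. Agreeing polarities collapse to one
link (logged); opposing polarities are a hard error, because a signed
merge is only well-defined when every contributor of a link agrees on its
sign, and the study protocol this emulates resolves such conflicts with
the original map builders rather than by vote.

## Merge semantics

The merged matrix M over the union index (sorted case-insensitively for
deterministic output) has M[i,j] = σ(i→j) · |{diagrams containing i→j}|.
Invariants: the merge is order-invariant; Σ|M| equals the total number of
constituent links; |M[i,j]| never exceeds the frequency of either
endpoint. Conflicting links abort the merge by default. The
`resolve="majority"` escape hatch keeps the majority polarity (count =
majority size), drops exact ties, and logs loudly; it exists for
exploratory use on data whose conflicts cannot be sent back to the
communities, and is never the default. Reciprocal pairs (a→b and b→a) are
distinct links throughout, and the unique-link count counts directed
pairs.

## DEMATEL

Direct influence is the matrix of absolute merged counts, used raw: the
analysis is invariant to any positive rescaling of the direct matrix
(s rescales identically), so linear transforms of the counts would change
nothing, and nonlinear ones would need a justification we do not have.
Normalisation uses s = max(max row sum, max column sum), which bounds the
spectral radius of D by 1; a row-sum-only variant is available behind
`normalisation="row"` for comparison. The total relation matrix is
computed by solving (I − D)ᵀ Xᵀ = Dᵀ rather than forming an inverse.

Merged community diagrams are strongly cyclic, and a perfectly balanced
cycle structure can push the spectral radius to exactly 1, making I − D
singular. When the condition number exceeds 10¹², D is damped by
(1 − 10⁻⁶) with a warning instead of failing; the damping perturbs scores
far below the two decimals at which they are reported.

Naming: R is always the row sum of T (influence dispatched), C the column
sum (influence received), so relation R − C > 0 marks a net influencer.
Published prose around such tables sometimes attaches the letters the
other way; the convention here is chosen so that "highest R − C" and
"highest net influencer" coincide, and is stated wherever scores surface.

Ranking sorts by prominence descending, ties broken by relation
descending, then label — a deterministic total order.

## Paring

Reduction order is fixed: variable cut first, then the edge cut on the
induced subgraph. Threshold comparisons are inclusive (prominence ≥ cut),
and sensitivity thresholds are multiplicative, cut × (1 + δ) for
δ ∈ {±0.05, ±0.10, ±0.15} by default: "increase the cut by 5 %" means
exactly that. The edge cut removes links with |count| below 2 by default
— a link only one community drew is not evidence of commonality.
Variables isolated by the edge cut stay in the summary (flagged), since
the variable cut, not connectivity, decides importance. Polarity is
restored from the sign of the merged cell, which under the conflict-free
merge invariant equals the polarity every contributing community drew; a
zero cell for a summary link is an integrity error, not a default.

`suggest_cut` automates the scatter-plot inspection that places the cut
at the "clear boundary" between the prominent core and the long tail. It
returns the midpoint of the largest *relative* gap between consecutive
sorted positive prominence values (the largest gap on a log scale).
Absolute-gap and variance-based (Otsu/2-means) rules were considered and
rejected: prominence distributions are heavy-tailed, so the largest
absolute gap usually separates the top one or two variables from the rest
of the core, and the variance-optimal split strands low-degree core
variables below the cut. The relative gap is scale-free and looks for an
order-of-magnitude drop, which is what visually separates "core" from
"tail" on the scatter. The suggestion is advisory; the operative cut
always comes from configuration, and zero-prominence (isolated) variables
are ignored when locating the gap.

## Synthetic ensembles

The generator emulates a 13-community study producing ~290 unique
variables and ~1,000 unique links after merging. Defaults: 25 core
variables wired into a random weakly connected digraph (an oriented
random spanning tree plus extra arcs, hence cyclic) with 60 links; each
community includes each core link with probability 0.7; 20 community-
unique noise variables and 75 noise links per community; planted links
are negative with probability 0.2; communities use a synonym for a core
variable with probability 0.3 (the emitted vocabulary reverses this).
13 × 20 + 25 ≈ 285 unique variables and 60 + 13 × 75 ≈ 1,035 unique
links match the intended order of magnitude.

Polarity is a property of the planted link, shared by every community
that draws it, so generated ensembles are conflict-free by construction.
Every noise link is anchored on at least one community-unique variable
(the other endpoint may be core), so its merged count is exactly 1 and
the edge cut at 2 removes it; anchoring noise to the core keeps the
merged graph connected, as real community diagrams are, rather than
leaving disconnected noise islands.

What the generator does *not* model: community-specific re-signing of
shared links (real conflicts), weighted or uncertain links, workshop
group dynamics, and vocabulary errors subtler than a planted synonym.
Passing recovery tests therefore shows the pipeline's mechanics are
correct under known structure — not that any particular real collation
is right.

Recovery under the advisory cut is high but not guaranteed perfect: a
core variable that drew few links can occasionally fall below the
suggested cut (observed: single-variable misses on some seeds, recall
0.96 in the worked example). Measured over seeds 1–20 of the default
configuration, mean variable recall ≈ 0.99 and mean link recall ≈ 1.0
with precisions 1.0; the regression band asserted in the tests
(means ≥ 0.85, precisions ≥ 0.95) was frozen from that measurement.

## Problem sizes and determinism

All analyses here run on matrices of a few hundred variables, where the
dense solve is instantaneous; the test suite and the acceptance script
use 13-community ensembles (285 variables) and batches of ≤ 100 random
matrices with n ≤ 12, sizes chosen to exercise every code path while
keeping the whole suite in seconds. Random-matrix checks restrict the
normalised spectral radius to ≤ 0.85 so the 200-term reference series is
converged far below the 10⁻⁸ comparison tolerance. Everything stochastic
is driven by an explicit seed through `numpy.random.default_rng`;
identical seeds give byte-identical ensembles and artifacts, and run
manifests record SHA-256 hashes of every written file.

## Known limitations

- The vocabulary step only applies human judgment; garbage mappings
  produce garbage canonicalisation, flagged only when they create
  polarity conflicts.
- There is no principled rule for the number of constituent diagrams
  needed before the summary stabilises ("saturation"); the sensitivity
  analysis quantifies threshold stability, not sampling adequacy.
- Communities are unweighted; a link drawn by two small workshops counts
  as much as one drawn by two large ones.
- Feedback-loop detection in the summary diagram is out of scope; the
  summary is a subgraph, not a loop inventory.
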