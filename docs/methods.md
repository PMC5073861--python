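# Methods

## The drug-effect graph model

A DEG is an undirected bipartite graph G = {U, V, E} with U a set of drugs
and V a set of effects, U ∩ V = ∅, and every edge joining a drug to an
effect. Drugs and effects live in disjoint id namespaces (internally every
node is addressed as a `(partite_class, id)` pair), so the same string can
in principle appear as a drug id and as an effect id without the partite
sets colliding. At most one edge exists per (drug, effect) pair; duplicate
input rows collapse silently with a logged count. Edges carry a label
(`adverse`, `pseudo_non_adverse`, `unlabeled`) and two optional weights:
the mean day gap between the mentions that produced the edge (real ≥ 0)
and the number of per-user graphs contributing it (integer ≥ 1).

The pharmacological neighborhood Γ(x) is the set of nodes reachable within
two hops of x, **excluding x itself**. The definition deliberately mixes
partite classes: for a drug it contains adjacent effects (distance 1) and
the drugs sharing those effects (distance 2). Whether x belongs to its own
neighborhood is a genuine modeling choice; we exclude it, since including
it would add a constant +1 to every non-isolated node's |Γ| and blur the
preferential-attachment contrast between weakly and strongly connected
nodes.

## Topological features and their conventions

For a query pair (d, e): common neighbors N = |Γ(d) ∩ Γ(e)|, Jaccard
S = N / |Γ(d) ∪ Γ(e)|, Adamic–Adar A = Σ_z 1/ln|Γ(z)| over the common
neighborhood, preferential attachment PA = |Γ(d)|·|Γ(e)|, plus the two
one-hop endpoint degrees (distinct from the two-hop |Γ| used by PA; both
are informative and both are exposed).

Numerical choices:

* **Log base.** Natural logarithm in the Adamic–Adar sum. Any common
  neighbor z with |Γ(z)| ≤ 1 is skipped: ln 1 = 0 would make the term
  singular, and a degree-one common neighbor carries no discriminating
  information anyway.
* **Empty neighborhoods.** Jaccard of two empty neighborhoods is 0, not
  NaN, so isolated pairs featurize to the all-zero vector.
* **Query-edge handling.** Features are computed on the graph *as given*:
  an existing edge is not removed before featurization, and training
  negatives are featurized as the absent pairs they are. Hypothetical
  candidates are inserted before featurization, mirroring how the positive
  (present) edges looked during training. A consequence worth stating
  plainly: edge presence is itself recoverable from the two-hop
  neighborhoods under this convention, so a classifier trained this way
  performs above chance even when the planted block structure carries no
  signal. This is a property of the method, not an artifact of the
  implementation; the bulk featurizer also offers `insert_query=True`,
  which featurizes every query pair with that pair present (via an exact
  incremental neighborhood update, oracle-tested against brute-force
  insertion) for analyses that want presence held uniform.

## Pseudo-negative sampling

Databases record only positive (adverse) pairs, so negatives are drawn
uniformly without replacement from the complement of the adverse edge set.
Sampling is rejection-free: ranks are drawn over the complement size and
mapped past the sorted adverse pair indices by fixed-point shifting, which
stays exact even when the requested sample exhausts the complement. The
seed is a required argument; the same seed reproduces the same set. Note
the inherent degree bias of complement sampling (high-degree drugs are
under-represented among absent pairs); it is small at realistic densities
but contributes to above-chance null classification together with the
query-edge convention above.

## Stream-side construction

Timestamps are truncated to calendar dates before differencing. Within one
user's history, every (drug mention, effect mention) pair with absolute
day gap ≤ t (default 20 days) qualifies; the edge weight is the mean gap
over **all** qualifying pairs, not nearest matches only — "average time
between mentions" is read as a plural over pairs. The gap is
direction-agnostic (effect-before-drug also counts) and a same-tweet
co-mention yields gap 0. Mentions deduplicate per canonical id per tweet
only; the same entity in several tweets contributes several mentions.
Per-user graphs contain only nodes participating in at least one edge.
Merging averages temporal weights over the contributing users and sets the
frequency weight to their count.

## Entity extraction

A dictionary matcher replaces heavyweight biomedical annotators while
keeping the same contract: longest case-insensitive match over token
n-grams (n ≤ 5), greedy left to right, with a stop list that suppresses
ambiguous surfaces (the classic example being "pic", a social-media
abbreviation that collides with a medical acronym) and synonym tables that
map trade names onto canonical compound ids. Tokenization lowercases and
splits on non-alphanumeric boundaries; URLs and @-handles are counted and
removed first, hashtags keep their word part, and "n't" negations are
counted on the raw text because splitting destroys them.

## The experiential filter

Tweets are kept only when they relate the author's own experience. The
filter is a 10-tree random forest over seven feature families: hashtag,
negation, URL, pronoun, drug-entity and effect-entity counts plus a
bag-of-words block (vocabulary = training tokens with document frequency
≥ 2, raw term frequencies). Negation and pronoun word lists are
configurable; the defaults are {no, not, never, n't, without, cannot} and
a fifteen-word personal-pronoun list. Training uses a 60/40 split with the
vocabulary fitted on the training portion only, and reports stratified
10-fold cross-validation on the training split plus held-out metrics.

## Semantic context

Sentiment is any function tweet → {2, 1, 0, −1, −2}; the scorer interface
is pluggable, and the shipped default counts positive- and negative-
lexicon tokens and clamps their difference into the codomain. The
sentiment context of an edge is the pair of mean scores over contributing
tweets mentioning the drug and the effect respectively; a tweet mentioning
both contributes to both, and an endpoint with no contributing tweets gets
0 with a warning.

Topic context uses latent Dirichlet allocation fitted by the online
variational Bayes algorithm over exactly the tweets containing at least
one entity mention, with k = 20 topics by default, symmetric
document-topic prior 1/k and topic-word prior 0.01 (standard weakly-
informative choices; the priors are not prescribed by the problem). A
tweet's topic vector lies on the k-simplex; a tweet that is entirely out
of vocabulary gets the uniform vector. An entity's context is the mean
topic vector of the tweets containing it, and an edge's topic block is the
concatenation c(drug) ++ c(effect) (2k values) — concatenation rather than
a difference, so the classifier sees both endpoints' contexts rather than
a single contrast.

## Classification and evaluation

Four nested feature sets are evaluated: Twitter topology + edge weights;
+ sentiment; + topics; + the SIDER-side topological block (the *enriched*
set). When an endpoint of a Twitter edge is absent from the database graph
the SIDER block is all zeros with an explicit indicator flag — absence is
rare when the lexicon is database-derived but must be well-defined for
hypothetical use. The classifier is a 10-tree random forest with the 0.5
vote-fraction threshold; splits are 50/50 by seeded permutation, and
cross-validation is stratified (fold collapse to one class scores 0 on the
undefined metrics, with a warning). Precision is 0 by convention when no
positive predictions are made.

## Hypothetical edges

All pairs of the bipartite product not already adverse are enumerated
lazily. Each candidate is inserted, featurized, scored, and removed; the
graph compares equal to its pre-call state and repeated calls give
identical scores. Candidates are rankable by positive-class vote fraction;
both the score and the thresholded label are exposed, since downstream use
may prefer either.

## What the generators emulate — and what they do not

`generate_planted_sider` partitions drugs and effects into blocks
(contiguous chunks, remainder spread over the leading blocks) and draws
adverse edges with probability `p_in` within blocks and `p_out` across.
The defaults (50 drugs, 100 effects, 5 blocks, p_in = 0.6, p_out = 0.02)
give a graph whose adverse edges are topologically distinguishable from
sampled negatives, emulating the class-separable feature distributions
that real side-effect data exhibits. It does not emulate the heavy-tailed
degree distribution of real databases, frequency/severity annotations, or
polypharmacy correlations.

`generate_tweet_stream` scripts each user as a sequence of two-tweet
episodes: a drug mention, then an effect mention at a controlled day
offset. Planted episodes use adverse pairs at offsets 0–10 days; spurious
episodes use non-adverse pairs at offsets 30–60 days, so they enter the
graph only when the window crosses their offset — this makes the
window-sweep behaviour (adverse fraction dropping as t grows past the
spurious offsets) true by construction. Episodes of one user are spaced
100 days apart so they cannot cross-pair within any swept window. Spam
tweets carry ≥ 3 hashtags, a URL and no entities; experiential tweets
carry pronouns, an entity surface, topic-pool filler words and sentiment
words at the configured rates. The ledger of intended edges is the oracle
for reconstruction tests. The generator does not emulate misspellings,
sarcasm, third-person reports, retweets, or entity surfaces absent from
the lexicon — so passing reconstruction tests demonstrates correctness of
the windowing/merging machinery, not robustness to real Twitter noise.

The 18-tweet case-study fixture is fixed permanently: the per-user entity
assignments beyond the first user are not printed in full anywhere, so
they were chosen once, constrained to reproduce every published count
(9 users with the 3/1/2×7 tweet distribution, 3 drugs, 9 effects, 9
user graphs, all merged frequencies 1, and the first user's three edges of
weight 2).

## Problem sizes and determinism

The test suite runs the planted classification at the generator defaults
(50×100 nodes) over 10 seeds, oracle equivalence on 1,000 random graphs of
at most 30 nodes, and the balanced-set arithmetic on a 1,430 × 5,868 graph
with 139,756 edges; these sizes keep the full suite under a minute while
exercising every scale-dependent code path. All generators, samplers,
splits and forests are pure functions of their seeds; every stochastic
test pins its seed.

## Known limitations

* The dictionary extractor cannot resolve mentions absent from its
  lexicon, and longest-match is greedy — overlapping surfaces resolve
  left to right.
* The default sentiment scorer is intentionally simple; it exists to make
  the Eq-style averaging concrete and testable, and real deployments
  should plug in a stronger scorer honoring the same codomain.
* Classification metrics on synthetic graphs say nothing quantitative
  about real side-effect databases; only the relative behaviour (signal
  vs no-signal, feature-set nesting) transfers.
* Negative labels are *pseudo*-negative: an absent pair may simply be an
  unreported adverse effect — which is precisely what the hypothesis
  module is for.
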