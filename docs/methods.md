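# Methods

## Scope and model

`litmine` treats a literature review as an unsupervised text-mining
problem: each document is a bag of stemmed words from its title and
abstract, weighted by TF-IDF, and thematic structure is recovered with
k-means.  No topic priors, labels, or citation-graph information enter the
clustering; metadata (year, citations, Open Access flag) is used only for
trend tables and group comparisons.  The approach assumes that articles on
the same theme share enough vocabulary after stemming that cosine-like
geometry separates themes — true for abstracts written in English in a
common field, not for multilingual corpora or very short titles-only
records.

## Preprocessing

Cleaning applies, in order: lowercasing; removal of whole whitespace
tokens that are not English words — after stripping leading/trailing
punctuation, any token still containing a digit, `@ / . - _` or a
non-ASCII character is dropped (catches URLs, e-mails, numbers, and
hyphenated compounds, which are dropped rather than split); splitting the
survivors on non-letter runs; removal of generic then custom stopwords;
and a 2–21-letter length filter.  Dropping sentence-final words along with
their trailing period would distort every frequency table, which is why
punctuation is stripped from token edges *before* the non-alphabet test.
Cleaning is idempotent on its own output (property-tested).

The generic stopword list is scikit-learn's English list, frozen into the
package as a data file (318 words, one per line) so results cannot drift
with library versions.  The custom list defaults to the abstract
boilerplate words `abstract, background, results, conclusions` and is
user-extensible via configuration.  Both lists are applied to the
*unstemmed* word, as is the length filter.

Stemming is the classic Porter algorithm, implemented in-package (the
stack here ships no stemmer) directly from the original rule tables and
verified against the algorithm's canonical examples.  Editorial listings
of word families sometimes print roots no standard stemmer produces (e.g.
an "anali" family for *analysis/analytical/analyzed*); we treat those as
simplifications and do not special-case them.

## TF-IDF

Weights are `tf · idf` with raw-count tf and smoothed
`idf = ln((1+N)/(1+df)) + 1`, rows L2-normalized (zero rows stay zero), so
all weights are in [0, 1] and a term present in every document keeps a
positive weight.  This is scikit-learn's `TfidfTransformer` default, which
performs the computation; tests compare it entry-by-entry (1e-12) against
an independent brute-force implementation of the formula.  The vocabulary
is lexicographic with `min_df = 1` (no pruning by default).

## Clustering and k selection

Distances are Euclidean on the unit-normalized rows — monotonically
equivalent to cosine dissimilarity on the sphere — used consistently for
k-means and silhouettes.  `kmeans_fit` runs Lloyd iterations from
k-means++ starts, best of `n_init = 10` restarts, `random_state = seed`
(default 0, recorded in every result).  On random small instances
(n ≤ 8, k ∈ {2,3}) best-of-10 reaches the exhaustive-partition WCSS
optimum in ≥ 95% of cases (tested at 100 instances).

Silhouettes are s(i) = (b−a)/max(a,b); singleton clusters get s(i) = 0
(including the degenerate all-singletons case, which the underlying
library rejects and we define as all zeros).

k selection quantifies the visual silhouette-plot check: a k is *feasible*
when every cluster's silhouette peak reaches that k's mean silhouette
("crosses the dashed average line"), and among feasible ks the smallest
coefficient of variation of cluster sizes wins ("parity of thickness" —
bar thickness in a silhouette plot encodes cluster size), ties to the
smaller k.  If nothing is feasible the k with the best mean silhouette is
returned and flagged.  The rule is deliberately advisory — thematic
granularity is a judgment call — so every pipeline entry point accepts an
explicit k override.

Subclustering extracts one cluster's documents and re-runs preprocessing,
vocabulary fitting, TF-IDF and the k sweep from scratch on the subset, so
sub-theme vocabulary regains contrast that corpus-level document
frequencies had flattened.  `k_max` is clipped to the subset size;
singleton clusters cannot be subclustered.

## Descriptive analyses

Relative word frequency is token-based (count / total tokens in scope); a
document-frequency mode is provided because published frequency bar plots
rarely state which convention they use.  Ties rank alphabetically.  The
2-D projection is exact full-SVD PCA of the centered dense matrix —
deterministic, sign of each axis arbitrary — with cluster centroids mapped
through the same centering and axes.  Trend tables count documents per
(year, cluster) in a configurable window (default 2001–2021); unknown
years are excluded and reported.  Group comparisons report the overlap of
top-n word lists (default n = 20) with the ranks of the differences, plus
min/max/mean/median citations for citation splits.  The most-cited split
keeps exactly ⌈fraction·n⌉ documents after sorting by (citations
descending, id ascending) — a fixed, documented tie-break, since tie bands
at the quantile boundary are common in citation data.

## Evidence tables

One record per published activity report: plant species, part, solvent,
bacterium as printed, value, reference.  The value cell is parsed as
mg/mL MIC; a trailing `#` marks MIC50; percent or percent-range entries
(e.g. `0.25-0.5%`) are stored with `unit=percent` (value = range midpoint)
and never enter mg/mL means.  Bacterium names are normalized by stripping
strain designators (ATCC/DSM/MSP/W numbers) and expanding genus
abbreviations via a packaged epithet→genus table scoped to the organisms
of the packaged dataset (the epithet key is ambiguous in general —
*pneumoniae* could be *Klebsiella* or *Streptococcus* — so the mapping is
data-scoped, and unmappable names are kept as printed with a warning).

Category shares are computed over raw table rows ("reports") by default,
with a strain-collapsed alternative (one count per distinct
species/part/solvent/bacterium combination).  For share tables, resistance
qualifiers ("Methicillin-resistant …") remain distinct categories — they
are clinically distinct report types — while value pooling strips them.
Exact shares sum to 100 by construction; the integer display rounding can
make a column of rounded shares sum a point or two away from 100, which is
why both exact and rounded values are kept.

Per-bacterium means default to `MIC_only` scope (MIC50-flagged rows
excluded); `MIC_and_MIC50` pooling is available.  On the packaged table
the MIC-only scope is the convention under which the published per-species
means are reproduced where they are reproducible at all, which is why it
is the default.  Means are order-invariant and invariant to strain-level
splitting of pre-normalized duplicates (tested).

The packaged table transcribes 172 microdilution reports on *Cistus*
extracts.  It round-trips byte-identically through load/write.  Of the
published summary statistics for this table, the species shares (27/27/23),
part shares (38/37), ethanol share (22), bacterium-use shares (27/17/11)
and the *P. aeruginosa* mean MIC (7.765 mg/mL) are reproduced exactly at
printed precision; the water (17) and methanol (16) shares and the
*S. aureus* (2.658) and *E. coli* (6.537) means are not reproducible from
the printed table under any documented convention (we compute 16, 15,
2.650 and 6.353) — the discrepancies are sub-percent to a few percent and
consistent with the printed table differing slightly from the spreadsheet
the statistics were computed from.  The corresponding acceptance tests
assert the printed values and are left failing rather than loosened.

## Synthetic data

The corpus generator plants `k_topics = 5` equally weighted topics over
`n_docs = 500` documents.  Each document draws `tokens_per_doc = 60`
tokens i.i.d. — the content words surviving stopword removal in a typical
abstract — from its topic's private 40-word vocabulary with probability
`p_topic = 0.7`, otherwise from a 100-word background vocabulary shared by
all topics.  Every vocabulary pool is sampled with Zipf (1/rank) weights:
flat profiles make top-word lists pure multinomial noise, whereas Zipf
weighting reproduces the real-corpus situation in which a handful of
generic terms dominates the frequency tables and split-half top-20 lists
overlap heavily (~17/20 under metadata splits independent of topic).
Years are 2001–2021 with optional per-topic linear trends; citations are
rounded log-normal (μ = 2.5, σ = 1.2, i.e. median ≈ 12 with a heavy right
tail); Open Access is Bernoulli(0.3).  Synthetic words are consonant-only
strings over an alphabet chosen so that no Porter rule rewrites them and
no stopword list contains them — the generator's labels survive the full
preprocessing stack unchanged.  One seeded NumPy generator drives
everything; identical configs are byte-identical.

The nested variant makes one topic a mixture of `n_subtopics = 3`
sub-topics *inside the parent's vocabulary*: the Zipf head of the topic
vocabulary (25% of its words) is a shared core used with probability 0.7
per topic draw, and the flat tail is partitioned into per-sub-topic
blocks.  Keeping the sub-structure inside the parent's dimensions is what
makes the topic cluster as one coherent group at corpus level (sub-topic
words with their own out-of-topic vocabulary would get extreme idf weights
and split the parent coarsely) while re-fitting TF-IDF on the cluster
alone exposes the blocks.  Sub-topics are equal-prevalence and assigned in
balanced rotation, matching their definition and the size-parity selection
rule.  Coarse selection of k = 5 and exact sub-topic recovery (ARI 1.0)
hold across seeds 0–12.

The activity-table generator draws categories uniformly from fixed pools
and values from a log-normal, emitting values as exact decimal strings; it
returns the exact shares and MIC-only means implied by its own draws, and
the evidence module reproduces them with zero tolerance.

What passing these tests shows — and does not.  The synthetic corpus has
single-membership topics, disjoint topic vocabularies, i.i.d. tokens and
metadata independent of content.  Real abstracts mix topics within one
document, share vocabulary across themes, and correlate metadata with
content; recovery there is necessarily softer, which is exactly why the k
choice is advisory and the pipeline records silhouette evidence rather
than claiming an optimal k.

## Numerical and reproducibility choices

Problem sizes throughout (500-document corpora, k swept to 16, 100
oracle instances) are desk-scale: the full test suite runs in ~15 s and
the acceptance script in ~10 s on one CPU.  All randomness flows from
explicit integer seeds; k-means records its seed and `n_init` in every
result.  Pipeline bundles are plain CSV/JSON with floats printed at 12
significant digits, and a manifest (config + seed + version) from which a
rerun reproduces every file byte-identically.  PCA uses the exact
full-SVD solver; axis signs are arbitrary and tests compare up to sign.
Degenerate inputs are defined rather than left to chance: empty documents
become zero TF-IDF rows, all-singleton clusterings have silhouette 0,
empty vocabularies and single-cluster silhouettes raise errors.

## Known limitations

No lemmatization, n-grams, language detection or spell correction; no
alternative clusterers or selection criteria (gap statistic, BIC); no
statistical testing of word-frequency differences between groups; no
deduplication across article and patent databases; no dose–response
modelling or meta-analytic weighting in the evidence module.  Word-cloud
and figure rendering are out of scope — the analyses emit the underlying
tables.
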