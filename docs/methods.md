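# Methods

This note documents the models, numerical choices and limitations behind
hgtrace, in the order the pipeline runs.

## Scope and stand-ins

The pipeline reproduces the *inference machinery* of a comparative-genomics
HGT survey, not the external tool runs it would orchestrate at full scale.
Alignment construction (MAFFT/MUSCLE), profile HMM search (hmmer), tree
inference (FastTree/IQ-TREE/RAxML-NG) and PDA are represented by in-package
equivalents with the same contracts: an ungapped PSSM stands in for a
profile HMM, best-window extraction stands in for `hmmalign --trim`,
birth–death simulation with assigned supports stands in for bootstrap tree
inference, and greedy PD maximisation reimplements PDA's objective exactly.
Each stand-in is described below as what it is; none attempts to reproduce
the numerical output of the corresponding external tool.

## Sequence and tree I/O

Protein sequences use the 20-letter alphabet plus `X`; the ambiguity codes
B, Z, U and O are mapped to `X` with a warning, because profile scoring
needs a closed alphabet. Coordinates are 0-based half-open internally and
converted losslessly to 1-based closed form only for display. Newick
internal-node labels are read as integer supports in [0, 100] when numeric
(the ultrafast-bootstrap convention: the label names the support of the
edge above the node); non-numeric labels are preserved as names. Missing
branch lengths default to 0.

## Alignment trimming and the profile model

`trim_gappy_columns(aln, f)` keeps exactly the columns whose non-gap
fraction is ≥ f; the pipeline default f = 0.2 matches the gap-threshold
trimming convention (a column survives when at least 20 % of rows hold a
residue). Column emissions follow the Laplace rule
p(a|j) = (c_ja + α)/(n_j + 20α) with default α = 1 against a uniform
background; log odds are log2(p/q). `X` residues are excluded from the
counts and score 0 (uninformative) at search time. The score of a sequence
is the maximum over ungapped windows of the per-column log-odds sum —
deliberately gap-free: the scorer only needs to be order-preserving for the
pipeline's thresholding and capping contracts, not a substitute for
forward/Viterbi statistics.

## E-values

E-values are empirical: decoys (residue-shuffled copies of the database,
composition-preserving) are scored under the profile, and within the decoy
range e(s) = D · (#decoys ≥ s + 1)/(n + 1) for a database of size D. The
add-one rule floors the empirical E-value at D/(n + 1), which cannot cross
a 1e-3 cutoff with desk-scale decoy sets, so above the maximum decoy score
the tail is extended exponentially, e(s) = floor · exp(−λ(s − s_max)), with
λ the reciprocal mean excess of the decoys' top decile (a
peaks-over-threshold fit, falling back to λ = 1 when the tail is
degenerate). The mapping is monotone non-increasing, strictly positive, at
most D/(n + 1) above all decoys and approximately D below them all. At
least 100 decoys are required.

## Search, caps and iteration

Hits pass at E < 1e-3, then each species' contribution is capped at its 10
best hits by E-value (ties broken by lexicographic sequence id), limiting
the pull of transcriptome assemblies with many isoforms. The cap applies
per round; the cumulative hit set is the union across rounds, so earlier
discoveries are never displaced. `iterate_search` rebuilds the profile each
round from the current alignment (seed rows plus each hit's best window),
and stops when a round contributes no sequence outside the cumulative set
("saturated"), when a hit belongs to the declared outgroup
("contamination" — the search has drifted into a neighbouring family, e.g.
poly(A) polymerases when searching for CD-NTases), or at the round budget.
The strict "no new sequences" rule is used rather than a slack tolerance.
Balanced seeds concatenate the two domains of life after downsampling each
side to 50 phylogenetically diverse sequences (below).

The Phase-4 in-group filter removes hits that lack every diagnostic family
domain, and hits that cluster outside the in-group: the tree is rooted at
the outgroup's median leaf (by sorted id — a deterministic stand-in for
manual inspection), and anything outside the smallest clade containing all
reference in-group leaves is discarded. Each removal is logged with the
rule that fired.

## PD subsampling

PD(S) is the total branch length of the minimal subtree spanning S,
computed on the unrooted topology (an edge belongs to the subtree exactly
when S occurs on both of its sides; zero-length edges are allowed). Greedy
selection — seed with a maximally distant leaf pair found by the standard
double sweep from the lexicographically smallest leaf, then repeatedly add
the leaf with the greatest distance to the current spanning subtree — is
exactly optimal for PD maximisation on trees, so the greedy subset's PD
equals the exhaustive optimum (verified against `brute_force_max_pd`, which
is guarded to ≤ 12 leaves). All ties break lexicographically by leaf id, so
results are reproducible and invariant to input leaf order; when several
distinct subsets achieve the same optimal PD, the reported *set* may differ
from another implementation's, but the PD value cannot.

## Tree comparison and clade extraction

Bipartitions are stored in canonical orientation (the side containing the
lexicographically smallest leaf); a bifurcating root contributes a single
split whose weight is the sum of the two root-adjacent edge lengths.
`collapse_low_support` contracts internal edges with support strictly below
the threshold (70 by default; an edge at exactly 70 survives) and keeps
edges that carry no support value. The weighted Robinson–Foulds distance is
the sum of |w1(b) − w2(b)| over the union of the two trees' non-trivial
bipartitions, a split missing from one tree counting zero there — the
"zero weights allowed" semantics; trees are pruned to their common leaf set
first (≥ 4 shared leaves required), and a shared-splits-only variant is
exposed as an option. Pendant edges are excluded, so two trees differing
only in pendant lengths are at distance 0.

Eukaryotic clades are the maximal bipartition sides whose leaves are all
eukaryotic; pendant sides are included so a single transferred sequence is
still reported. Archaea count as prokaryotic context. Sister composition is
computed locally on the unrooted topology: from the node across the clade's
stem edge, the neighbouring subtree richest in prokaryotes (ties: larger,
then lexicographic) is taken as root-ward, and the union of the remaining
subtrees is the sister — so the result does not depend on the input
rooting, which is arbitrary in practice. A singleton clade's pendant stem
carries no support of its own, so its stem support is read from the
adjacent supported edge (the eukaryote-plus-sister split).

## The four-criterion HGT call

Criterion 1 ("branched adjacent to bacteria with strong support") is
operationalised as stem support strictly greater than 70 *and* a sister at
least half prokaryotic — strict on the printed support bound, lenient on
adjacency. Criterion 2 requires ≥ 2 distinct species from one supergroup
inside the clade; criterion 3 requires ≥ 2 distinct source studies;
criterion 4 requires a clade with a matching species set (exact-set match
by default; a Jaccard option exists for noisy trees), itself passing 1–3,
in every other replicate tree. Whether criterion 1's support should sit on
the eukaryotic stem or on the joint eukaryote+bacteria edge is genuinely
underdetermined; the stem edge is used. Candidates failing any criterion
are reported with their per-criterion flags and a robustness count, never
dropped, and the caller records each clade's data types
(genome/transcriptome) without filtering on them — transcriptome-only
species cannot rule out long-term bacterial symbionts, and no principled
automatic rule exists for that. Transfer direction is never inferred; a
passing candidate means "eukaryotic clade nested in bacterial context".

The supergroup-breadth report counts distinct supergroups among a clade's
species over a configured total (default 12) and labels the clade "broad
(LECA-compatible)" when it spans at least half of them — an explicitly
labelled heuristic, not an ancestral-state reconstruction.

## Superfamily classification

Among a sequence's domain hits to the diagnostic accessions, the lowest
E-value (ties to the higher bit score, then accession) decides: PF18144
(SMODS) → eSMODS, PF10421 (OAS1-C) → OAS, PF03281 (Mab21) → cGLR, PF20300
(Prok_STING) on a eukaryotic sequence → blSTING; anything else is
unclassified. A clade label that contradicts the domain call downgrades the
call to unclassified with a conflict note. Classification is a pure
function of the domain table (row order is irrelevant).

## Catalog analytics

The presence/absence catalog is strictly binary (1 = at least one homolog
found), matching the encoding of published supplementary catalogs; hit
counts stay in the search logs. All-zero species rows are retained —
absence counts are the point. Venn (co-occurrence) regions are counted by
exact partition over the chosen families within a stratum, and strata
(e.g. Metazoa vs the rest) are driven by the supergroup field, not a
hard-coded species list. Collectors curves accumulate distinct newly
recovered sequences per round; the final value equals the iterative
search's total distinct discovery count. The spreadsheet importer reads one
tab of an xlsx workbook with an explicit column mapping (published catalogs
do not share a fixed column-naming convention) and rejects any non-binary
cell with its location.

## The synthetic-data generator

`simulate_backbone_tree` draws two constant-rate birth–death trees
(defaults: birth 1.0, death 0.2) and joins them at the root — bacterial
leaves on one side, a monophyletic eukaryotic clade on the other — which
guarantees domain-of-life monophyly without rejection sampling. Eukaryotes
receive one of 12 supergroup names round-robin, a study from a configurable
pool (default three studies) and alternating genome/transcriptome data
types; internal edges carry integer supports from the high range
(default 85–100) unless explicitly assigned from the low range (40–65).
`plant_hgt_clade` grafts a caterpillar clade of new eukaryotic species onto
a bacterial edge, with branch lengths scaled to the local bacterial
subtree's mean edge length so the graft is not trivially long, and records
ground truth including which criteria the construction can satisfy (one
species necessarily means one study; any failed construction flag also
voids robustness, because criterion 4 quantifies over clades passing 1–3).
Benchmark scenarios (`build_hgt_scenario`, defaults 24 bacteria + 10
backbone eukaryotes + a 3-species/2-study planting, 4 replicate trees) use
graft targets subtending at most half the bacteria — a graft onto the edge
above nearly the whole backbone would make the "sister" the rest of the
tree, which is not the nested-in-bacteria situation being modelled.
Replicates are branch-length-jittered copies; the robustness ablation
instead scatters the planted leaves one-per-host across bacterial pendant
edges so no two remain sisters. With 10 backbone eukaryotes spread one per
supergroup, the backbone clade itself cannot satisfy criterion 2, giving
the benchmark a clean planted-versus-background contrast.

`synthetic_family` builds search problems: a tight seed family (8 variants
of a random 25-residue ancestor, 4 substitutions each), database members
sampled column-wise from a *sharp* profile of that alignment (pseudocount
0.05) embedded in background flanks, and background-only decoys. Members
are generated from the sharp profile because real homologs track the family
consensus far more closely than a heavily smoothed emission model; the
search itself still uses the default α = 1 profile. Under these defaults
the search recovers 100 % of members and passes 0 % of decoys at the 1e-3
cutoff; the tested guarantee is ≥ 90 % / ≤ 5 %.

What the generator does **not** emulate: substitution-model sequence
evolution along the tree (members are exchangeable draws, with no
tree-structured covariance), indels, alignment error, rate heterogeneity,
genuinely ambiguous supports near the 70 boundary, contamination that
mimics transfer, or database incompleteness. Passing tests therefore show
that the machinery is correct under its stated rules — recovery of planted
events whose construction satisfies the criteria, with sound failure
attribution — not that the criteria themselves have any particular
sensitivity or specificity on real data.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale, chosen so the full suite
completes in seconds: 200-tree sweeps (≤ 8 leaves) for exhaustive PD
comparison, 100 seeded pairs for metric axioms, 50 simulations each for
recovery and ablations (24 + 10 + 3 leaves, 4 trees), families of 50
members and 50 decoys, and one large PD downsample at the real study's
scale (6,132 leaves → 500). Every stochastic component takes an explicit
integer seed and is a pure function of its inputs; identical seeds give
byte-identical trees, sequences and tables.
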