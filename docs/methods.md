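# Methods

`ppikex` classifies candidate protein–protein mention pairs in single
sentences as interacting or not. A candidate is an unordered pair of
protein mentions co-occurring in one dependency-parsed sentence; the
classifier is a soft-margin SVM over a precomputed kernel that fuses three
complementary similarity measures. This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## The three kernels

**Lexical feature kernel.** Each candidate pair is entity-blinded
(ENTITY1/ENTITY2 for the pair, PROT0 for other protein mentions) and
described by sparse binary features: words inside the entity names
(`a_i__w`), words strictly between them (`b_i__w`, positional; `b_0__NULL`
when the gap is empty), up to `window` context words outside the pair
(`l_i__w`, `r_i__w`), keyword-lexicon hits among the between/context words
(`k_w`), and exactly one bucketed distance feature (`d_3` for gaps ≤ 3
words, `d_8` ≤ 8, `d_15` ≤ 15, `d_16` beyond). Similarity is the isotropic
Gaussian K(x,y) = exp(−‖x−y‖² / 2s²) over the union of feature names.

Open choices made here: context is taken at the *outer boundary* of the
pair (one left window before the earlier mention, one right window after
the later), not four per-mention windows — the worked IL-8 example only
admits the outer-boundary reading. The window defaults to 3 words per
side. Keyword matching is case-insensitive; the packaged lexicon is a
~40-word list of interaction cues (binds, activates, receptors, …) and is
user-replaceable — serious corpus work should substitute a curated list.
Tokenization splits leading/trailing punctuation but deliberately keeps
parentheses and hyphens attached, because they occur inside biomedical
entity names such as "(IL)-8".

**Dependency-path tree kernel.** The shortest undirected path through the
dependency graph between the two entity head tokens is rendered as a
bracketed tree: a `DEPENDENCY` root whose children are the path's relation
labels, each carrying its (governor, dependent) word pair as leaves, e.g.
`(DEPENDENCY(CONJ(ENTITY1,ENTITY2)))`. Paths with fewer than
`min_path_len` (default 3) relation nodes are too thin to judge, so they
are extended by up to `max_extension_edges` (default 2) extra dependency
edges: the governor chain above the ENTITY1-side endpoint first, prepended
outermost-first, then the ENTITY2 side. Trees are compared with the
subset-tree convolution kernel K_c(T₁,T₂) = Σ_{n₁∈N₁} Σ_{n₂∈N₂} Δ(n₁,n₂),
where Δ is 0 when the two nodes' productions differ (leaves carry no
production), λ when the node is pre-leaf, and λ·Π_k (1 + Δ(child_k))
otherwise. λ ∈ (0,1) (default 0.5, the midpoint of its admissible range)
damps large fragments; Δ is memoized over node pairs grouped by
production, so only potentially matching pairs are visited. Values are
cosine-normalized, K′ = K/√(K₁₁K₂₂), giving a unit-diagonal Gram.

**Tag-graph kernel.** The blinded sentence becomes a directed graph — one
node per token, one edge per dependency arc — with one tag per node per
tier: lowercased surface (tier 0), POS (tier 1, `UNK` when absent), and
entity role ENTITY1/ENTITY2/PROT0/OTHER (tier 2). With adjacency E and
0/1 label matrices L_r, the walk-weight matrix M = Σᵢ ξⁱEⁱ fuses directed
walks of every length at weight ξ per edge ([Eⁿ]ᵢⱼ counts length-n walks).
Two graphs are compared tag-to-tag:

    K(G,H) = Σ_r β_r ⟨ L_r M L_rᵀ , L′_r M′ L′_rᵀ ⟩

with the elementwise matrix inner product taken over the union of tag
vocabularies. Defaults: ξ = 0.3 (keeps ξ·ρ(E) < 1 for typical parse
graphs), β = (1,1,1) (no a-priori tier preference; the fusion stage, not
β, is the tuned surface), series truncated at order 10 (always convergent;
an exact resolvent form (I−ξE)⁻¹ is available when ρ(ξE) < 1, and the two
agree on acyclic graphs once the truncation covers the longest path).
Grams are cosine-normalized like the tree kernel.

## Fusion and training

The fused kernel is the convex combination K = Σᵢ ηᵢKᵢ with ηᵢ ≥ 0,
Σηᵢ = 1; uniform weights recover the plain multi-kernel sum up to scale.
Weights are tuned by exhaustive search over a simplex grid (default step
0.1) scoring each weighting by pooled F over stratified inner CV folds
(default 3) — deterministic and transparent where gradient-based
multiple-kernel learning would be opaque. Ties prefer the larger tag-graph
weight, then the larger weight vector in sorted kernel-name order.

Training solves the soft-margin dual on the fused precomputed Gram
(L_d = Σα_t − ½ΣΣ α_tα_s r_tr_s K(x_t,x_s), 0 ≤ α_t ≤ C, Σα_tr_t = 0) via
scikit-learn's SMO; the tests assert the optimality conditions against an
independent SLSQP solve, so the contract is the dual solution, not the
solver. C defaults to 1.0 with `class_weight="balanced"` (the interaction
corpora this mirrors are roughly 1:5 positive:negative). A bias term is
included, as is standard for soft-margin duals. If the fused training Gram
has an eigenvalue below −1e−8 it is floor-shifted by adding
|λ_min|·I (recorded on the model as `psd_shift`); all three kernels are
positive semidefinite by construction, so the repair is a numerical
safeguard rather than a routine step.

Prediction evaluates g(x) = Σ_t α_t r_t Σᵢ ηᵢ Kᵢ(x_t, x) + b over the
support pairs; the sign is the label and raw values are returned for
thresholding.

## Evaluation protocol

Precision, recall and F (harmonic mean) are reported as percentages to two
decimals; any 0/0 ratio is defined as 0 and flagged `degenerate`.
Cross-validation partitions *documents*, never sentences (shuffled by the
run seed, dealt round-robin into k folds; default k = 10, k = 5 in the
synthetic study), so same-abstract candidates never straddle a split.
Per fold, training — including weight tuning — touches only train-slice
rows and columns of the precomputed Grams. Pooled (micro-averaged)
confusion counts are the headline numbers; per-fold results are also
reported. The comparison harness runs every kernel combination
(3 singles, 3 two-kernel fusions, the three-kernel fusion) on shared Gram
matrices and emits a method × P/R/F table.

## The synthetic generator

Real interaction corpora require external downloads, a dependency parser,
and a curated keyword lexicon, so the test bed is synthetic. Each sentence
draws 2–3 protein mentions (`PROTn` namespace) connected by filler text
over a fixed-plus-gibberish vocabulary, with a projective dependency tree
(a head-final chain, plus overrides below). Adjacent mention pairs are
positive with the probability that yields the target positive fraction
(default 0.3); a positive pair receives a lexical cue — a trigger word
from the keyword lexicon in its ≤ 3-word gap — and/or a structural cue — a
dedicated `INTERACT` dependency linking the two mention heads directly
(selectable: `lexical`, `structural`, `both`). Negative adjacent gaps are
4–8 words, so a negative pair that *spans* a positive one (and therefore
contains its trigger) still differs in distance bucket and path shape;
this is what keeps the planted signal separable for each kernel family.
Label-flip and spurious-trigger noise rates make the task arbitrarily
hard. Generation is fully deterministic per seed, down to byte-identical
XML and sidecar files.

What the generator does **not** emulate: real biomedical syntax and
vocabulary, multi-token entity names, overlapping or nested mentions,
parser errors, unparsed sentences, cross-sentence relations, or the long
ambiguous coordination structures that make the public corpora hard.
Passing the synthetic study shows the pipeline is correct and that fusion
preserves a detectable mixed signal; it does not predict absolute
performance on real corpora.

**Study conditions** (fixed): 40 documents × 5 sentences (~516 candidate
pairs at mention rate 2.75), positive fraction 0.3, mixed signal, no
noise, 5-fold document CV, median-heuristic RBF bandwidth, tuned fusion
weights at grid step 0.1. The median bandwidth (s² = median ‖x−y‖²/2) is
the study condition because binary feature vectors at the package default
s = 1 give an effectively diagonal Gram — correct but unlearnable; the
default is kept at 1.0 for users who want the textbook formula verbatim.

## Numerical choices and degenerate inputs

- Normalization returns 0 when either self-kernel is 0; an unparsed
  sentence therefore contributes an all-zero row *and* a zero diagonal in
  the structural Grams — it simply carries no structural evidence.
- Mention heads: the span token whose governor lies outside the span;
  multi-headed or unparsed spans fall back to the last token.
- Shortest paths between entities use the undirected view of the
  dependency graph; ties are broken deterministically by sorted edge
  order. Disconnected pairs yield the flagged root-only tree.
- Bracketed-tree serialization escapes `( ) , \` in labels, so word
  leaves such as "(IL)-8" round-trip.
- The simplex grid requires the step to divide 1 exactly; weights are
  exact multiples of the step, avoiding drift in the Σηᵢ = 1 constraint.
- All randomness (corpus generation, fold assignment, inner CV shuffles)
  flows from explicit integer seeds; repeated runs are byte-identical.

## Known limitations

- The tag-graph kernel down-weights long walks geometrically (ξⁱ), so
  similarity beyond a few edges is effectively invisible — inherent to the
  walk-series design. In the synthetic study it is the weakest single
  kernel (pooled F ≈ 62%); fusion lets the stronger kernels carry it.
- Weight tuning is O(grid × inner folds) SVM fits; at step 0.1 with three
  kernels that is 66 weightings per fold. Coarser grids trade fidelity for
  time.
- Gram assembly is O(n²) kernel evaluations per kernel; corpora beyond a
  few thousand candidates need blocking or subsampling, which the package
  does not provide.
- Self-interactions (two mentions of the same protein string) are kept as
  ordinary candidates; no coreference handling.
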