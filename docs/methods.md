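# Methods

This note records the models, defaults and design choices behind
`resilmine`, and what the synthetic test bed does and does not establish.

## Text model and preprocessing

Documents are plain text records (`doc_id`, `title`, `body`).
Preprocessing lowercases, splits sentences on terminal punctuation with a
small abbreviation guard, tokenizes by a word regex, and removes a packaged
English stop-word list plus punctuation.  Sentence boundaries are found
*before* stop-word removal because the sentence-reordering augmentation
permutes real sentences.  A document reduced to zero tokens is flagged
empty rather than rejected: downstream stages skip it.  No minimum document
length is enforced.

## Contrastive representation learning

The encoder contract is: token list → fixed-dimension vector,
deterministic given fixed parameters.  Two implementations ship:

* **HashingEncoder** (default): each token gets a fixed Gaussian direction
  derived from a stable hash of (seed, token); a text embeds as the token
  mean.  It needs no fitting, is identical across processes, and is the
  pipeline default because every downstream contract (cosine geometry,
  determinism) holds without training time.
* **TrainableEncoder**: a linear bag-of-tokens map (one weight row per
  vocabulary entry, one shared out-of-vocabulary/mask row) trained by
  InfoNCE with in-batch negatives.  Gradients are derived analytically
  (softmax cross-entropy through cosine similarity through the token-mean
  embedding) and verified against numerical differentiation in tests.

Training defaults mirror a transformer fine-tuning recipe: temperature
τ = 0.07, batch 16 with 2-step gradient accumulation (effective 32), AdamW
(decoupled weight decay 0.01), peak learning rate 2 × 10⁻⁵ with linear
warmup over the first 10% of steps and linear decay to zero, gradient-norm
clipping at 1.0, 3 epochs, a 15% validation split (round-half-up, seeded
shuffle), validation every 50 steps, and early stopping after 5
non-improving MRR checks.  The peak learning rate is the one default a
user of the linear encoder should raise (the examples use 0.05): 2e-5
presumes a pretrained model's loss surface.  The masked-language-model
term that would accompany this objective in a transformer fine-tune is out
of scope here; only the contrastive term is optimized.

Validation ranks each anchor against the augmented copies of all
validation documents.  Ties break *pessimistically* (a tied competitor
counts as ranked above the positive), making reported MRR and contrastive
accuracy conservative; an encoder that collapses all documents to one
vector scores MRR = 1/n, accuracy 0.  Coherence is the mean cosine of
caller-supplied same-topic pairs and is NaN when none are supplied — on
real corpora there is no canonical pair source, so the synthetic topics
provide them.

Augmentation: masking replaces round(mask_rate · n) token positions
(sampled without replacement) with a reserved mask token; sentence
reordering permutes sentence spans; synonym replacement consults a
packaged lexicon with probability 0.1 per eligible token.  Token count is
invariant under all three.

## Phrase scoring and screening

Candidates are all contiguous 1..max_n-grams (default max_n = 4) with
exact total and document frequencies.  Scores:

* **TF-IDF**: raw = total_freq · ln(N/doc_freq), rescaled by the pool
  maximum into [0, 1].  A phrase present in every document scores 0.
* **Relevance**: (cos(phrase embedding, domain centroid) + 1)/2, where the
  centroid is the mean document embedding.  "Semantic coherence" and
  "semantic relevance" share this one implementation; both use the 0.65
  default threshold.
* **Specificity** (no standard formula exists; this is our definition):
  mean token IDF over the phrase's tokens, divided by the corpus's
  95th-percentile token IDF, clipped to [0, 1].  Unseen tokens take the
  maximal IDF ln(N).  This matches the intent of excluding generic terms:
  ubiquitous words have zero IDF and drag the score down.

The funnel: Phase 1 keeps total_freq ≥ 5; Phase 2 keeps total_freq ≥ 7
AND doc_freq ≥ 10; Phase 3 keeps relevance ≥ 0.65 with optional TF-IDF
(≥ 0.45) and specificity (≥ 0.50) gates — the quality thresholds are
folded into Phases 3–4 and individually toggleable, since their ordering
relative to the funnel is genuinely open; Phase 4 drops phrases longer
than 6 words, generic single words, and blocklisted (ambiguous) phrases,
applies the reviewer-consensus gate (≥ 2/3) only when a ratings table is
supplied, and merges near-duplicates (embedding cosine ≥ 0.9) keeping the
higher-relevance member.  All phases operate on canonically sorted
candidates and the merge uses a deterministic relevance-then-text order,
so screening is independent of pool order.  An upper-quartile (type-7
linear interpolation) frequency rule is available alongside the fixed
Phase-1 threshold; precedence is configurable.  The sensitivity analysis
re-runs Phases 3–4 at each threshold and reports retention and overlap
with a reference set.

Ambiguity filtering is a user-supplied blocklist; no automatic ambiguity
model is attempted.

## Ball geometry and embedding

Distances use the standard ball formula with curvature fixed at −1.
`clip_to_ball` rescales any point with norm ≥ 1 − ε to norm 1 − ε
(ε = 10⁻⁵) and guards every optimizer step.

The tangent-space projection used for clustering is the conformal-factor
scaling v = 2x/(1−‖x‖²) (λₓ · x).  Note this is *not* the exact origin
log-map of the ball, which applies artanh to the norm
(log₀(x) = 2 artanh(‖x‖) · x/‖x‖); the two agree to first order near the
origin, where indicator embeddings concentrate.  The scaling form is used
deliberately and consistently — it preserves radial ordering exactly, so
the fidelity score is unaffected — and this note records the discrepancy
rather than silently substituting the textbook map.

No standard fitting objective exists for placing indicators in the ball
from a dissimilarity matrix, so embedding is weighted metric stress,
Σ wᵢⱼ (d(xᵢ,xⱼ) − δᵢⱼ)², minimized by projected gradient descent: the raw
Euclidean gradient is rescaled by the inverse squared conformal factor
(1−‖x‖²)²/4 (the natural Riemannian correction — without it
near-boundary points barely move), a backtracking line search accepts only
non-increasing objective values, and every accepted iterate is re-clipped
into the ball.  Initialization is seeded uniform in a radius-0.1 ball;
defaults are 2000 iterations at base step 0.05.  When a hierarchy is
supplied, a hinge term Σ relu(‖x_parent‖ − ‖x_child‖ + m)² (m = 0.02,
weight 1, on by default) pushes parents toward smaller radii.  The
Euclidean baseline is the identical optimizer with the flat metric and no
margin term.  Dissimilarities from encoder output are δ = 1 − cosine,
floored at 10⁻³ so distinct phrases never coincide.

**Distortion** (values of this statistic are widely reported without a
formula; ours is): rescale embedded distances by the least-squares scalar
s = ⟨d_emb, d_ref⟩/⟨d_emb, d_emb⟩, then average |s·d_emb − d_ref|/d_ref
over off-diagonal pairs.  Any embedding reproducing the reference up to a
global scale scores zero.  Stress descent finds locally optimal fits: on
planted trees the ball consistently wins on hierarchy fidelity, but its
*distortion* is not asserted to beat the flat baseline and often does not
at these problem sizes — headline fidelity/distortion values from any
particular corpus are corpus-dependent and are not reproduction targets.

## Relation matrix and acyclicity

Attention follows the standard scaled dot-product form per head
(softmax(QKᵀ/√d_k)V, 8 heads, d_k = 64 by default), operating on indicator
embeddings, not token sequences.  No published construction specifies how
concatenated head outputs become an n×n score matrix; mapping each
indicator's concatenated vector through a single fixed projection to an
n-vector would break permutation equivariance (relabeling indicators must
relabel rows *and* columns).  We therefore use a bilinear output
transform: two factor projections W_src, W_dst of shape (h·d_k) × n_out
give C = (O·W_src)(O·W_dst)ᵀ — equivariant, asymmetric, and still a linear
transform of the concatenated outputs.  Parameters are seeded
orthogonal-initialized; no training objective for them is defined here.

The acyclicity penalty h(C) = tr(e^{C∘C}) − n uses the scaling-and-squaring
Padé matrix exponential; exhaustive enumeration against a depth-first
cycle oracle (all binary patterns up to 4×4) confirms h < 10⁻⁹ exactly on
acyclic graphs.  `enforce_dag` minimizes ½‖X−C‖² + λh(X) with normalized
gradient steps, accepting a step only when it lowers both the composite
objective and h itself (so the penalty is monotone across accepted
iterations), doubling λ on plateau.  Near-zero residual cycles that
survive the h ≤ 10⁻⁸ tolerance are then broken by zeroing the smallest
participating entry — zeroing can only lower h, since the trace
exponential is monotone in the nonnegative Hadamard square — so the output
also passes the discrete cycle check at threshold 10⁻⁶.

## Clustering and model selection

k-means is Lloyd's algorithm with a seeded farthest-point initialization,
10 restarts (best within-cluster sum of squares wins), and an explicit
empty-cluster rule: an emptied centroid is re-seeded at the point farthest
from its assigned centroid.  Silhouette follows the usual (b−a)/max(a,b)
with singleton clusters contributing 0 and the a=b=0 degenerate case
defined as 0; Davies–Bouldin raises an error naming the clusters when two
centroids coincide rather than dividing by zero.  Both are cross-checked
against an independent library implementation in the tests.

Topic coherence is add-one-smoothed NPMI over within-cluster phrase pairs
computed from document co-occurrence: p(i) = (dfᵢ+1)/(N+1),
p(i,j) = (dfᵢⱼ+1)/(N+1), NPMI = ln(p_ij/(p_i p_j)) / (−ln p_ij), averaged
over pairs then over clusters with at least one pair.  Phrases never
co-occurring score negative; phrases always co-occurring with equal
document frequencies score exactly 1.  Coherence is computed on the
analysis corpus itself (an external reference corpus would also be
defensible; none is assumed).

Cluster counts k = 3…7 are scored by all three metrics; the selected k is
the majority vote of {max silhouette, min Davies–Bouldin, max coherence},
with every tie (within a metric and across the vote) resolved toward the
smaller k.  Splitting an already-pure cluster cannot lower NPMI coherence,
so the smaller-k tie rule is what makes the coherence vote decisive on
planted structure.

## Validation statistics

Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from marginal
category products; two constant, identical raters define κ = 1
(convention, logged).  A panel of more than two raters is summarized by
the *mean pairwise* κ — not a multi-rater generalization — because the
pairwise statistic is what the quantity of interest names; the alternative
(Fleiss) is out of scope.  Likert retention is conjunctive by default:
≥ 4 raters scoring ≥ 4 AND item mean ≥ 4.0, each sub-rule toggleable.
Consensus gating passes at fraction ≥ 2/3 exactly.  "Variance greater
than 20% between groups" is operationalized as relative range,
(max group mean − min group mean)/overall mean > 0.20, toggleable to
coefficient of variation; flags never remove items.

## Synthetic study conditions

The default corpus recipe emulates the scale of the evidence base this
kind of pipeline targets: 230 documents, ~120 filler tokens each drawn
from a 2000-word Zipf(s = 1.1) vocabulary (long-tail term statistics so
TF-IDF behaves realistically), ten planted multi-word phrases across a
root-plus-three-branches topic hierarchy, with planted frequencies
deliberately straddling the screening gates (one phrase fails the ≥ 7
total-frequency rule, one fails the ≥ 10-article breadth rule).  Phrases
are planted as contiguous token runs over a vocabulary disjoint from the
filler, so an n-gram recount recovers the planted table *exactly* — this
exactness is what lets every funnel count be checked against a brute-force
oracle.  One integer seed drives all streams through SeedSequence
spawning.

What the synthetic world does **not** establish: semantic discrimination.
All generated text is "in-domain" by construction, so the relevance gate
cannot separate planted phrases from filler the way a contrastively
fine-tuned model separates resilience phrases from generic academic prose
on real articles; tests therefore exercise the relevance gate with planted
scores, and the end-to-end pipeline records when it falls back from an
empty screening result to the frequency/breadth survivors
(`indicator_source` in the report).  Likewise, passing recovery tests on
planted trees and blobs shows the machinery is correct, not that any
particular real corpus yields a given fidelity score, distortion, or k.

Rater panels draw a latent consensus score per item; each rater reports it
with probability `agreement`, otherwise an independent uniform score —
agreement 1 gives κ = 1 and agreement 0 gives κ ≈ 0, calibrating the
statistic's endpoints.

## Pipeline and problem sizes

The orchestrator fans one global seed into per-stage seeds by fixed
offsets and is byte-deterministic for a fixed config.  Default problem
sizes (230-document corpus, 2-dimensional embeddings, 800 stress
iterations, 8×16 attention) keep a full run in a few seconds while leaving
every stage's behaviour observable; all are configurable upward.  Tests
use 3-level branching-3 trees (40 nodes) for the geometry comparison and
600 iterations per fit — sizes at which the directional fidelity claim is
stable across seeds.

## Known limitations

* The encoder is bag-of-tokens; word order within a phrase does not affect
  its embedding, which is why near-duplicate merging treats reordered
  phrases as identical.
* `enforce_dag` returns a locally nearest acyclic matrix under its descent
  procedure, not the global least-squares projection (which is NP-hard).
* Stress embedding is non-convex; different seeds give different local
  optima, and only seed-fixed determinism is guaranteed.
* Attention parameters are random (seeded); an optional fitting mode
  against encoder similarities is not implemented beyond the DAG
  projection, as no loss is canonically defined for it.
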