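# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `photocat`, in the spirit of a methods appendix.

## The modeling problem

Photocatalytic reaction outcomes are condition-dependent: the same reactants
can give different main products under different photocatalysts, acids or
bases, additives, wavelengths, and solvents. The canonical example is a
reaction that yields a ketone in the absence of acid but switches to an
alkene when a strong acid such as TfOH is present. `photocat` treats this as
a family of sequence-to-sequence problems over SMILES:

* **forward prediction** — reactants (plus zero to five condition tokens)
  → main product;
* **retrosynthesis** — product → reactant set (single-step);
* **condition recommendation** — full reaction → the five condition tokens.

Conditions are encoded as compact category-prefixed tokens: `P*`
(photocatalyst), `B*` (base or acid), `A*` (additive), `W*` (wavelength),
`S*` (solvent), with index 0 meaning "condition absent" in every category
(`B0` = no base or acid). A per-category bijective vocabulary maps common
reagent names to indices; raw names pass through an editable synonym
dictionary with case- and whitespace-insensitive matching. Reactions whose
reactants act as their own photosensitizer carry the photocatalyst label
`autocatalysis`. Wavelengths are categorical labels ("390 nm", "blue LED"),
not numbers: the platform treats light selection as classification.

In forward sources the condition tokens follow the reactant tokens in the
fixed order P, B, A, W, S, truncated to the first *n* categories, so the
5-condition input extends the 4-condition input prefix-wise and
condition-count ablations differ only in how much context is appended.

## Model

The sequence model is an encoder–decoder attention transformer implemented
in NumPy with hand-written backpropagation (gradient-checked against finite
differences in the test suite). Two configuration profiles matter:

* **Full-scale profile** (`ModelConfig.full_scale()`): 6+6 layers, model
  dim 512, 8 heads, dropout 0.1, label smoothing ε = 0.1, Adam with
  β₁ = 0.9, β₂ = 0.998, Noam learning-rate decay with factor 2.0,
  token-based batches of 4096 with gradient accumulation over 8
  micro-batches, gradient-norm clipping disabled, sinusoidal position
  encoding, standard (Glorot-style) random initialization with an explicit
  seed. This profile documents the reference recipe; nothing in the test
  suite trains at this scale.
* **Tiny profile** (`ModelConfig.tiny()`): 2+2 layers, dim 64, 4 heads,
  feed-forward 256. Two small-scale departures from the classic layout make
  float32 CPU training stable and fast: pre-norm residual connections (with
  a final layer norm per stack) and tied input/output embeddings. The
  warmup-based schedule peaks too high for this model in float32, so the
  grammar recipes instead use a constant rate of 1.5e-3 with a tenfold drop
  for the last fifth of updates ("polish phase"); gradient norms are clipped
  at 1.0. These are recipe choices of this package, selected once while
  designing the desk-scale setup.

The label-smoothing loss places 1−ε on the gold token and spreads ε
uniformly over the vocabulary; with ε = 0 it is exactly cross-entropy (a
hand-computed three-class case pins this in the tests). Decoding is beam
search without length normalization; candidates are deduplicated as strings
and sorted by accumulated log-probability with lexicographic tie-breaks, so
decoding is deterministic given a checkpoint. A candidate's validity flag
means its detokenized string canonicalizes as (multi-component) SMILES.

**Transfer learning.** `staged_fit` supports the two transfer modes:
sequential (pretrain on a generic corpus, then fine-tune) and convex mixture
(one run whose micro-batches are drawn 9:1 from pretrain and fine-tune
streams). Passing a single stream reproduces the two baselines
(pretrain-only, fine-tune-only). The staged retrosynthesis recipe —
molecule-level span-mask denoising, then reaction-level pretraining, then
domain fine-tuning — is expressible by chaining streams;
`grammar.denoising_pairs` builds the masked-molecule stage. Named profiles
`retro_stage` (constant lr 1e-3, batch 64, accumulation 4) and `cond_stage`
(short run at a small constant rate over an augmented stream) mirror the
reference recipes at reduced budgets.

**Attention extraction.** Teacher-forced encoder-decoder attention is
exposed per decoder layer, head-averaged or per head; each output row is a
distribution over source positions (sums to 1). Where the condition focus
lands is realization-dependent in a model this small: across training runs
we observed either a dedicated cross-attention head reading the base/acid
token at the branch-deciding output position, or an encoder self-attention
head mixing the base/acid token into the molecule representations with a
decoder head reading it at some output position. The interpretability check
therefore scans layers and heads on both sides and asserts that the
attention mass on the base/acid token exceeds the uniform baseline by a wide
margin (≈2–6× in trained models), rather than pinning one layer/head. The
functional counterpart — flipping the base/acid token flips the predicted
branch — is tested independently and does not depend on where attention
concentrates.

## Synthetic reaction grammar

Because the full curated database and web-scale pretraining corpora are out
of reach for a desk-scale build, all experiments run on a synthetic grammar
that reproduces the *statistical* structure the platform assumes — it makes
no attempt at mechanistic realism. Molecules are assembled from a
12-fragment alphabet (alkyl, branched, ether, thioether, alkene, CF₂,
benzene, pyridine, furan); every fragment is valid SMILES alone, attaches by
string concatenation, and assembled substituents are capped at 9 characters.
Four templates produce records:

| template | reactants | product | conditions |
|---|---|---|---|
| `branch` | R1-C(=O)O + R2-Br | R1-C(=O)-R2 (no acid) / R1-C=C-R2 (acid); terminal -O with an "oxidative" photocatalyst | photocatalyst group and acid branch decide the product |
| `ester` | R1-C(=O)O + R2-O | R1-C(=O)O-R2 | none |
| `amine` | R1-N + R2-Br | R1-N-R2 | none |
| `threecomp` | R1-C(=O)O + R2-Br + R3-N | R1-C(=O)N(R2)R3 | none |

Only the photocatalyst (terminal hydroxyl or not) and the base-or-acid slot
(ketone vs alkene core) are informative; additive, wavelength and solvent
are drawn independently at random, so condition-count ablations rise exactly
when an informative category enters (P at one condition, B at two) and are
flat afterwards. Products are stored as the grammar renders them —
literature databases store author-written SMILES, not canonical forms — and
all metrics canonicalize before comparison. Records carry full five-category
conditions, times (0.5–48 h), yields (15–99 %), and synthetic references.

`ambiguity_fraction` (default 0.5) is the fraction of records belonging to
condition-ambiguous pairs: identical reactants and photocatalyst group,
base-or-acid on opposite sides of the acid branch, distinct products. A
condition-blind predictor resolves at most half of those records, so its
held-out top-1 is bounded by 1 − ambiguity_fraction/2 (0.75 at the default);
the condition-aware model is unconstrained by this ceiling. Reactant-set
instantiations are sampled without replacement, and a deterministic hash
partition of the instantiation space yields train/test splits whose held-out
records use *unseen reactant combinations* of seen templates. The
pretraining corpus contains only condition-free templates over a superset
fragment alphabet: pretraining overlaps the fine-tune distribution (shared
fragments, shared templates) without ever revealing a condition-dependent
product, which is what makes the transfer ordering (pretrain→fine-tune ≥
fine-tune-only ≥ pretrain-only) and the near-zero pretrain-only accuracy on
condition-branched products meaningful.

What the grammar does **not** emulate: reagent-specific reactivity, yield
structure correlated with conditions, stereochemistry, atom mapping, the
long tail of rare reagents, and the name diversity of real condition
annotations (six photocatalysts and a handful of bases/solvents versus
dozens in a curated database). Passing tests therefore demonstrate that the
pipeline recovers condition-dependent structure *when it is present*, not
that any particular accuracy transfers to literature data.

## Evaluation

Accuracy is canonical-SMILES equality; multi-component predictions (the
retrosynthesis task) are compared as order-insensitive multisets of
canonical components. Invalid candidates can never count as hits, and the
invalid-SMILES fraction is measured on rank-1 candidates only. Top-k uses
ranked beam candidates; k-fold splits are uniform shuffles without
stratification. For retrosynthesis, only an exact (canonical multiset) match
counts — chemically equivalent alternative precursors are scored as misses,
which makes the reported retro accuracies conservative.

## Problem sizes and budgets

All training in the test suite and the reproduction script uses the tiny
profile at the package's standard desk-scale sizes: 2,500 training records,
300 held-out records, 4,000 pretraining reactions; 2,500 optimizer updates
for forward/retro models, 1,000 per transfer stage, 1,500 for the condition
model. At these sizes a forward model reaches ≥95 % held-out top-1 with all
five condition tokens (typically 98–99 %), and each training run takes a few
minutes on one CPU core. These sizes are the package's chosen desk-scale
study conditions; the full-scale profile exists as configuration only.

## Numerical choices and degenerate inputs

* float32 parameters and activations; loss and log-softmax in float64.
* Beam ties broken lexicographically; k-best lists deduplicated as strings.
* Tanimoto of two empty fingerprints is defined as 1.0.
* Histogram bins for similarity distributions are fixed at width 0.05.
* Exact k-nearest-neighbor search (cosine distance on difference
  fingerprints) replaces approximate LSH-forest indexing at these dataset
  sizes; the `knn_graph`/`mst` split leaves an indexing hook for scale. The
  difference fingerprint (summed product minus summed reactant Morgan count
  vectors, folded to 256 bits) is a structural stand-in for learned reaction
  fingerprints, so cluster shapes are only qualitatively comparable.
* Kruskal's MST relies on a stable sort, making tie-breaks deterministic in
  edge insertion order; the tree layout is a deterministic radial drawing
  (leaves get DFS-ordered angular slots, internal nodes the mean angle of
  their subtree, radius = depth), with exact coordinate collisions
  perturbed deterministically.
* Span masking replaces one contiguous token span (length drawn uniformly
  from 2–4, clamped at the sequence end) per application with probability
  0.5; randomized SMILES permute atom indices through an explicit generator
  so augmentation is reproducible. Augmented copies default to 5 per record
  for condition-model training streams.
* Checkpoints store parameters, configuration, and the token vocabulary;
  loading refuses a vocabulary-hash mismatch. Optimizer moments are not
  checkpointed: resuming fine-tunes restarts Adam, which at these scales is
  indistinguishable after a few dozen updates.

## Known limitations

* The condition-recommendation model can only recover what the data
  determines: on the grammar, the acid *branch* (99+ %) and photocatalyst
  *group* (~90 %), while specific tokens of uninformative categories stay at
  chance. On real data with informative correlations the same architecture
  would be trained identically.
* Single-step retrosynthesis only; no route search trees.
* Novelty flags come from an exact canonical-reaction index lookup, with a
  hook for external checkers; no licensed-database search is attempted.
* The grammar's retrosynthesis task has intrinsic ambiguity (symmetric
  ketone products admit two precursor splits), which caps exact-match retro
  accuracy slightly below forward accuracy.
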