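# Methods

This note documents the models, parameter choices, numerical decisions and
limitations of `ptm_crosstalk`. It is the place where genuinely open
design questions and their resolutions are recorded.

## Quantitation and the target-score scheme

Site intensities are assumed multiplicative: a site's measured intensity
is (biological modification level) × (protein loading) × (lognormal
noise). Normalising by per-condition protein abundance before taking the
log2 ratio therefore removes loading exactly; the synthetic generator
reproduces this structure so the cancellation identity
(`x = 0` for pure loading changes) holds to machine precision at zero
noise and is tested that way.

The fold-change-to-score transformation is

    score(x) = (x + 1)/2 + 0.25, clipped to [0, 1]

with the wild-type anchor fixed at 0.75. The log base is 2 (the MS
label-free-quantitation convention); the base only rescales the interval
on which the map is linear. Clipping is applied in score space, plus an
optional symmetric pre-clip at |x| ≤ 4 to tame outlier ratios. Sites
detected in exactly one condition are excluded from targets by default
(no imputation); an optional pseudo-intensity floor (half the smallest
positive intensity in the table, with a per-condition median-abundance
fallback for the missing normaliser) can be enabled. Direction calls use
a dead zone: |x| ≤ 0.1 is "unchanged", so numerical noise is never
classified as hyper/hypo. The same dead zone is applied to predicted
fold-changes for comparability.

Continuous targets are trained with binary cross-entropy. BCE against a
soft label t is minimised exactly at p = t, so the continuous scores act
as calibrated targets rather than class labels; binary accuracy (threshold
0.5) is logged as a coarse training metric.

## Sequence encoding

Uniform 514-token windows: `[start][≤512 residues][end][pads]`. Token
vocabulary: the 20 amino acids in alphabetical order (ids 0–19), start=20,
end=21, pad=22. Positional information enters as the standard sinusoidal
encoding (sin/cos pairs, 10000^(2i/d) wavelengths) added to the learned
embeddings; the encoding dimension equals the model dimension (128 at
study scale).

Proteins longer than 512 residues are chunked into 512-residue windows
advanced by 256 residues (half-window overlap) and per-residue predictions
are averaged over overlaps. The overlap choice is a deliberate design
decision: a window that does not contain the mutated residue produces
*identical* WT and mutant representations for every site it covers, so
crosstalk from the mutation is structurally invisible there. With
half-window overlap, any two positions up to 768 residues apart share at
least one window — in particular every window of either Hsp90 isoform
(732/724 aa) contains the K283/K275 site. A narrower overlap (we first
used 32) silently caps the recoverable site set; this is checked by a
dedicated test.

Padded key positions are masked out of attention (additive −1e9 bias), so
trailing pads cannot influence real-token outputs. This makes two exact
optimizations available: batches may be cropped to their longest real
window, and mixed-length batches may be bucketed by length.

## Predictor architecture and pretraining

The per-residue predictor is a pre-norm transformer encoder (LayerNorm
inside the residual branches, final LayerNorm before the head) with a
13-way sigmoid head. Pre-norm is used for stable training at the larger
learning rates the desk-scale models need. The study-scale default is
d=128, 4 layers, 4 heads, FFN 256 — the architecture of the original
base models is not public, so these are declared choices with d matching
the stated 128-dimensional positional encoding. The desk/test profile is
d=64, 2 layers, 4 heads, FFN 128: experiments showed that at d=32 the
single trainable block lacks the routing capacity to express the
mutation's long-range effect at most sites, while d=64 suffices (see
"Desk-scale adaptations").

Everything is implemented in NumPy with a small reverse-mode autodiff
engine that is part of the package (float32 by default; the engine's
gradients are verified against central finite differences in float64).
Training is full-batch or mini-batch Adam; all randomness flows through
`numpy.random.Generator` seeds, making pretraining and fine-tuning
bit-reproducible for a given seed on a given platform.

Base models are pretrained on the synthetic motif corpus with full-matrix
BCE (every cell supervised, since synthetic labels are fully observed).
Per-class PR-AUC (average precision) on a held-out split must beat the
class-prevalence baseline for motif-bearing classes; classes with no
held-out positives are flagged absent and fall back to equal ensemble
weights rather than scoring 0.

## Fine-tuning protocol

"Freeze all but the final encoding layer and the last dense layer" is read
as: the last transformer encoder block, the final LayerNorm, and the
output head are trainable; embeddings and earlier blocks are frozen. The
alternative reading (head only) is available as a selectable freeze
policy. Freezing is enforced at three levels: the optimizer skips frozen
parameters, frozen parameters stop requiring gradients (so backprop does
not traverse them), and SHA-256 checksums of every frozen group are
verified after training.

Two exact cost reductions follow from the freeze structure and are used
during fine-tuning:

- **Frozen-prefix caching** — activations below the first trainable block
  are constant across epochs and are computed once.
- **Supervised-query restriction** — when only the network tail is
  trainable, its output is needed only at supervised positions, so
  attention is computed for those query rows only (keys/values over the
  full cached prefix). This is algebraically identical to the full pass
  (attention rows are independent given keys/values) and ~15× cheaper at
  514-token windows with ~30 supervised cells per window; a test asserts
  equality against an explicit full forward pass.

The six-sequence dataset pairs each record with a target matrix: WT
records carry the 0.75 anchor at WT-observed sites; the K→Q and K→R
records both carry the scores derived from the knock-out MS fold-changes
(the study's MS conditions are HDAC-knock-out cells, which motivate the
acetyl-mimetic mutants; no separate measurement exists for the blocking
mutants, so both variants receive the measured targets). At a mutated
position, classes the new residue cannot carry (acetyl-K on Q/R) are
masked out of the loss. Loss is computed over supervised cells only —
full-matrix supervision with implicit zeros would punish genuinely
unmeasured sites.

Per-member seeds derive deterministically from (config seed, member
index). Ensemble weights are the base models' held-out PR-AUCs,
normalised per class; the fine-tuned members are combined as a per-class
weighted arithmetic mean of probabilities.

## Synthetic-data generator

The generator defines the study conditions end to end:

- **Sequences**: uniform residue draws; lengths uniform in a range.
- **Labels**: local motif rules (context window with wildcards, e.g.
  basophilic `RR?S` for phospho-S, `GK` for acetyl-K, `K?E` for SUMO,
  `N?S/T` sequons) emit positives at `boosted_rate` on context match and
  `base_rate` otherwise, only ever at chemically eligible residues; a
  long-range `CrosstalkRule` boosts every eligible site when a distal
  trigger pattern (`GKG`) occurs anywhere in the chain, and the corpus
  generator plants that trigger in half the sequences. The motif model is
  a stand-in for the unknown statistics of real PTM training data and
  makes no fidelity claim.
- **Intensity tables**: per-site lognormal baselines, per-condition
  abundance factors, planted log2 effects in KO conditions, multiplicative
  lognormal noise. At `noise_sd=0` with unit abundance factors the
  quantitation stage recovers every planted effect exactly.
- **Interactome tables**: lognormal baselines with planted ±log2 shifts
  in designated KO conditions, giving known Venn ground truth.
- **Hsp90 stand-ins**: deterministic sequences with the real isoform
  lengths (α 732, β 724), the correct residue identity at every panel
  position, and the α/β numbering offset of 8; the acetyl-lysines carry
  the generator's own acetylation context (`GK`), with the full `GKG`
  crosstalk trigger placed uniquely at K283/K275 so the K→Q/K→R mutation
  removes the one planted distal trigger. They are clearly labelled
  synthetic and are *not* the real HSP90AA1/HSP90AB1 sequences.

**Panel effect magnitudes** (fixture choices): hyper effects +0.4 log2
units (target score 0.95) and hypo effects −1.0 (target 0.25). Both are
interior points of the score map's invertible range. We initially used
+1.0 for hyper sites, which saturates the target at the clip boundary
(exactly 1.0); saturated targets make BCE chase an unbounded logit against
the shared WT anchor and measurably destabilise recovery, and their
magnitude is unrecoverable by construction. Interior targets avoid both
problems.

What the generator does **not** emulate: peptide-level identification and
roll-up, missing-value mechanisms correlated with intensity, retention
time or FDR structure, correlated noise across sites, and real evolutionary
sequence structure. Passing tests therefore demonstrate correctness of the
pipeline's arithmetic and learnability of planted structure under the
stated noise model — not performance on real proteomes.

## Desk-scale adaptations

The study-scale protocol (15 pretrained base models, 500 epochs, Adam
lr 1e-4, d=128) assumes mature pretrained bases. The desk profile used by
tests and `run_crosstalk_study` re-creates small bases from scratch, and
two protocol parameters required scale adaptation, kept as explicit,
separately-documented profile defaults (the study-scale defaults are
unchanged):

- **Learning rate / epochs**: expressing a single-residue input difference
  across a 514-token window requires the trainable block's attention to
  lock onto the mutated position; with randomly initialised small bases
  this "attention alignment" needs on the order of 10³ full-batch Adam
  steps at lr 1e-2. At the protocol's 1e-4 × 500 the fine-tuned model
  fits the target *means* but never discriminates mutant from WT
  (predicted fold-changes ≈ 0 everywhere). The desk profile uses
  lr 1e-2 × 2000 epochs; probe experiments at short sequence length
  (40 aa) confirm the protocol values themselves learn perfectly when the
  attention span is small, i.e. this is a scale effect, not a protocol
  defect. Training much longer (6000 epochs) over-trains and degrades
  sign recovery; 2000 sits on the plateau.
- **Capacity**: at d=32 two of three members reproducibly stall with only
  a minority of planted sites recovered; d=64 with 4 heads recovers most
  sites per member.

Individual members still differ in *which* sites they recover (attention
alignment is per-site and seed-dependent); the PR-AUC-weighted ensemble
union substantially stabilises the readout. Across our experiments the
ensemble's *precision* was always 1.0 — every site whose predicted
|log2 fold-change| cleared the dead zone agreed with the planted
direction — while the *call rate* varied with seed (roughly 7–13 of the
13 directional panel sites). The end-to-end test therefore asserts what
the procedure actually guarantees: ≥90% direction agreement on
jointly-called sites plus a minimum-coverage floor (≥9 of 13 sites
called), rather than a claim of full recall.

An attempt to instill the long-range crosstalk capability during
*pretraining* (so fine-tuning would only re-weight it) did not converge at
desk scale: models pretrained on the trigger-bearing corpus learn the
local motifs and the marginal rates but show no measurable response to
trigger ablation. The corpus keeps the long-range structure (it is part of
the study conditions), but at this scale the fine-tuning stage is where
the long-range dependence is learned.

## Numerical choices

- float32 training precision (halves memory traffic on the (B, H, L, L)
  attention maps); float64 for all quantitation arithmetic.
- Softmax shift floored at −60 before exponentiation: exp(−60) ≈ 9e-27 is
  an exact zero for attention purposes but avoids subnormal-arithmetic
  slow paths triggered by the −1e9 pad mask.
- Stable BCE-with-logits (`max(z,0) − zt + log1p(exp(−|z|))` form); the
  logistic function computed via tanh.
- ε = 1e-6 probability floor in predicted fold-changes guards p = 0 cells
  (eligibility-masked residues give 0/0 → lfc 0, "unchanged").
- Ensemble weights are normalised per class; a class with zero total
  weight is an error, except that classes absent from validation data
  fall back to equal weights.
- Ties and boundaries: direction thresholds are strict inequalities, so
  |x| exactly at the dead zone is "unchanged"; binder classification at
  exactly ±threshold is "unchanged".

## Known limitations

- The synthetic stand-in sequences preserve panel residues and lengths
  but not real Hsp90 sequence context; conclusions about the real
  chaperone require supplying the real FASTA records.
- Concordance is sign-agreement only; predicted magnitudes are not
  calibrated to MS fold-changes and are not compared.
- The desk-scale ensemble's call rate varies with seed (see above); only
  the precision of called directions is a stable guarantee at this scale.
- The base-model architecture, its pretraining corpus, and the chunking
  policy for >512-residue inputs are not public; all three are declared
  package choices and configurable.
- No statistical test is attached to concordance (the analysis claims
  trend agreement, not significance), and no FDR modelling is performed
  anywhere.
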