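# ptm-crosstalk

Analysis pipeline for post-translational-modification (PTM) crosstalk on
the Hsp90 chaperone: does acetylation of a specific lysine
(Hsp90α-K283 / Hsp90β-K275) reshape phosphorylation elsewhere on the
protein? The package converts site-level mass-spectrometry (MS) PTM
intensities into continuous training scores, fine-tunes an ensemble of
per-residue multi-label PTM predictors on wild-type and acetyl-site-mutant
Hsp90 sequences with almost all weights frozen, and compares the
mutant-versus-WT predicted phosphorylation changes against the MS-derived
hyper/hypo calls. A synthetic-data module generates every input — labeled
pretraining corpora, MS-style intensity tables with planted effects, and
drug-pulldown interactome tables with planted Venn structure — from
explicit distributions and seeds, so the whole pipeline runs and is tested
without any external data.

It is aimed at computational proteomics groups who want a reusable,
testable implementation of this analysis pattern (MS quantitation →
continuous targets → frozen-backbone fine-tuning → trend concordance)
rather than a one-off notebook.

## The method

**Quantitation.** For a modified site measured in a knock-out/mutant (KO)
and wild-type (WT) condition, the abundance-normalised log fold-change is

    x = log2( (I_KO / A_KO) / (I_WT / A_WT) )

where `I` is the site's modified-peptide intensity and `A` the protein
abundance in that condition, so pure loading changes cancel.

**Target scores.** Fold-changes become continuous training targets on
[0, 1] via

    score(x) = (x + 1) / 2 + 0.25, clipped to [0, 1]

which anchors "no change" at score(0) = 0.75 — the same constant assigned
to every WT observation — keeping unchanged sites inside the positive
prediction class (> 0.5) while leaving headroom for hyper- (→ 1) and
hypo-modification (→ 0). The map is strictly increasing and invertible on
x ∈ (−1.5, 0.5).

**Model.** A transformer encoder over protein sequence: learned token
embeddings plus 128-dimensional sinusoidal positional encodings, uniform
514-token input windows (start + ≤512 residues + end, padded; longer
proteins are chunked with half-window overlap and overlap-averaged), and a
13-way sigmoid head giving per-residue probabilities for 13 PTM classes
(phospho-S/T/Y, acetyl-K, methyl-K/R, ubiquitin-K, SUMO-K, N-/O-glyco,
palmitoyl-C, hydroxyl-P/K), with chemically impossible (residue, class)
cells masked to zero.

**Fine-tuning protocol.** Base models are pretrained on a motif-labeled
corpus; fine-tuning then freezes everything except the final encoder block
and the output head and trains binary cross-entropy against the target
scores of a six-sequence dataset — α-WT, β-WT, and the K→Q
(acetyl-mimetic) and K→R (acetyl-blocking) variants of each isoform —
over the supervised cells only (500 epochs, Adam, learning rate 1e-4 at
the study-scale default). The procedure repeats over 15 base models (study
scale), and per-PTM-class ensemble weights are derived from each base
model's held-out precision-recall AUC.

**Crosstalk readout.** For mutant vs WT predictions the per-site predicted
log fold-change `log2((p_mut + ε)/(p_wt + ε))` is classified hyper / hypo /
unchanged with the same ±0.1 dead-zone used for MS calls, and concordance
with the MS directions is summarised per class. Because the model scores
each isoform separately, every isoform-ambiguous MS site ("K283;K275")
resolves into distinct α and β rows.

**Interactome sets.** Independently, drug-complex pulldown abundances
(protein × {WT, KO_a, KO_b}) are classified increased / decreased /
unchanged per KO by a log2 threshold and partitioned into shared/unique
Venn cells per direction.

## Worked example

Simulate the Hsp90 study panel without noise and quantify the
acetyl-mimetic condition:

```python
from ptm_crosstalk import (gen_intensity_table, hsp90_site_panel,
                           normalize_and_lfc, score_from_lfc)

sites, effects = hsp90_site_panel()
table = gen_intensity_table(sites, effects, noise_sd=0.0,
                            abundance_factors={"WT": 1.0, "KQ": 1.0, "KR": 1.0},
                            seed=1)
for fc in normalize_and_lfc(table, "KQ"):
    print(f"{fc.protein_id:24s} {fc.position:8s} {fc.ptm_type:10s} "
          f"x={fc.x:+.2f} {fc.direction:9s} score={score_from_lfc(fc.x):.2f}")
```

prints

```
HSP90A_SYN               231      phospho_S  x=+0.40 hyper     score=0.95
HSP90A_SYN               263      phospho_S  x=+0.40 hyper     score=0.95
HSP90A_SYN               399      phospho_S  x=+0.40 hyper     score=0.95
HSP90A_SYN               453      phospho_S  x=+0.40 hyper     score=0.95
HSP90A_SYN;HSP90B_SYN    283;275  acetyl_K   x=+0.40 hyper     score=0.95
HSP90A_SYN;HSP90B_SYN    362;354  acetyl_K   x=-1.00 hypo      score=0.25
HSP90A_SYN;HSP90B_SYN    615;607  acetyl_K   x=-1.00 hypo      score=0.25
HSP90B_SYN               226      phospho_S  x=+0.40 hyper     score=0.95
HSP90B_SYN               255      phospho_S  x=+0.40 hyper     score=0.95
HSP90B_SYN               261      phospho_S  x=+0.40 hyper     score=0.95
HSP90B_SYN               391      phospho_S  x=+0.40 hyper     score=0.95
HSP90B_SYN               532      phospho_S  x=+0.40 hyper     score=0.95
```

Each row is one site of the planted panel: `x` is the recovered log2
fold-change (exactly the planted value at zero noise — note the pure
loading-change cancellation), the direction is the hyper/hypo call, and
`score` is the fine-tuning target the site receives. The three `K…;K…`
rows are isoform-ambiguous acetyl sites shared between Hsp90α and Hsp90β.

The full study — pretrain, fine-tune the ensemble, and measure
predicted-vs-planted concordance — runs with

```python
from ptm_crosstalk.pipeline import run_crosstalk_study
result = run_crosstalk_study(seed=1)      # a few minutes on one CPU
print(result.summary.n_concordant, "/", result.summary.n_compared)
```

or from the shell via `ptm-crosstalk crosstalk --seed 1 --out-dir out/`.
The other CLI subcommands (`simulate`, `build-dataset`, `encode`,
`pretrain`, `predict`, `quantify`, `interactome`) wrap the corresponding
library functions; see `ptm-crosstalk --help`.

## Scope notes

The packaged Hsp90 α/β FASTA records are deterministic *synthetic
stand-ins* (correct isoform lengths, correct residues at every study-panel
position, the study's α/β numbering offset) — not the real
HSP90AA1/HSP90AB1 sequences; real sequences can be supplied as FASTA.
Upstream of this package (raw spectra, peptide identification,
search-engine output) and downstream enrichment/visualisation are out of
scope; see `docs/methods.md` for the model's assumptions and limitations.
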