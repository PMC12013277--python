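# Methods

## Problem

In Sec-utilizing bacteria the UGA/TGA codon is dual-use: usually a stop, but
in selenoprotein genes an in-frame TGA is recoded to selenocysteine (Sec)
when recoding machinery and a downstream SECIS element are present. Standard
gene callers therefore truncate selenoprotein genes at the Sec codon.
`selenoscan` predicts selenoprotein genes with a two-stage design:

1. **Geometric + neural stage.** Every TGA triplet in all six reading frames
   (both strands) of the query genome is collected. Around each TGA a
   candidate ORF is reconstructed (ATG/CTG/GTG start, no in-frame terminator
   before the TGA, a terminator after it). The fixed-length window
   immediately downstream of the TGA — the region that physically carries
   the recoding signal — is scored by a transformer encoder over overlapping
   k-mer tokens. The model is structure-agnostic: it learns the downstream
   sequence signal without folding RNA.
2. **Homology stage.** Model-positive candidates are translated with U at
   the recoded TGA and searched against a microbial protein database. A
   candidate is retained iff (i) at least one Sec-containing homolog aligns
   Sec-to-Sec, or (ii) at least two of the top ten hits place cysteine at
   the Sec position and come from different organisms. Hits are
   pre-filtered at e-value ≤ 0.01 and identity ≥ 20%. Retained candidates
   are labeled *known* when a supporting Sec homolog belongs to a curated
   known-selenoprotein set, else *new*.

## Scanner conventions

Coordinates are 0-based, half-open, strand-local (an index into the reverse
complement for minus-strand features); 1-based conversion happens only in
GFF3 output. Replicons are treated as linear; ambiguous IUPAC bases never
match TGA.

Open choices the scanner pins down (all configurable in `ScanParams`):

- **Start codon selection** — the farthest in-frame start not separated
  from the TGA by a terminator (longest-ORF convention of standard
  prokaryotic gene callers); nearest-start available via `longest_orf=False`.
- **Terminator set** — `{TAA, TAG}` by default: a downstream in-frame TGA is
  ambiguous (it could itself encode Sec), so TGA terminates the walk only
  when explicitly added to the set.
- **Length floors** — `min_upstream_codons=10` and `min_orf_len=90` nt
  suppress spurious micro-ORFs while keeping short selenoproteins; both can
  be set to 0 to disable.
- **Contig edges** — windows truncated by the contig end are 3'-padded with
  N (k-mers containing N tokenize to UNK), so near-end candidates survive;
  3'-partial ORFs are flagged and excluded from translation/homology.

## Tokenization and model

Windows of L ∈ {100, 200, 300} nt are tokenized into overlapping k-mers
(k ∈ {3, 4, 5}, stride 1), giving L − k + 1 tokens; the vocabulary holds the
4^k ACGT k-mers after five reserved specials (PAD, UNK, CLS, SEP, MASK).
The production configuration is 300 nt / 3-mer.

The classifier is a BERT-style encoder implemented in NumPy with explicit
forward/backward passes (verified against finite differences in the test
suite) and AdamW. Default (`paper` profile) architecture: 768-dim token +
learned positional embeddings, 6 post-LayerNorm encoder blocks with 6
attention heads and 2048-unit GELU feed-forward layers, dropout 0.2 on
hidden and attention activations. Pretraining is masked-token prediction
(15% of tokens selected; 80% → MASK, 10% → random k-mer, 10% kept) on the
label-free training windows, batch 32, 3 epochs. Fine-tuning adds a softmax
head on the CLS representation and trains 10 epochs with cross-entropy,
AdamW, batch 128, learning rate 1e-6; after each epoch validation accuracy
is logged and the best epoch's weights are retained (ties → earliest).
The pretraining learning rate is not separately specified by the published
description; we use 1e-4, the convention of the BERT lineage.

The `test` profile: 2 layers, 64 dims, 4 heads, intermediate 256, 5
fine-tuning epochs, fine-tuning batch 64, 2 pretraining epochs, learning
rate 1e-3 for both phases. At this scale the optimizer has only ~160
fine-tuning steps; at the paper-style rates it is still on its initial loss
plateau when the budget ends, so the desk-scale rate is raised until the
plateau breaks within the budget (the label-shuffled control guards against
the higher rate fitting noise). A second profile difference beyond size:
the test profile sets attention-probability dropout to 0 (hidden-state
dropout stays 0.2). Generating a fresh (batch × heads × 300 × 300) dropout mask
each step dominated single-CPU step time while contributing nothing at this
scale; the paper-scale profile keeps attention dropout at 0.2.

Numerics: float32 parameters and activations; the attention softmax and its
backward are fused numba kernels with pure-NumPy fallbacks (the float64
fallback path is what the finite-difference gradient checks exercise);
inference runs without dropout and without activation caches, so scoring is
deterministic and batch-size invariant. All randomness flows through seeded
`numpy.random.Generator` objects; a fixed seed reproduces a training run
bit-for-bit on one machine.

## Corpus construction

Positive windows are extracted downstream of annotated Sec-TGA codons,
negative windows downstream of the terminal TGA of genes in
non-Sec-utilizing organisms; exact duplicates are dropped. Splits follow a
family-aware recipe: 90% of sequences from 40 seeded-random selenoprotein
families (sampled per family, preserving family proportions) train; 50% of
sequences from 30 further families validate; everything else is a test
candidate, kept only if its identity to every train/validation sequence is
below 70%. Negatives are shuffled and subsampled so each split has as many
negatives as positives.

Identity definitions (the published corpus used an external clustering
tool; we need reproducible in-process definitions):

- **Clustering** (50% identity / 80% coverage, greedy longest-first):
  identity = matches / aligned columns of a local alignment (match +1,
  mismatch −1, gap open −2, extend −1), coverage = aligned span / length,
  required for both sequences. Greedy assignment joins the earliest-founded
  cluster whose representative passes both thresholds.
- **Test-set leakage cap (≥70%)**: identity = local-alignment matches
  normalized by the shorter sequence (the CD-HIT convention). Per-column
  identity of a bare local alignment is not usable here: a short
  near-perfect local alignment between unrelated sequences exceeds 70%,
  which would empty the test split.

## Homology backends

Three backends implement one tabular contract (the 12-column BLAST dialect
plus aligned query/subject strings and an organism tag): precomputed hit
tables, external `blastp`, and a built-in Smith-Waterman backend
(BLOSUM62, gap open −11, extend −1) used by tests and fixtures. Sec is
scored as Cys on both sides (aligners lack U scores; this maximizes
Cys-homolog detectability) and restored in the reported alignment strings;
the query's Sec index travels out-of-band. The built-in backend's e-values
follow the Karlin–Altschul form E = mn·2^(−bits) with gapped BLOSUM62
constants — deterministic and monotone in score but **not calibrated**
against BLAST/DIAMOND statistics; it is adequate for fixture databases,
not for production screens. Criterion (i) of the retention rule is applied
to the full filtered hit list (the published rule states no rank bound);
criterion (ii) is applied to the top ten. "Different organisms" means
distinct organism tags parsed from subject headers (`id|organism|family`
dialect; configurable for real databases).

## Synthetic data

The fixture generator emulates the study conditions without downloads. The
recoding signal is a 24-nt position weight matrix (consensus
`GGTCAGCGGTTCCGCGAAGCCTGC`, chosen stop-free in frame) emitted immediately
after the Sec-TGA and mixed with background at `motif_strength` (default
0.8); background is i.i.d. at the configured GC content (default 0.5). A
PWM, not a folded stem-loop, is deliberate: the classifier contract only
needs a learnable localized downstream signal, and the model itself is
structure-agnostic.

Corpora default to 2,000 windows per class. Synthetic genomes (default
100 kb) carry 10 planted selenogenes — TAA guard, ATG, 15–30 random sense
codons, TGA, a 300-nt frame-safe downstream region carrying the PWM
emission, TAA — and 50 decoy genes that genuinely stop at TGA, placed
non-overlapping on both strands; the TAA guard pins the reconstructed ORF
start to the planted ATG. The fixture database holds 3 Cys-variant homologs
per planted gene (U→C plus 5–15% random substitutions, distinct organism
tags) and unrelated decoy proteins; decoy genes get no homologs.

What passing these tests shows — and does not. The synthetic signal is a
fixed-position PWM; real SECIS elements vary in position, structure and
strength, and real negatives are not i.i.d. background. Desk-scale results
therefore validate the machinery (scanning, learning, filtering,
reporting), not the published benchmark numbers, which required the
83k-organism corpus and GPU training and are out of scope here.

## Desk-scale study conditions

The scaled-down learning run uses the default corpus (2,000 + 2,000
windows, motif strength 0.8), split 50/25/25 into train/validation/test,
the `test` model profile, and a label-shuffled control fine-tuned from a
clone of the same pretrained encoder (pretraining is label-free, so sharing
it is exact). The end-to-end run scores the default 100-kb genome with the
same classifier and the built-in alignment backend over the generated
fixture database. These sizes are the package's fixed desk-scale
conditions; `scripts/acceptance.py` re-runs all of them from a single seed.

## Known limitations

- No SECIS secondary-structure validation; structure checking of new
  candidates is a downstream manual step.
- The built-in aligner's e-values are uncalibrated (see above).
- Paper-scale training (768-dim, 6-layer, tens of thousands of windows) is
  supported by the same code path but is not practical on one CPU; no
  trained paper-scale weights ship with the package.
- Circular replicons are treated as linear: ORFs and windows do not wrap
  the origin.
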