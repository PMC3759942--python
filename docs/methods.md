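# Methods

This note documents the models, procedures, numerical choices and known
limitations of `afebox`.

## Problem setting

LuxR-family quorum-sensing regulators bind palindromic operators
(lux-box-like elements). The afe-box — the operator upstream of the AHL
synthase gene of *Acidithiobacillus ferrooxidans* — is a 30-bp element with
an unusual modular structure: a large palindrome (LP) whose two halves are
themselves short palindromes (SP) and inverted repeats of each other, with
a central 18–20-bp medium palindrome (MP) corresponding to the canonical
lux-box. `afebox` predicts candidate binding sites genome-wide by modelling
each module separately, so that conservation of palindromic *structure*,
rather than plain sequence conservation, drives the search.

## Palindrome templates and training alignments

Five fixed-length templates encode the modules (fixed positions literal,
variable positions as wildcards):

| id | pattern | variants |
|------|----------------------------------|-----|
| SP13 | `TGACA-NNN-TGTCA` | 64 |
| SP15 | `Y-TGACA-NNN-TGTCA-R` | 256 |
| MP18 | `GCTGTCAA-NN-TTGACAGC` | 16 |
| MP20 | `AGCTGTCAA-NN-TTGACAGCT` | 16 |
| LP30 | `TGACAAGC-TGTCA-NNNN-TGACA-GCTTGTCA` | 256 |

Wildcards expand combinatorially (`N`→{A,C,G,T}, `Y`→{C,T}, `R`→{A,G}) in
lexicographic order, so the training alignments are byte-reproducible. The
SP15 expansion enumerates all 64 central trinucleotides times the two
flanking degeneracies (256 sequences); restricting the centre to
homopolymer 3-mers would give only 16 and is not what the 256-row
alignment implies, so the full expansion is used.

Model letters A–E (A=SP13, B=SP15, C=MP18, D=MP20, E=LP30) are merged
downstream into the SP/MP/LP sets, so the assignment within the A/B and
C/D pairs cannot affect results.

## Profile models and scanning

Because every training alignment is fixed-length and ungapped, the
insert/delete states of a profile HMM are degenerate; each model is an
ungapped position-wise emission profile. Emissions are maximum-posterior
frequencies with a symmetric pseudocount (default 1.0 per base); the
background is the scanned genome's mononucleotide composition,
strand-symmetrised (A=T, C=G). Windows are scored as

    S(w) = sum_i log2( p_i(w_i) / q(w_i) )   [bits]

with ambiguous bases contributing 0 bits. Both strands are scanned;
above-threshold windows are accepted greedily by descending score,
discarding windows that overlap an accepted hit of the same model on
either strand (multiple non-overlapping matches per sequence). For
dyad-symmetric models the two strand scores at a locus coincide; such
duplicates are collapsed to one forward-strand hit (tolerance 1e-9).

The score threshold defaults to 0 bits (configurable). An optional
calibration sets it to the (1−q)-quantile of window scores on a
dinucleotide-shuffled genome (default q = 1e-5, Eulerian-walk shuffle).
This is a deliberate re-implementation of glocal multi-hit profile search
for the fixed-length case, not an emulation of any particular HMM
package's bit scores; absolute hit counts therefore depend on the chosen
threshold.

## PBS catalog

A predicted binding site (PBS) is a genome fragment covered by one or more
model hits on either strand. Hits overlapping by ≥1 bp merge by single
linkage; the PBS interval is the union, its label set the union of member
SP/MP/LP labels (single/double/triple sites). Merging is independent of
input order and idempotent. The PBS centre — used for all distance
reporting — is the floor of the interval midpoint.

## Genomic context

Intergenic (IG) regions are the complement of the CDS intervals. An IG
region is *sense* when at least one flanking gene reads away from it into
its own body, i.e. the gene's start codon abuts the region (the gap
between converging genes' stop codons is not sense). Classification:

* **Type I** — the PBS interval overlaps (≥1 bp) a sense IG region;
* **Type II** — otherwise, the PBS centre lies within the strand-aware
  window [start−200, start+50] of some gene's start codon;
* **Type III** — everything else.

Type I uses interval overlap while Type II uses the centre; the two
idioms are both present in the underlying definition of the classes and
the split is configurable. The "250-bp zone" total (t250Z) is the union
over genes of the same strand-aware windows. Densities per megabase use
denominators tIG (Type I), t250Z − tIG (Type II) and L − t250Z (Type
III); these sum to the genome length L by construction. On gene-sparse
layouts the Type II denominator can be non-positive, in which case the
density is reported as undefined rather than negative or infinite.

Candidate selection: all Type I PBSs are kept; a Type II PBS is kept only
if a σ70-like promoter prediction occurs within the PBS ± 100 bp; Type
III is always discarded.

## σ70-like promoter predictions

A deliberately simple consensus predictor stands behind the promoter
gate: positional weight matrices anchored on TTGACA (−35) and TATAAT
(−10) with consensus-base frequencies from the classic *E. coli*
compilations, remaining probability spread evenly over the other bases.
Every −35/spacer/−10 placement with spacer 15–19 bp is scored on both
strands as the sum of the two hexamer log-odds scores; placements above
the threshold (default 60% of the maximum achievable score) are reported
best-first without overlap. Reports label these "σ70-like predictions".
No transcription start sites and no alternative sigma factors are
modelled; the gate is intentionally permissive and its output is an
annotation (overlaps −35 / overlaps −10 / near / none, with −35 taking
precedence and "near" meaning within 10 bp).

## Motif refinement

**Discovery.** A single ungapped motif is re-estimated from the selected
PBS neighbourhoods (PBS ± 80 bp) by EM under the ZOOPS model (zero or one
occurrence per sequence, both strands; OOPS available). The E-step
computes posterior site locations; the M-step re-estimates emissions with
a 0.25 pseudocount per base and the per-sequence site prior γ. EM restarts
from 5 subsequence-derived seeds (20 iterations each); the best restart
runs to convergence (relative LLR change < 1e-6 or 500 iterations).
Because the pseudocount makes this MAP-EM, a raw-likelihood decrease is
possible in principle; iteration therefore also stops on any decrease and
keeps the best model, so the recorded LLR trace is non-decreasing by
construction. A phase-shift move (restarting from column-shifted models,
±1 and ±2) corrects the register-offset local optima EM is prone to.
With a width range, the width maximising a BIC-penalised LLR
(LLR − (3W/2)·ln of the total window count) is kept. With constant flanks
around identical planted sites the register is genuinely unidentifiable;
the tests account for this.

**Exact p-values.** PSSM cell scores are discretised to a granularity of
0.01 bits and the distribution of the discretised window score under the
background is obtained by dynamic-programming convolution across
positions — exact for the discretised matrix, with total probability 1 to
float precision.

**Database rescan.** Each intergenic sequence is scanned on both strands;
the best window score yields a position p-value from the exact
distribution, a sequence p-value 1 − (1 − p)^m over the m scored windows
(an independence approximation of the MAST kind), and an e-value =
sequence p-value × database size. Occurrences below the e-value cutoff
(default 10) are reported ascending.

**Consensus and logo.** Site alignments reduce to a plurality consensus
(ties → IUPAC codes) and per-column information content
2 + Σ_b f_b log2 f_b bits under the uniform background, written as a
per-column TSV consumable by any plotting layer.

## Synthetic data

The generator emulates a desk-scale slice of an acidophile chromosome:
single contig, default 100 kb at 58% GC (i.i.d. mononucleotide
background, matching the scanner's background model; a first-order Markov
option with mild CpG depletion exists for robustness tests);
non-overlapping CDSs of 0.6–1.5 kb separated by 80–250 bp gaps until the
chromosome is full (~90% coding, as in real bacterial genomes). Junction
arrangements are sampled from a configurable diverging/converging/tandem
mix; the right-hand gene's strand is derived from the left one, so a
sampled type that is unreachable from the current strand yields a
different realised junction — the realised layout is what the annotation
records. Planted instances are sampled from a template's emission profile
with a sharpness parameter interpolating towards background (1.0 =
consensus-sharp), spliced at positions whose context classification is
verified at placement time, at least 60 bp apart so that distinct plants
can never be merged by ≤30-bp hits. The truth table stores interval,
strand, context and expected type; identical configs and seeds produce
byte-identical FASTA/GFF3/truth outputs.

The standard recovery benchmark plants 30 consensus-sharp instances
across templates and contexts in a 100-kb chromosome and measures, over 5
seeds: sensitivity (PBS covering ≥50% of a planted interval), false
merges (a PBS bridging two disjoint plants), and context classification
accuracy of recovered instances.

What passing these benchmarks does *not* show: real operators diverge
from the consensus (sharpness < 1 regimes are harder); real intergenic
background is not i.i.d.; real annotations contain overlapping and
frame-shifted CDSs, RNA genes and mis-called starts; and the promoter
gate is a consensus caricature of real σ70 promoters. Absolute hit and
PBS counts depend on the scan threshold and are not comparable across
backgrounds.

## Problem sizes and defaults

Default problem sizes were chosen so a full run stays interactive on one
core: 100-kb benchmark chromosomes, 5 benchmark seeds, 20×200-bp motif
recovery sets, EM width fixed to 18 in the orchestrated pipeline examples
(the afe-box core width; a 13–30 width scan is available and simply takes
proportionally longer). `scripts/acceptance.py` reruns all of the above
from scratch in well under a minute.

## Known limitations

* Ungapped profiles cannot represent variable-spacer operators; all five
  templates are fixed-length by design.
* The greedy non-overlap selection is order-deterministic but not a
  maximum-weight interval packing; ties are broken by position then
  strand.
* The sequence p-value's independence approximation is anti-conservative
  for overlapping self-similar windows (palindromes); e-values are
  comparable within a database, not across tools.
* Gene "product" text is taken verbatim from the GFF3; no functional
  re-annotation is attempted.
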