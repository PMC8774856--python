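# Methods

This note documents the models, conventions and numerical choices behind
mitoprofile. The package characterises small circular mitochondrial genomes —
the vertebrate mitogenome being the motivating case: a ~16.5 kb circular
duplex carrying 13 protein-coding genes (PCGs), 22 tRNAs, two rRNAs, a
light-strand replication origin (O_L) and a control region (D-loop) — and
compares conspecific mitogenomes for intraspecific variation and congeneric
ones for phylogeny.

## Coordinates and strand conventions

All coordinates are 1-based inclusive on the heavy (H) strand, the GenBank
feature-table convention. Light-strand features are stored by H-strand span
plus a strand flag and reverse-complemented on extraction; composition is
always reported for the H strand, so AT-skew = (A−T)/(A+T) and
GC-skew = (G−C)/(G+C) measure strand asymmetry directly. A skew whose
denominator is zero is reported as null, never as 0. Wrap-around features are
not supported; the bundled gene-layout template needs none. Spacing between
consecutive features is `next.start − prev.end − 1` (negative = overlap), with
a circular closure pair between the last and first feature.

## Composition

Percentages are taken over non-N bases; N counts are carried separately.
CpG islands follow the Gardiner-Garden & Frommer sliding-window criterion:
100 bp windows, G+C% strictly above 50, observed/expected CpG
(`nCpG·W/(nC·nG)`) at least 0.6; overlapping or abutting qualifying windows
merge, and merged islands shorter than 200 bp are dropped. The strict/non-
strict choice per threshold is configurable because published descriptions
of the same tool disagree between ">" and "≥"; the defaults above were fixed
once and match the published island on the reference genome's coordinates.
Molecular weight sums average anhydrous nucleotide-monophosphate residue
masses (A 313.21, C 289.18, G 329.21, T 304.20 Da) over both strands of the
circular duplex, with no terminal corrections; these constants reproduce the
published reference weight (10,196.19 kDa) exactly from the published base
counts.

## Codon usage and bias indices

Translation table 2 (vertebrate mitochondrial) throughout: stop family
{TAA, TAG, AGA, AGG}, Met = {ATA, ATG}, Trp = {TGA, TGG}; Leu and Ser are
treated as single six-fold families, giving the degeneracy classes
12 two-fold / 6 four-fold / 2 six-fold. Genes whose length mod 3 is 1 or 2
end in incomplete stop codons (T– or TA–) completed to TAA by mRNA
polyadenylation; completion is applied before any counting, so stop usage
includes the completed TAAs and the codon count per gene is ceil(size/3).

* RSCU(c) = k·n_c / N for a codon in a family of size k with family total N;
  family RSCU values sum to k exactly.
* ENc uses Wright's bias-corrected family homozygosity
  F = (n·Σp² − 1)/(n − 1), class means over families with n ≥ 2, and
  ENc = Σ_k m_k / F̄_k clipped at 60. A class with no eligible family is
  imputed from the global mean F (flagged); under the mito code ENc ranges
  from 20 (one codon per family) to 60 (uniform usage). Because of the n-1
  correction ENc is only asymptotically invariant to count scaling.
* CBI = (N_opt − N_ran)/(N_tot − N_ran) with N_ran = Σ n_aa/k_aa; the optimal
  set defaults to the per-family argmax of the pooled usage (alphabetical
  tie-break) and per-gene CBI uses the pooled optimal set.
* GC3s is the G+C fraction at third positions of sense codons (all sense
  codons are synonymously variable under this code; stops excluded), and the
  null ENc–GC3s curve is ENc*(s) = 2 + s + 29/(s² + (1−s)²).

The bundled pooled codon-usage table reproduces the published amino-acid
frequencies (e.g. Ile 8.64%, Ser 7.49%, Cys 0.68%) and RSCU(CTA) = 2.70 by
direct arithmetic. Two published numbers are arithmetically inconsistent with
that table (a Trp frequency of 8.38% where the table sums to 2.76%, and a
pooled GC3s of 0.404 where the table's third positions give 0.369); the
package computes from the table and does not target those two values.

## Repeat, palindrome and motif scanning

Conventions are stated explicitly because census totals depend on them:

* **SSRs** are maximal perfect runs of a primitive unit (periods 1–10 by
  default, ≥3 whole copies, span ≥6 bp), reported once at the smallest
  period. A chance flanking base can shift the reported whole-copy window by
  up to period−1 positions relative to a planted array — recall tests allow
  exactly that slack and nothing more.
* **Palindromes** are even-length windows equal to their own reverse
  complement (6–30 bp); by default one maximal palindrome per center,
  with a `count_all` mode matching census tools that count every sub-length.
* **Inverted repeats / hairpins** are arm–spacer–arm structures found by an
  anti-diagonal scan: positions p, q with p+q constant pair when
  seq[p] = complement(seq[q]); each maximal run of consecutive pairs is one
  hit whose spacer is fixed by its innermost pair (arms 6–50 bp, gap ≤ 20 for
  SIRs; loop 3–20 with stem ≥ 5 for hairpins; zero mismatches). Arms longer
  than the cap are trimmed outward, keeping the inner anchor.
* **Tandem repeats** use a simplified seed-and-extend detector: candidate
  periods p ≤ 500 are seeded where seq[i] = seq[i+p] matches are dense
  (≥ 0.7 per one-period window), the merged region is trimmed at edges that
  break periodicity, a majority consensus is built per period phase, and the
  region is locally aligned to cyclic repetitions of the consensus by
  wraparound dynamic programming with weights +2/−7/−7 and minimum score 50.
  Copy number is (aligned pattern columns)/period; percent matches is over
  all alignment columns; overlapping hits are resolved by score (smaller
  period wins ties). This honours the published scan weights without
  promising the reference tool's probabilistic model; accuracy is
  demonstrated on planted arrays (period, copies ±0.3, matches ±2 points).
* **Motifs** over {A,C,G,T,N} are scanned on both strands with N as a free
  wildcard; circular scans wrap the origin and deduplicate by canonical
  start.

## Control-region annotation

The D-loop divides into ETAS, central conserved (CD) and CSB domains in fixed
order. Elements (ETAS1, the GCCCCAT D-loop terminator, TAS-A, F/E/D/C/B
boxes, CSB1–3, HSP, LSP) are located by minimum-edit-distance infix search
(edlib) under per-element caps from a motif-library TSV; the leftmost best
match wins, and elements exceeding their cap are reported missing, never
placed. Domain boundaries anchor on the F-box (CD start) and B-box (CD end).
The bundled library is a **synthetic stand-in**: the conserved cores that are
public (GCCCCAT, the ATGN9CAT palindromic core inside ETAS1 and CSB1, the
TATAT termination-associated core, a C-rich CSB2) are embedded in synthetic
context, because no single printed source provides the full mustelid
consensus set. Annotation of real genomes should use a species-appropriate
library with the same schema; the shipped tests therefore validate recovery
of planted library motifs, not fidelity to any real control region.

## Variation and diversity

A variant is one polymorphic alignment column; contiguous gap runs shared by
the same rows merge into a single indel event, and a column holding both a
substitution and a gap yields two calls. Multi-allelic columns count once
(all alternatives recorded) and are typed transition only if every ref–alt
pair is one. Insertions relative to the reference anchor on the preceding
reference base. Coding effects translate ref/alt codons under table 2
(L-strand genes complement the alleles); indels are not frameshift-classified.

Diversity statistics default to complete deletion (columns with any gap or N
excluded), matching the common population-genetics software convention:
π = mean pairwise differences per considered site, k = mean pairwise
difference count, Hd = n/(n−1)(1 − Σp²) over haplotype frequencies,
C = fraction of monomorphic considered sites, singleton and
parsimony-informative site counts as usual. Haplotypes group rows identical
over gap-free columns (indel columns excluded by default, so length variants
of one substitution haplotype merge). The haplotype network is the union of
all minimum spanning trees over Hamming distances between haplotype
representatives — an edge is kept exactly when its endpoints are not
connected by strictly lighter edges. This is a deliberate substitute for
median-joining: with a handful of closely related haplotypes the
minimum-spanning network carries the same information without median-vector
inference. Hypervariable segments merge sliding windows (50 bp, step 10)
whose variant incidence reaches 1/25 bp; the threshold is configuration, not
inference, since published HVS bounds are drawn by inspection.

## Distances and trees

p-distances are mismatches over pairwise-complete sites (pairwise deletion by
default, per the published distance-table convention). TN93 uses the
closed form with the two transition classes and base frequencies estimated
from each pooled pair (configurable); any pair driving a logarithm argument
non-positive is flagged undefined rather than clipped. Neighbour joining is
the standard Saitou–Nei agglomeration with a deterministic lexicographic
tie-break; negative branch lengths are clamped to zero with the deficit moved
to the sister branch (Kuhner–Felsenstein), preserving path lengths. Distance
NJ is used deliberately in place of likelihood inference: the original
analysis reports that NJ, ME and MP gave trees identical to its ML tree, so
distance NJ preserves the comparative conclusions at a fraction of the
dependency surface. Bootstrap supports resample alignment columns (rows are
sorted by id first, making supports invariant to row order) and report the
percentage of replicates containing each internal bipartition of the
point-estimate tree.

## Synthetic data

The generator emulates the study conditions: a 16,504 bp circular genome
with the bundled gene layout; background bases i.i.d. with H-strand fractions
A 0.3282, C 0.2611, G 0.1383, T 0.2724 (A>T>C>G, A+T ≈ 60%); control-region
plants (the motif library's elements in domain order with random spacers,
microsatellites (CT)₃/(AT)₃, homopolymers T₆/C₇/G₈, and a 10 bp × 22
minisatellite array); and an 11 bp stem / 13 nt loop hairpin at the O_L
position. PCG frames are made stop-free by single-base repairs that preserve
the A+T count (e.g. TAA→TAT, AGA→ACA), re-imposed iteratively because
overlapping genes can reintroduce stops into each other's frames; canonical
ATG starts and terminal T/TA/TAA signals are written the same way. The
no-stop constraint and the planted elements shift realized A+T by well under
one percentage point.

Haplotype sets use a star genealogy: each of n haplotypes mutates
independently from the ancestor with per-site substitution probability μ
(capped at 0.01 to stay in the single-hit regime), transition probability
κ/(κ+1) given a substitution (defaults n = 6, μ = 0.002, κ = 10 — a
transition:transversion skew of the order seen in conspecific mitogenome
panels), and indel events at rate 1e-4 with geometric lengths. The generator
emits the alignment directly (insertion columns added in place), so no
aligner is involved, and records every event plus the exact per-column
expected substitution calls. Under the star model E[π] = 2μ exactly, which
the calibration tests check to Monte-Carlo precision. What the star model
does **not** emulate: genealogical correlation (coalescent topology), rate
heterogeneity along the genome, selection, VNTR copy-number mutation and
heteroplasmy — so passing tests demonstrate correctness of the statistics,
not realism of mitochondrial evolution.

## Problem sizes in the shipped tests

Scanner-versus-oracle equivalence runs on 20 random 300 bp sequences per
detector; diversity calibration on 100 replicates of 2 kb, 6-haplotype
simulations; NJ recovery on 25–50 random 5–8 taxon additive trees; bootstrap
determinism at B = 25–100. These sizes were chosen so the whole suite runs
in well under a minute while keeping every Monte-Carlo check at ≥3-standard-
error resolution. The accession-based checks (published π, pairwise distance
and clade support) need the deposited GenBank records and are built by
`scripts/fetch_accessions.py`; without those files the corresponding tests
skip.

## Known limitations

* The tandem detector is not a TRF clone: its statistical model, multi-period
  reporting and redundancy rules differ, so census totals on real genomes are
  indicative, not reproducible bit-for-bit (the same holds for web-tool
  SIR/palindrome totals, which depend on undocumented maximality rules).
* TN93 is undefined for saturated pairs; such entries are flagged, and NJ
  refuses matrices containing them.
* The default control-region motif library is synthetic (above); O_H
  prediction, tRNA/rRNA structure and thermodynamic folding are out of scope.
* Variant calling assumes a trustworthy input alignment; no realignment or
  heteroplasmy handling is attempted.
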