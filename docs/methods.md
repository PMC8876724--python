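# Methods

This note documents the models, rules and numerical choices behind
`mitowgs`, and what the synthetic-data validation does and does not
demonstrate.

## Reference and coordinates

All coordinates are 1-based with inclusive ends, the forensic mtDNA
convention; the genome is a 16,569-bp circle and regions may wrap the
origin (position 16,569 is followed by 1). The control region is nps
16,024–576 (1122 bp) and the coding region nps 577–16,023 (15,447 bp);
the two partition the circle.

The bundled FASTA is a **synthetic stand-in** for the rCRS
(NC_012920.1). It reproduces the features the pipeline's logic touches:
length 16,569; the HVS2 A-stretch (300–302) and C-stretch (303–315,
interrupted by 310T); the HVS1 A-stretch (16,180–16,183) and C-stretch
(16,184–16,193, with 16,189T); the C-stretches at 956–960 and around
10,946; and the real reference base at every position named by the
built-in NUMT signatures, NUMT catalog and PHP hotspot list (263A,
13,062A, 13,095T, 13,105A, 16,390G, 16,519T, 16,093T, …). The remaining
filler is drawn once, from a fixed seed, with human-mtDNA-like base
composition. Every operation in the package is position-based, so
results transfer unchanged to the real rCRS; what does *not* transfer is
any sequence-specific mappability structure (the real mitogenome has a
few short repeats the synthetic filler lacks).

## Read simulator

The simulator emulates the mitochondrial alignment of a deep shotgun WGS
sample:

* **Read model** — 150+150 paired-end reads, insert 350 ± 50 bp,
  constant Q35 base quality, per-base miscall rate 1e-3. These match
  modern PCR-free short-read chemistry at desk scale.
* **mtDNA fragments** are uniform on the circle (fragments may span the
  origin); the pair count realizes the requested average depth
  (`n = depth·L / (2·150)`).
* **Point heteroplasmies**: each mtDNA fragment carries the minor base
  independently with the PHP's fraction, so the local minor-read
  fraction equals the planted fraction and distinct PHPs ride distinct
  molecules (phase-discordant), as in true intra-individual
  heteroplasmy.
* **NUMT donors** are haplotypes differing from the reference only at
  their documented variant cluster; reads are drawn uniformly from a
  homology tract extending 600 bp beyond the cluster on each side
  (real NUMT homology tracts are much longer than their distinguishing
  variant clusters). `copy_fraction` is defined *locally*: it is the
  expected fraction of donor-derived reads over the homology span, i.e.
  the expected minor-nucleotide frequency at the donor's variant
  positions. The donor pair count is sized so that interior positions of
  the span reach `depth·f/(1−f)` donor depth. Built-in donors carry the
  two recurrently observed signatures: the ND5-region trio (A13062G,
  T13095C, A13105G; span nps 13,060–13,110) and the six-variant in-phase
  HVS1 cluster (G16390A, A16399G, C16444T, G16496A, T16519C, C16527T;
  span nps 16,380–16,535).
* **Contamination** is a second full-circle haplotype at a fixed
  fraction of total reads.
* **Post-homopolymer errors**: bases within 3 bp 3′ of a run of ≥ 4
  identical bases (computed on the read as sequenced) have their miscall
  rate multiplied by 20 (default) and errors there are biased (0.8)
  toward the run base. This is the simplest mechanism that reproduces
  the recurrent A-stretch artifacts (e.g. A302M) seen 5′ of the HVS
  C-stretches in patterned-flow-cell data. No quantitative rate for this
  artifact is established, so the boost is a free parameter.
* A single generator seeded from the spec drives every draw; identical
  specs yield byte-identical reads.

Not modelled: PCR duplicates, indel sequencing errors, GC bias, quality
decay along the read, mega-NUMT tandem structure, and nuclear flanking
sequence on donor reads (only the mtDNA-homologous portion co-aligns,
which is the portion that matters to this pipeline). Consequences for
interpretation: passing tests show the *decision logic* (thresholds,
phasing, clustering, gates) behaves correctly under controlled mixtures;
they do not certify performance against real flow-cell artifact spectra
or alignment ambiguity around indel-rich C-stretches, which in real data
produce the below-threshold positions the nearly-complete category
exists for.

## Aligner and consensus workflow

The acceptance contract is the pair (length fraction, similarity
fraction): an alignment is accepted iff aligned-read-bases/read-length ≥
the length fraction and matches/aligned-columns (read-insert columns
excluded) ≥ the similarity fraction. Permissive mapping uses 0.5/0.8,
stringent consensus remapping 0.95/0.95 — at 150 bp, 0.95 similarity
tolerates 7 mismatches, so a single 150-bp read can only be rejected by
stringency when it disagrees with the sample consensus at 8 or more
columns; the depletion of NUMT reads by the consensus remap is therefore
partial at these read lengths, which is exactly why the downstream
variant-level classification exists.

Implementation: exact 15-mer seeding against the doubled reference
(circularity by coordinate reduction mod L), gapless extension in the
common case, and edlib infix alignment (unit edit costs) as the gapped
fallback. Reads tying at two or more distinct loci are discarded rather
than placed randomly — random placement would inject seed-dependence
into minor-allele frequencies. Mates are aligned independently.
Consensus: per-position majority over aligned bases; ties and uncovered
positions fall back to the reference base (deterministic,
reference-stable). The realignment step transfers stringently-accepted
reads to reference coordinates 1:1 (the consensus is a per-position
substitution of the reference) and applies no further acceptance gate.

## Variant detection

A base observation is *qualified* if its own quality is ≥ 30 and the
mean quality of the ±5-bp window on the read (truncated at read ends) is
≥ 30; both central and neighborhood minima are read as "≥ 30" because
only the radius and the minimum are established — this concrete
window-mean reading is this package's contract. Frequencies are over
qualified depth, deletions included in the denominator. Positions with
qualified depth < 100X are flagged, not called. At callable positions
the major base is called (count ties resolve toward the reference); a
second base at ≥ the detection threshold (2%, 5% or 10%) produces a
mixed position with the two-base IUPAC code; a third base at threshold
routes the position to QC as multi-allelic mixture evidence instead of
force-coding.

Haplotype post-processing: indels shift to the 3′-most equivalent
position of their homopolymer run (insertions get decimal suffixes at
the run end); within the configured C-stretch regions (303–315 and
16,184–16,193) a read-count analysis over runs ≥ 3 bp reports only the
major-length molecule (ties → shorter molecule; point substitutions in
runs are retained); mixed positions inside the A-stretch zones (300–302,
16,180–16,183) are removed as post-homopolymer artifacts. If a sample
has 1–4 positions below 100X it is *nearly complete*: such positions are
auto-confirmed into the haplotype when depth ≥ 20X and the major base
reaches 90% — an automated stand-in for manual review of the alignment —
otherwise they are excluded from the reported range.

The 2% call set is always computed alongside the analysis threshold: the
band between 2% and the analysis threshold ("low band") is evidence for
classification, and higher thresholds are exact frequency filters of
lower ones, so call sets nest by construction.

## NUMT / PHP classification

Phasing is read-pair based: for two positions, over the pairs covering
both, the pair is *minor-bearing* if it shows either minor; the pair of
positions is `in_phase` if ≥ 90% of minor-bearing pairs carry both
minors, `unassessable` with < 5 covering pairs (typical for positions
more than an insert length apart — the short-read limitation that makes
distant phasing invisible), else `discordant`. A strand-balance check
runs first: a minor allele with < 10% of its observations on the rarer
strand is tagged artifact (no established value exists; 10% is this
package's default and is configurable).

Initial review (per sample): NUMT label if (a) the position lies in a
documented NUMT hotspot region — nps 12,612–13,105 or 16,390–16,527 —
and is in phase with another mixed/low-band position in that region, or
(b) it is in phase with a catalogued NUMT variant, or (c) its positional
cluster (circular gap ≤ 500 bp, a window spanning the larger hotspot
region) has ≥ 2 members of which at least half are catalogued or
hotspot-region members.

Secondary review (dataset-aware): only positions with minor frequency
< 10% in samples with average depth ≤ 1500X enter — NUMT interference
is only observed under those conditions, so everything else defaults to
PHP. Inside the gate, at least 2 of 4 indicators must concur for a NUMT
label: catalogue membership; the same variant NUMT-labelled in ≥ 3 other
samples; an in-phase 2–5%-band partner; not being a known PHP hotspot
(nps 146, 152, 204, 16,093, 16,192, 16,311). The two analysts' holistic
judgement has no published decision rule; the explicit ≥ 2-vote
structure is this package's reproducible stand-in, and both the vote
count and the indicator set are configurable. An optional mode ignores
np 16,093 in all interpretations, the conservative treatment proposed
for that hotspot.

The bundled catalog distinguishes externally documented NUMT variants
from signature variants established by initial review of WGS data; both
count as catalogue members.

## Sample QC

Complete = every position ≥ 100X qualified depth; nearly complete = 1–4
below; incomplete = ≥ 5 below. A sample is flagged a possible mixture
when it retains ≥ 5 residual PHPs after NUMT removal or shows any
multi-allelic position — calibrated so that a genuine four-PHP sample
passes; this residual-count rule is weaker than a phylogenetic (
haplogroup-based) mixture review, which is out of scope, and a
contaminant haplotype that happens to share catalogued NUMT variants can
be absorbed as NUMT interference instead of flagging. Shared haplotypes
are substitution-only matches ignoring indels and any position
heteroplasmic in either sample; shared pairs with nuclear kinship above
0.0884 (the second-degree lower bound; the convention names the degree,
not a number) keep only the deeper sample. Percent-mapped-to-nuclear
metrics require nuclear alignments and are accepted as metadata only.

## Problem sizes and determinism

The test suite validates on simulations of 120–800X (seconds each); the
signature-recovery check uses a 2000X sample (~110,000 read pairs,
tens of seconds), the scale at which an 8% donor fraction is measured
with ±0.6% binomial noise so the 5%-vs-10% threshold behaviour is
unambiguous. The analysis drivers run a twelve-sample cohort of
60–1200X. All pipelines are deterministic given the configuration and
seed; reruns are byte-identical.

## Known limitations

* The CLC length/similarity-fraction semantics for gapped alignments are
  not public; the column-walk definitions above are this package's
  contract and may diverge at the margin for indel-containing reads.
* Haplogroup assignment, nuclear-genome competitive mapping, BLAST-based
  NUMT discovery and phylogenetic mixture deconvolution are out of
  scope; external labels can be supplied where relevant.
* The synthetic reference stands in for the rCRS (see above); swap in
  the real NC_012920.1 FASTA via the `reference_fasta` config key for
  real-data use.
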