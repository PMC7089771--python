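# Methods

## Coordinates and conventions

All transcript coordinates are 0-based, half-open, in transcript
orientation; GTF input (1-based, inclusive) is converted at parse time.
`cds_end` is one past the last nucleotide of the stop codon — the CDS
*includes* the stop. GENCODE CDS features exclude the stop codon, so the
parser extends the CDS by the `stop_codon` feature when present, otherwise
by 3 nt after verifying the sequence is a stop triplet. Sequences are kept
in the DNA alphabet (T); U appears only in reporting labels (e.g. `UGA`,
column names of the context outputs).

## Transcript selection

Quantifying 3'UTR translation requires that the region downstream of a stop
codon is not the CDS of another isoform. Per gene, isoforms are filtered in
order: (1) keep those whose stop codon is 3'-most in genomic orientation
(largest genomic end on +, smallest genomic start on −); (2) APPRIS
principal, else APPRIS alternative; (3) CCDS membership; (4) longest CDS;
(5) shortest 3'UTR; (6) shortest 5'UTR; and, when everything ties, the
lexicographically smallest transcript id — an arbitrary but deterministic
final tie-break. A selected transcript is then discarded if any of its
exons overlaps any exon of any isoform of the nearest same-strand neighbor
gene (upstream or downstream, by genomic span distance), or if its UTR
intervals (exon-level) overlap an annotated pseudogene. Transcripts without
both UTRs, with incomplete-CDS tags, or whose CDS fails the
multiple-of-3 / terminal-stop checks are dropped with logged reasons.

## A-site assignment

The observable is the footprint's 5' end; the quantity of interest is the
codon in the ribosomal A site. We store each read as one count at the
nucleotide in the **center** of the A-site codon; the codon start is
`center − 1` and all window arithmetic downstream is defined on codon
starts. Offsets are calibrated per library and read length from reads over
the start codon: an initiating ribosome holds AUG in the P site, so its
A-site codon is the second codon, with center at `cds_start + 4`. For reads
with 5' ends within 40 nt upstream of the start codon the candidate shift
is `cds_start + 4 − five_prime`; the offset for a length is the mode of
candidate shifts within [10, 20] (ties to the smaller shift, logged).
Lengths with fewer than 200 calibration reads fall back to the canonical
table {28:16, 29:16, 30:16, 31:17, 32:17, 33:17, 34:17, 35:17}. The
literature describes the shift as reaching "the center of the A or P site
codon"; the center-of-A-site reading is the one that reproduces that
canonical table under start-codon calibration, and is our convention
throughout. Short 20–23 nt (empty-A-site) footprints have an analogous
table {20:16, 21:16, 22:17, 23:17} and can be ingested, but all analyses
default to full-length 28–35 nt reads.

Only primary alignments are counted; a `--unique-only` switch additionally
drops low-MAPQ reads for sensitivity analyses. Reads whose shifted A-site
falls off the transcript are dropped, not clipped. Depth normalization is
reads-per-million computed within each read length and summed
(`per_length`, the default) or with a single library-wide factor
(`global`). All ratio statistics (RRTS, metagene ratios, occupancies) are
per-transcript ratios and do not depend on a global scale factor; the exact
raw/RPM equivalence holds under `global` normalization, while `per_length`
reweights read lengths slightly. The mode is recorded in each run report.

## Metagene profiles and the 3'UTR/CDS ratio

Stop-anchored windows span −150..+100 with position 0 at the first
nucleotide of the stop codon (the stop occupies 0..2, so "+4" — the first
3'UTR nucleotide — sits at window position +3); start-anchored windows span
−100..+150. Each transcript's track is divided by its own mean CDS density,
transcripts whose window does not fit entirely inside the transcript (or
with zero CDS density) are excluded and counted, and profiles are averaged
with equal weight per transcript — the CDS normalization has already
removed expression differences, so read-weighted averaging would only
reintroduce them. The 3'UTR/CDS ratio is 100 × mean profile over +5..+100
divided by mean over −147..−16, computed on the averaged profile
(a per-transcript-then-average variant is available behind a flag);
stop-proximal positions are excluded to avoid the termination peak.

## RRTS

`RRTS = ext_density / cds_density` with CDS window
`[cds_start+18, cds_end−15)` and extension window `[cds_end+6, tc3_pos)`.
Exclusions, each recorded as exactly one reason in the output table:
`low_reads` (fewer than 128 reads assigned anywhere on the transcript —
the threshold is deliberately not restricted to the CDS), `no_3tc`,
`short_extension` (fewer than 5 complete codons strictly between the NTC
and the 3'TC, i.e. `tc3_pos − cds_end < 15`, which leaves at least 9
informative nucleotides after the 6-nt exclusion), and `zero_cds`
(zero CDS-window density, rather than an infinite score). Zero RRTS values
are genuine measurements (no detected readthrough) and are kept; for
log-scale plotting they are floored at 2⁻¹⁵, and excluded from
correlation statistics.

Group comparisons by stop-codon identity (or the 4-nt stop signal) use the
Mann–Whitney U test: exact enumeration when both groups have ≤8 untied
observations, otherwise the normal approximation with continuity and tie
correction. Comparisons involving a designated +4 nucleotide can be
one-sided ('greater').

## NTC vs 3'TC relative readthrough

For eligible transcripts, downstream/upstream density ratios are computed
in 30-nt flanks of each stop codon, excluding the codon immediately before
and after it: with position 0 at the stop's first nucleotide, upstream
[−30, −4] and downstream [+6, +32], 27 nt each (the stated windows were
ambiguous about half-open ends; we keep them symmetric). Densities are
CDS-mean normalized. Transcripts are excluded when they lack an in-frame
3'TC, the first 3'TC lies within 30 nt of the NTC, fewer than 30 nt remain
downstream of the 3'TC, or another in-frame 3'TC falls in the 30 nt
downstream of it. The per-anchor summary is the mean ratio; with ≥2
replicate libraries a paired t-test compares the per-replicate mean TC3
ratio against the NTC ratio.

## Frames and codon occupancy

The frame of a count is `(codon_start − cds_start) mod 3`, with residue
classes {0, 1, 2} reported as frames {0, +1, −1}. Region fractions use
CDS-normalized densities, making them invariant to expression scaling. The
frame-resolved 3'TC profile anchors, independently per frame, on the first
3'UTR stop triplet whose start lies in that frame and sums depth-normalized
density over ±12 nt. Transcripts with any additional stop triplet (any
frame) overlapping the window are discarded: termination at a nearby stop
in another frame — including the NTC itself when the anchor is
stop-proximal — would otherwise contaminate the profile, and with this
filter an off-frame anchor shows no density step while the in-frame anchor
shows the termination drop.

Codon occupancy (pause score) of a sense codon is the mean over all its
occurrences of (density in the codon's 3-nt window) / (transcript CDS mean
density excluding the first and last 15 nt), skipping occurrences in the
first or last two codons of the CDS. Under uniform dwell times the
occurrence-weighted mean occupancy is 1 by construction.

## Stop-codon sequence context

The context of a transcript is the 30-mer from 15 nt upstream of the stop
codon through 12 nt downstream, weighted by the transcript's RRTS
(transcripts with 3'UTRs shorter than 12 nt are dropped). For each of the
27 non-stop positions and each nucleotide, a pooled-variance (Student)
two-sample t-test compares RRTS weights with vs without that nucleotide at
that position, one-sided in the direction of the observed mean difference
(the direction is not pre-registered; signed statistics are reported).
Welch's test is available behind a flag. The stop codon is tested as three
codon-vs-rest cells. Benjamini–Hochberg adjustment spans all tested cells
— positional and stop — as one family. Cells with fewer than two records
on either side, or constant weights with unequal group means (no
within-group variance to test against), are reported untested; fully
constant weights give t = 0, p = 0.5.

The ridge model regresses RRTS on a binary design of 27 positions × 4
nucleotides plus 3 stop-codon indicators — 111 features, the only encoding
consistent with that feature count. Features are not standardized (they
are binary), the intercept is unpenalized, and the default penalty is
α = 10³. Nucleotide-frequency matrices are computed around the NTC
(−40..+60, requiring ≥60 nt of 3'UTR) and the first 3'TC (±12 nt, requiring
≥12 nt downstream and no other in-frame stop in the window), with the stop
codon collapsed to a single row whose columns are the three stop codons;
every row sums to 1.

## The synthetic generator

The generator emulates the features of ribo-seq data the analyses rest on:
log-normal per-transcript expression; footprint lengths 28–35 nt with a
known length→offset truth table; 3-nt periodicity with tunable frame
fidelity *f* (the observed A-site is jittered ±1 nt with probability
1 − f, split evenly — the jitter moves the A-site, not the read length, so
offset calibration stays clean); dwell-time multipliers per codon, at the
start codon (initiation peak, default 2×) and at stop codons (termination
pause, default 5×); readthrough of the NTC with probability π per
transcript; and termination/readthrough at each in-frame 3'UTR stop with a
separate probability. Ribosome positions are drawn from the flux-weighted
dwell distribution along each transcript, so downstream densities equal
the product of the readthrough probabilities crossed. Context-dependent
readthrough is expressed as multiplicative factors on π keyed by context
features (e.g. `"4:C": 2.0` doubles π when C follows the stop), which
makes planted effect sizes exact for recovery tests; an additive logistic
parameterization was considered and rejected because its effect on π is
only approximately multiplicative. Defaults emulate a G418-treated
library: π = 0.2, 3'TC readthrough 0.46, stop pause 5×, frame fidelity
0.95, human-like stop-codon usage (UAA 0.28, UAG 0.24, UGA 0.48), uniform
base composition. The 3'UTR can be constrained to place the first in-frame
3'TC at an exact distance with a guaranteed stop-free stretch after it,
which the NTC-vs-3'TC analyses use to control eligibility.

What the generator does **not** model: sequencing errors, UMI duplicates,
rRNA contamination, nucleotide-composition biases of ligation/digestion,
uneven coverage along the CDS beyond codon dwell times, drug-dependent
initiation changes, and alternative isoforms (one transcript per gene by
construction). Passing recovery tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to every
artifact of real libraries.

Transcript-space SAM (one reference per transcript) is the canonical
simulation output; a genome-embedding mode places the transcripts on a toy
chromosome with random strands and optional introns to exercise the
genome→transcript projection path.

## Problem sizes and numerical choices

Recovery analyses use desk-scale problem sizes chosen so that sampling
error is well below the effects being measured: 500 transcripts × 1M reads
for RRTS recovery (median within 15% of π), 300 × 3M × 2 replicates for
the NTC/3'TC contrast (ratio-of-counts estimates are biased upward at low
UTR coverage, so this analysis uses deeper coverage), 2,000 × 4M for
context-effect detection, and 200–300 × 0.5–0.8M elsewhere. Determinism:
every stage is a pure function of (inputs, seed); identical seeds give
byte-identical outputs, and TSVs are written with 6 significant digits,
'.' decimals and '\n' newlines so reruns diff clean.

Known limitations: the neighbor-overlap filter considers only the nearest
up/downstream same-strand gene, as specified, not all overlapping genes;
the pseudogene filter uses gene spans against UTR exon intervals;
genome-space read assignment takes the first matching transcript (unique
by construction after selection); and the one-sided position tests choose
their direction from the data, so their p-values are calibrated as
two-sided evidence split across the reported direction.
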