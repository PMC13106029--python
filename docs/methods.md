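# Methods

This note documents the models, conventions and design choices behind
`ckrna`, in the spirit of a methods supplement: what each stage assumes, which
parameters matter, what the synthetic-data generator does and does not
emulate, and where the design was genuinely open.

## Read preprocessing and subtractive classification

Raw reads are 3′-adapter-clipped by the first exact occurrence of the
adapter's first 8 nt; inserts outside 15–34 nt are rejected with a reason
(`no_adapter` / `too_short` / `too_long`). Qualities are parsed but never
interpreted — the pipeline is perfect-match based, so base-quality filtering
would not change any downstream call. Collapsed unique sequences are mapped
to both genomes with an exact-match index (15-mer seed dictionary plus
full-length verification, both strands; reverse-complement occurrences are
reported on the minus strand in forward coordinates, multi-mapping loci are
all retained). Origin classes partition each library:

* **host** — ≥1 perfect host locus;
* **fungal** — no host locus, ≥1 perfect fungal locus;
* **ambiguous** — perfect loci in both genomes (excluded from candidacy
  rather than assigned);
* **unassigned** — no perfect locus in either genome.

Perfect-match-only mapping is a deliberate modelling choice: the selection
logic is defined by exact presence/absence, which makes every downstream
claim testable against a brute-force scan. Mismatch-tolerant alignment is a
non-goal.

## Profiles, feature classes and RPM denominators

Size × 5′-nucleotide profiles are RPM matrices over lengths 15–34 and
5′ A/C/G/U. Each subset (host-mapped, fungal-mapped) is normalized on its
*own* read total, so a non-empty profile always sums to 1e6 RPM. The same
convention fixes the candidate filter: the >25 RPM rule is evaluated against
the per-library **fungal-mapped** total. The per-sample "fungal percentage"
reported alongside uses the post-preprocess library total as denominator.

Fungal reads are assigned a feature class by overlap (≥1 base) with the
annotation, with a fixed priority when loci or overlapping features disagree:
rRNA > tRNA > snRNA > snoRNA > repeat > mRNA > intergenic.

## Candidate selection

A candidate cross-kingdom sRNA must satisfy four flags simultaneously:
`size_ok` (21–24 nt inclusive), `rpm_ok_all_am` (RPM strictly greater than 25
in every AM library), `absent_in_mock` (raw count ≤ `max_mock_count`,
default 0, in every mock library) and `fungal_exclusive`. "Absent in mock" as
a raw zero count is the strict reading of presence/absence; `max_mock_count`
exposes the obvious relaxation. Sequences differing by a single nucleotide
are reported separately — collapsing near-duplicates would hide genuinely
distinct loci.

## Duplex model for target prediction

An sRNA is aligned antiparallel to a transcript site. The admissible
alignment space is deliberately small and exhaustively enumerable: ungapped
for equal lengths, exactly one internal 1-nt site bulge when the site is one
base longer, exactly one unpaired sRNA position when it is one base shorter.
Terminal site bulges are excluded because they are equivalent to the
neighbouring equal-length window. Ties break toward fewer gaps, then the
leftmost gap.

The score is the classic plant-target penalty sum — mismatch 1.0, G:U wobble
0.5, gap 2.0 — doubled at sRNA positions 2–12. The reporting cutoffs default
to score ≤ 4.5 (inclusive) and energy ratio ≥ 0.7; both are parameters.

The energy model is a simplified nearest-neighbor RNA/RNA scheme: stacking is
summed over consecutive paired positions with no intervening bulge, using an
embedded Turner/Xia-style table of Watson–Crick stack free energies
(kcal/mol, 37 °C), keyed by the sRNA dinucleotide. Stacks involving a G:U
pair contribute a flat −0.45 kcal/mol — deliberately weaker than the weakest
WC stack (−0.93) so that *any* single edit to a perfect duplex strictly
raises the energy, which makes the energy ratio exactly 1 iff the site is the
perfect complement and monotone non-increasing along edit series. The
initiation term defaults to 0, so energies are hybridization energies
relative to open strands and a site with no complementarity has ratio 0
(after clamping to [0, 1]). This is an intentionally transparent stand-in for
a full secondary-structure engine: ratios are meaningful relative quantities
with provable properties, not literal hybridization free energies, and
reproduction of third-party prediction tools is approximate by construction.

Transcriptome scanning evaluates every window of lengths len±1 of every
transcript per sRNA. Window minimum scores are computed with a vectorized
diagonal-sum formulation whose agreement with the per-window aligner is
itself under test; windows passing the score cutoff are re-aligned, the
energy ratio applied, and one best hit is kept per cluster of overlapping
windows (lowest score, then highest ratio, then leftmost).

**Cleavability.** AGO slices its target between the bases opposite sRNA
positions 10 and 11; the call requires Watson–Crick pairing at both positions
and no bulge between them (positions are configurable, e.g. 9–11). The
reported cleavage coordinate is the transcript base opposite position 10;
slicing occurs between it and the base 5′ of it.

**STTM design.** Each mimic is the sRNA's reverse complement with the 3-nt
bulge `CTA` inserted between the bases opposite positions 10/11; mimics are
joined by the conventional 48-nt low-structure spacer. The designer validates
its own output: the bulged duplex must be non-cleavable while the pairing
excluding the bulge is perfect (binding score 0). Scrambled controls are
seeded uniform permutations redrawn (bounded retries) until the score against
the cognate sRNA exceeds the cutoff; composition is preserved exactly, and
mononucleotide runs fail loudly since they cannot be decomplementarized.

## Quantification

Trouvelot indices use the standard class weights (intensity 1,2,3,4,5 →
1,5,30,70,95; arbuscule/vesicle abundance classes 1,2,3 → 10,50,100):
F% = colonized/N × 100; M% = intensity-weighted mean over all fragments;
m% = M·N/colonized; mA_i% = intensity-weighted mean over fragments of
abundance class i × 100/M; a% = (100·mA3 + 50·mA2 + 10·mA1)/100; A% = a·M/100
(v%, V% analogous). The indices are invariant under fragment reordering and
table duplication, and A% ≤ M% always. Group statistics (ANOVA/Tukey) are
left to standard statistical software; the module emits tidy per-sample
tables for them.

ΔΔCt fold change is the plain 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference
per sample and ΔΔCt the difference of condition means; no efficiency
correction. The reference gene is an explicit required input.

## The synthetic-data generator

The generator emulates the *design* of an AGO co-IP ckRNAi screen at desk
scale, with every random choice derived from a single seed (same seed ⇒
byte-identical FASTA/GFF3/FASTQ/manifest):

* **Genomes.** Single-contig host (200 kb) and fungus (100 kb) with random
  backbones. The fungal annotation carries rRNA/tRNA/snRNA/snoRNA/mRNA loci
  and a repeat complement: one transposon family of identical dispersed
  copies, diverged transposon units, simple inverted repeats, and the tandem
  family F1 present at exactly four dispersed copies. The host carries the
  CDS loci (default 60) and miRNA-like 21-nt loci used for background reads.
* **Planted ckRNAs.** Default 12, lengths 21–24, 5′-U with probability 0.8,
  base 10 constrained to G/U so that wobble target sites are constructible.
  Two of them are a single-substitution pair encoded inside the F1 unit —
  each therefore maps to exactly four repeat loci; the rest occupy one
  intergenic locus each. Planted sequences never occur in the host genome
  (checked by scan, redrawn on collision) and never contain the adapter seed.
* **Libraries.** Default 5 AM + 3 mock at ~1e6 reads. All libraries share a
  host background (Zipf-weighted miRNA species plus uniform genome fragments,
  including the minor 17-nt component of unknown origin). AM libraries add a
  fungal component whose per-library total F is drawn from 40,500–44,000
  reads: the planted ckRNAs (counts set from a target RPM of 50–500 of F),
  the decoys, a small set of single-library 21–24-nt species, a multi-copy
  off-size class, and count-1 filler species sampled from the annotation with
  a repeat-dominated class mixture and the configured 5′-U bias (the 5′ flag
  is drawn once per species and held through redraws, so window collisions
  cannot bias the realized fraction).
* **Why ~4% fungal reads.** With integer counts, the strict ">25 RPM" rule is
  only exercisable when one read is at most 25 RPM of the fungal-mapped
  total, i.e. F ≥ 40,000 (at F = 40,000 one read is exactly 25.0 RPM). The
  default therefore fixes F at ~41–44 k per 1e6-read library (~4.2%), which
  also guarantees that every count-1 background species fails the cutoff
  arithmetically. Real colonized-root libraries sit lower (sub-4%); the
  generator trades that fraction for an exactly testable decision boundary.
* **Decoys.** One per filter, each violating exactly its named filter while
  passing all others: a 19-nt species (size), a species at 1 read ≈ 24.7 RPM
  in one AM library (rpm), a species with a single mock read
  (present_in_mock), a species absent from both genomes
  (no_perfect_fungal_match), and a species planted in both genomes
  (matches_host). Background draws are rejected against planted/decoy
  sequences so no accidental read can rescue or break a planted claim.
* **Transcriptome.** For every planted sRNA, four host transcripts carry one
  designed site each: perfect (the exact reverse complement), sub-cutoff
  (edits outside the seed verified at build time to give 0 < score ≤ 4.5 and
  ratio ≥ 0.7), wobble_10_11 (single G:U opposite position 10), and
  non-target (scrambled until score > 4.5 against all same-length planted
  sRNAs). The manifest records, per site, which planted sRNAs are expected to
  report it — evaluated directly on the designed site with the duplex scorer,
  which makes the single-nucleotide pair's cross-hits part of the expected
  truth rather than noise.
* **On-disk studies.** `write_world` expands collapsed libraries to FASTQ
  with the adapter appended, shuffles read order, and adds a configurable
  fraction of adapter-less junk reads so preprocessing has something to
  reject; sample sheet, GFF3, CDS FASTA and the JSON manifest accompany them.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: sequencing errors are off by default (an optional
substitution rate exists; errored copies are count-1 variants that can never
rescue a failed filter), there is no PCR-duplicate or quality model, genomes
are single-contig toys without true chromatin-scale repeat complexity, and
depth differences between libraries are not modelled beyond the sampled
totals. Recovery being exact on simulations demonstrates the *logic* of the
pipeline, not the error tolerance of perfect-match mapping on noisy reads.

## Problem sizes and determinism

The default study (5 AM + 3 mock, ~1e6 reads, ~27 k unique species per AM
library) simulates and analyses in a few seconds per seed; the test suite
sweeps 20 seeds for recovery and the acceptance script re-runs five. Unit
tests use the same generator with a reduced host background (the fungal load
stays at full scale since the selection arithmetic depends on it). All
randomness flows from numpy `SeedSequence` children of the study seed;
outputs are byte-stable across reruns, and the end-to-end report carries
SHA-256 checksums of every table to make that checkable.

## Known limitations

* Perfect-match classification understates fungal read counts in the presence
  of sequencing errors or strain-level variants.
* The energy ratio is a relative, model-internal quantity; absolute duplex
  energies from structure-aware engines will differ, so cutoff-boundary calls
  near 0.7 should not be over-interpreted on real data.
* Translational-inhibition targets (bound but never sliced, no cleavage
  signature) are out of scope by design.
* The mapper's 15-mer seed limits queries to ≥15 nt, matching the read-length
  window, and genomes are held in memory (fine for fungal-scale references;
  not engineered for multi-gigabase hosts).
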