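# Methods

## The assay being modelled

`amplicall` models a targeted amplicon deep-sequencing protocol for the
*EGFR* tyrosine-kinase domain: one PCR amplicon per exon 18–21 (184, 182,
208 and 196 bp), each amplification primer extended with a 10-nt Multiple
IDentifier (MID) tag and a short junction, pooled runs of 100–120 targets
(25–30 patients × 4 exons) and several hundred reads per target.  A unique
(forward MID, reverse MID) pair identifies each sample; both sequencing
strands are read.  Mutation calling is count-based: base qualities are
never consulted.

## Reference bundle

The amplicon references are synthetic stand-ins, generated once by
`refdata.build_reference_bundle()` and shipped as FASTA + sidecar TSV.
Each reference carries the published primer pair at its ends and the
published amplicon length; inside, a modelled codon window (18: 688–728,
19: 729–761, 20: 770–810, 21: 825–865) encodes the canonical EGFR residue
at every landmark the panel interrogates, using the canonical codon
wherever coordinate arithmetic depends on it (the exon 19 block
K745–D761 is the true gene sequence, so deletion-placement ambiguity
matches the real locus).  Filler codons and pads are synthetic and chosen
so that the only homopolymer runs of length ≥ 4 inside any insert are the
deliberately placed four-adenine runs (one per amplicon) that give
pyrosequencing-style noise a realistic landing site.

Coordinates are standard CDS c.-numbers, codon *N* at c.(3N−2)…3N, signal
peptide included (L858R = c.2573T>G, T790M = c.2369C>T).  Some older EGFR
literature numbers the exon 20 Q787Q polymorphism "2470"; that legacy
transcript numbering is offset +109 from the standard c.2361 and is
recorded as `LEGACY_TRANSCRIPT_OFFSET`.  Internally reference offsets are
0-based half-open; the c. convention appears only at the surface.

## Read simulator

The simulator is the package's model of the study conditions, not a
tuning knob.  Per (sample, exon) target it emits exactly
`depth_per_target` full-length, primer-to-primer reads (defaults: 700
reads/target, the platform's nominal depth at 120 amplicons per run).
Each read is independently

1. assigned to a clone: clone *k* (a haplotype group of spiked variants)
   with probability equal to its allele fraction, wild type otherwise —
   supporting-read counts are therefore Binomial(depth, fraction);
2. given a strand (forward with probability `strand_balance`, default
   0.5 — the protocol reads both strands and states no bias);
3. corrupted by homopolymer noise: every reference homopolymer run of
   length ≥ 4 inside the insert suffers a one-base insertion or deletion
   with probability `homopolymer_indel_rate` (default 5 × 10⁻³ per run per
   read, a realistic order for pyrosequencing chemistry, whose dominant
   error mode this is);
4. corrupted by uniform substitutions at `substitution_error_rate`
   (default 5 × 10⁻⁴ per base, a realistic residual miscall rate).

Allele fractions come either from an explicit `allele_fraction` or from
tumor purity via `purity × copies / ploidy` (heterozygous dysomic default:
purity/2).  Dilution "1:N" means one part homozygous-variant DNA in N
parts total, i.e. allele fraction 1/N — 1:100 is the assay's 1 % point.
MIDs, junction spacer and primers are emitted error-free: barcode and
primer errors would only move reads into the unassigned pile, and the
demultiplexer's exact-matching contract (below) is the property under
test.  Qualities are constant.  Identical configurations (including the
seed) produce byte-identical FASTQ output.

What the generator does **not** model: PCR jackpotting/duplicates,
read-length truncation, flowgram-level signals, quality-score error
profiles, and FFPE deamination (C→T/G→A) artifacts.  Passing tests
therefore demonstrate the pipeline's behaviour under idealised binomial
sampling with isolated indel/substitution noise, not performance on
degraded clinical libraries.

## Demultiplexing

MID matching is exact on both tags (no error tolerance): the published
scheme's guarantee that a MID couple identifies a sample univocally is
preserved by construction, and a single matching MID is never sufficient.
Orientation is decided by which known tag opens the read; the stored
insert is trimmed of MID, spacer and primers and kept in read orientation.
The grid designer minimises the number of tagged primers, choosing the
smallest f + r with f × r ≥ n (ties broken toward the most balanced pair
with f ≤ r) and assigning pairs row-major; 30 samples yield 5 × 6.
Corrupt FASTQ records are counted and reported, never fatal.

## Alignment and variant extraction

Reads are aligned globally to their amplicon insert under fixed affine
scores (match +1, mismatch −2, gap open −4, gap extend −1); alignments
below 70 % identity are excluded from tallies.  Reads span the full
insert by construction, so global alignment is exact; results are cached
per distinct insert sequence, which makes depth-2,000 runs cheap (a bin
is dominated by a handful of distinct sequences).

Edit normalisation is deterministic:

* edits separated by ≤ 2 reference bases merge into one
  deletion–insertion event;
* additionally, a length-changing event fuses with a neighbour when the
  fused, parsimony-trimmed event is no longer than the parts — affine-gap
  alignment of a single biological delins can leave accidental matching
  columns between the gap and the substituted bases (e.g.
  `del L747-A750 insP` aligns as a 9-bp gap, three matches and two
  mismatches), and this minimum-description rule recovers the single
  canonical event while never joining genuinely distant edits;
* pure indels are shifted to their leftmost alignment-equivalent
  placement (verified against a brute-force enumeration oracle);
* an edit is flagged `in_homopolymer` when its reference span, expanded
  one base either side, touches a reference run of ≥ 4 identical bases.

Protein names are computed by re-translating the edited coding sequence
and trimming the residue-level diff, giving the conventional reporting
style (`L858R`, `del E746-A750`, `del L747-A750 insP`, `Q787Q`);
frame-breaking events are marked `fs`.

## Call criteria

A tally (strand-split supporting counts against bin depth) is called iff

1. support ≥ `min_reads` (default 10),
2. the mutated-read percentage, rounded to
   `fraction_rounding_decimals` decimals (default 0, i.e. integer
   percent), is ≥ 100 × `min_fraction` (default 1 %),
3. at least one supporting read on each strand
   (`require_both_strands`, no stronger balance requirement), and
4. the variant is not an indel touching a homopolymer run ≥ 4
   (substitutions near runs remain callable — the excluded artifact is the
   pyrosequencing length error, which is an indel).

All failing conditions are recorded as filter reasons.  The integer-percent
default for (2) makes the 10-read rule the binding criterion at routine
depths, which is the assay's own operating logic: a 23/2,359 = 0.975 %
observation counts as 1 % and is called, 7/750 fails only the read-count
rule, and the 1:100 dilution is then consistently callable at ~2,000+
reads while 1:1000 (needing 0.5 % *and* 10 reads) never is.  With
one-decimal rounding the fraction rule would bind exactly at the nominal
1 % fraction and no depth could call a true 1 % variant consistently;
the parameter remains configurable for stricter use.

One read contributes at most once per variant.  Co-occurrence reports
count shared supporting reads per called pair (non-zero ⇒ in haplotype)
and flag pairs whose percentages agree within ±2 points as compatible
with a single neoplastic clone — the tolerance mirrors the assay's
observed mean run-to-run fraction variation (~2.6 points).

## Sensitivity calculators

`min_depth` is expectation arithmetic, `ceil(min_count/fraction)` — 10
reads at 1 % means 1,000 total, at 0.1 % means 10,000 — while
`detection_probability` gives the exact binomial upper tail for the
probabilistic view.  The dilution-series runner simulates the exon 20
synonymous polymorphism (G>A at the third base of codon 787) at fractions
1/N through the full pipeline and reports the smallest fraction called in
≥ 95 % of replicates as the analytical sensitivity ("consistently
detected" is not otherwise quantified; 95 % is this package's choice).
Defaults follow the wet protocol (depth 700, two replicates); the
acceptance script uses depth 2,400 × 24 replicates, sized so the whole
experiment runs in seconds while leaving binomial noise visible.

`dna_to_cell_equivalents` reports unrounded values (2 ng = 285.7 diploid
cell equivalents at 7 pg/cell; at a 1 % fraction that is ~2.9 mutated
cells if 1 % of cells are heterozygous).  Published narrative rounds this
scenario to "~4 mutated cells in ~200"; the two are not exactly
reconcilable from the 7 pg/cell arithmetic, so the module reports the
computation and leaves the rounding to the reader.

## Cohort fixture and reporting

The packaged cohort table holds one row per deep-sequencing mutation of
the 80-case validation series: 21 rows transcribe the published
discrepant-case table verbatim (including its printed exon labels and the
"del E746-A751" name, kept as strings), and 10 rows are constructed
concordant cases — labelled synthetic in file and docstring — carrying the
series' nine remaining exon 19 deletions and one L858R at fractions above
the Sanger floor.  `compare_callsets` recomputes every aggregate from
these rows (24/31 mutated cases/mutations by deep sequencing, 14/15 by
Sanger, 16 sequencing-only, the 22 vs 9 split across the 40 %-tumor-cell
strata, with equality at exactly 40 % assigned to the upper stratum) and
validates each Sanger-detected row against the detectability model.
Sanger status is an input transcribed per mutation, never re-derived.
`del L747-A750 insP` is classified as a delins, not an exon 19 deletion;
the published per-class totals are internally inconsistent at that level
of detail and are not reproduced class-by-class.

## Numerical and degenerate-input choices

* `min_depth` guards the float ceiling against exact-multiple artifacts
  by integer adjustment.
* Zero-depth bins cannot be called (error); empty bins yield empty call
  lists.
* Tie-breaks are all deterministic: leftmost gap placement, row-major
  grid assignment, lexicographic tally ordering, balanced-grid
  preference with f ≤ r.
* Seeds: one integer seed drives each simulation; experiment runners
  spawn per-replicate child seeds (kept below 2³¹) from it.

## Known limitations

Exact MID/primer matching discards, rather than rescues, barcode-error
reads; the aligner assumes full-length inserts (no chimera or truncation
handling); protein naming assumes single-amplicon, in-frame context and
does not implement full HGVS edge cases; the cohort module reproduces
published aggregates from a fixture and is not a general cohort
statistics engine.
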