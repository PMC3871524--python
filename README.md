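# amplicall

Dual-barcode amplicon deep-sequencing pipeline for *EGFR* exon 18–21
hotspot mutation calling in small lung-cancer specimens.

Selection of lung-cancer patients for tyrosine-kinase-inhibitor (TKI)
therapy requires detecting specific *EGFR* mutations — most importantly
exon 19 deletions and L858R (response) and T790M/R831H (resistance) — in
biopsies and cytology smears whose tumor-cell content is often far below
the ~20 % mutated-allele floor of dideoxy (Sanger) sequencing.  Targeted
amplicon deep sequencing solves this by reading each of the four
kinase-domain exons hundreds of times per sample and calling mutations
from read counts.  `amplicall` implements that workflow as a reusable
library and command-line tool for assay designers and molecular-pathology
analysts:

* **Simulation** of MID-tagged (10-nt Multiple IDentifier) forward/reverse
  amplicon reads at configurable depth, with spiked variants (dilution
  series or tumor-purity mixing) and pyrosequencing-style homopolymer
  indel noise.
* **Grid design & demultiplexing** — the minimal f × r combinatorial MID
  grid (5 forward × 6 reverse tags cover 30 samples) and exact dual-MID
  read binning with strand orientation.
* **Alignment & variant extraction** — global affine alignment of each
  read to its amplicon reference, deterministic left-alignment of indels,
  merging of adjacent edits into single deletion–insertion events, and
  HGVS-style c./protein naming (`c.2236_2250del` → `del E746-A750`).
* **Calling** under count-based criteria: a variant is a mutation iff it is
  seen in ≥ 10 reads *and* ≥ 1 % of the target's reads (percentage compared
  at integer-percent precision), on **both** strands, and — for indels —
  outside reference homopolymer runs of length ≥ 4 (pyrosequencing length
  artifacts).  Calls carry mutated-read percentages, filter reasons,
  TKI-role annotation and pairwise haplotype/co-occurrence reports.
* **Assay-design calculators** — minimum depth for a target allele
  fraction under the k-read rule (`ceil(k/f)`: 1 % needs 1,000 reads,
  0.1 % needs 10,000), exact binomial detection probabilities, DNA-mass →
  diploid-cell-equivalent arithmetic (7 pg/cell), the Sanger
  detectability model (20 % alleles ≈ 40 % tumor cells for a heterozygous
  mutation at a dysomic locus), and a full dilution-series experiment
  measuring the pipeline's analytical sensitivity.
* **Cohort reporting** — tumor-cellularity estimation, sequencing-run
  batching, and comparison of deep-sequencing call sets against Sanger
  results on the packaged validation-cohort fixture.

The bundled amplicon references are **synthetic stand-ins** (documented in
`amplicall.refdata`): published primer pairs and amplicon lengths with
canonical EGFR codons at every hotspot position, synthetic filler
elsewhere.

## Worked example

Simulate a run with two problem specimens — a bone metastasis with 10 %
tumor cells carrying heterozygous L858R, and a specimen with an exon 19
deletion at a 2 % allele fraction — then call mutations:

```bash
cat > run.cfg <<EOF
depth_per_target = 700
seed = 42
sample CASE80 purity=0.10
variant CASE80 exon=21 kind=snv cds=2573 alt=G
sample CASE76
variant CASE76 exon=19 kind=deletion cds=2236-2250 fraction=0.02
EOF
amplicall simulate --config run.cfg --out-dir sim
amplicall call --reads sim/reads.fastq --grid sim/grid.tsv --out-dir calls
```

which prints `2 mutation call(s) -> calls/calls.vcf`; the passing rows of
`calls/calls.tsv` are

```
sample   exon  cds_change      protein_change  %reads  fwd  rev  depth  called  filters  tki_prediction
CASE76   19    c.2236_2250del  del E746-A750   2.00    6    8    700    true    PASS     response
CASE80   21    c.2573T>G       L858R           6.00    18   24   700    true    PASS     response
```

The heterozygous mutation in a 10 %-pure tumor appears in ~5 % of reads
(here 6.00 %) — far below Sanger's 20 % floor yet confidently called from
42 reads on both strands; the 2 % deletion is called from 14 reads.
Homopolymer-touching indels and single-strand artifacts appear in the same
table with their filter reasons instead of `PASS`.

The depth calculator reproduces the assay's operating point
(`amplicall lod --fractions 0.01,0.001 --depth 2400`):

```
allele_fraction  min_depth  detection_probability
0.01             1000       0.9996
0.001            10000      0.0002
```

i.e. at ~2,400 reads per amplicon a 1 % variant is practically always
detected with ≥ 10 reads while 0.1 % is essentially never, which is why the
protocol's analytical sensitivity is 1 %.

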