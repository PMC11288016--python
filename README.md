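# commprime

Taxon-specific PCR primer design for **defined microbial communities**.

Given one coding-sequence (CDS) FASTA per genome, `commprime` finds genes
that are unique to a single community member (microbe-specific markers) or
shared by a chosen group of members and absent everywhere else
(group-specific markers), and designs PCR primer pairs on those genes under
thermodynamic and product-size constraints. It also provides the
copy-number arithmetic used to assemble equal-copy gDNA pools and to turn
absolute ddPCR counts into relative abundances.

Intended users: microbiome researchers working with gnotobiotic or other
defined communities who need member- or taxon-selective PCR/qPCR/ddPCR
assays without hand-curating marker genes.

## Method

1. **All-vs-all homology screen.** Every CDS is locally aligned against every
   other CDS (exact 13-mer seeding, banded Smith–Waterman extension, match
   +2 / mismatch −3 / gap −5). Hits below a fraction identity threshold
   (default 0.3), alignment-length floor, or coverage rule are discarded; an
   MMseqs2/BLAST `outfmt 6` table from an external aligner can be swapped in.
2. **Marker classification.** A gene whose only surviving alignment is its
   self-hit is *unique*; a gene whose cross hits stay inside its own genome
   is *multi-copy* (excluded — it would amplify at several loci); in group
   mode a gene is *group-shared* iff it hits every other group member and
   nothing outside the group. Non-target genomes contribute exclusion
   evidence only.
3. **Primer design.** Candidate genes are walked in decreasing length.
   Every admissible forward/reverse window pair is scored with

   `penalty = w_tm·|Tm−Tm_opt| + w_size·|len−len_opt| + w_gc·|GC−GC_opt|/10`
   per primer, plus `w_pair·|ΔTm|` per pair,

   where Tm is the unified nearest-neighbor melting temperature
   (SantaLucia 1998 parameters, Owczarzy salt correction; 50 mM monovalent,
   1.5 mM Mg²⁺, 0.6 mM dNTPs, 250 nM oligo). Hard filters: Tm and GC
   windows, poly-X runs, 3′ GC clamp, self-dimer / hairpin / cross-dimer
   scores. Defaults: 125–175 bp amplicons, Tm 62 ± 3 °C, pair ΔTm ≤ 1.5 °C.
4. **Quantification.** `copies/µL = X·6.0221×10²³ / (N·660 g/mol) · 10⁻⁹`
   for X ng/µL of an N-bp genome; equal-copy pool volumes ∝ 1/(copies/µL);
   relative abundance = member copies / total copies (members without
   usable primers can be dropped from both numerator and denominator).

A deterministic synthetic-community generator (`commprime synth`) plants
unique, group-shared, duplicated, and homolog-at-identity-x genes with a
truth manifest, so the whole pipeline is testable without downloads.

## Worked example

```bash
# 1. make a 3-genome community: 2 private genes + 1 family shared by all
commprime synth community/ --seed 5 --genomes 3 --private 2 --shared 1

# 2. align every CDS against every other CDS
commprime align community/ -o run/
# stderr: genome01: 3 genes ... hits: 15 total (9 self, 6 cross)

# 3. design microbe-specific primers
commprime primers run/alignment_hits.tsv community/ -o run/
```

`run/unique_gene_summary.tsv` then shows two unique genes per member
(the planted family copies are correctly rejected):

```
genome_id   n_unique  n_total  fraction_unique
genome01    2         3        0.6667
genome02    2         3        0.6667
genome03    2         3        0.6667
```

and `run/UniquePrimerTable.tsv` holds up to five ranked pairs per member,
e.g. (abridged):

```
label     gene_id                  gene_len  pair_penalty  amplicon_bp  fwd_seq               rev_seq
genome01  genome01|genome01_00001  722       1.3255        140          AACTGCAAGAATGGCCTCCA  ATGAGGGGGATAAGAGGCGA
```

Each row also carries per-primer length, GC %, and Tm; every number in the
table recomputes exactly from the printed sequences. Group mode
(`--mode group --group genome01 --group genome02 ...`) writes
`GroupPrimerTable.tsv` with a per-pair conservation flag telling whether
both primer sites occur verbatim in every group member's gene copy.

For pooling/ddPCR arithmetic:

```bash
commprime quant samples.tsv --total-volume 30 -o quant_table.tsv
# 1 ng/µL of a 1 Mbp genome → 912439.4 copies/µL
```

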