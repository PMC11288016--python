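# Methods

This note documents the models, algorithms, parameters, and design choices
behind `commprime`, and what its synthetic-data tests do and do not show
about real communities.

## Input model

Each community member is represented by its coding sequences (CDSs) in one
multi-FASTA file. Filenames must contain `cds` and end in `.fna`; the text
before the first `_cds` is the genome identifier (e.g.
`B_theta_VPI5482_cds.fna` → `B_theta_VPI5482`). Headers may follow the
Prokka, RAST, or NCBI dialects; detection is: leading `lcl|` or a
`[locus_tag=` attribute → ncbi; leading `fig|` together with a `_CDS_`
substring → rast; otherwise prokka. The dialect is recorded as provenance
only. Gene identifiers are `<genome_id>|<first header token>`, which keeps
the original token recoverable and makes identifiers community-unique;
duplicate tokens within a file are an error rather than silently renamed.

Sequences are uppercased; IUPAC ambiguity codes other than N are collapsed
to N (the internal alphabet is {A,C,G,T,N}); anything else is a parse
error. Genes with >5 % N still participate in alignment (an N matches
nothing, so it only weakens hits) but are excluded from primer design,
because ambiguous bases make nearest-neighbor Tm undefined. All
coordinates are 0-based half-open in memory; tabular files use the 1-based
inclusive convention of BLAST/MMseqs2.

## Homology screen

The screen is classic seed-and-extend:

* **Seeding.** Exact k-mer index, k = 13, both strands. Any gene pair
  sharing one exact 13-mer is a candidate. This is exact, not heuristic:
  a pair admitting an alignment that contains a 13-bp identical stretch is
  guaranteed to be nominated.
* **Extension.** Banded Smith–Waterman over the diagonal window spanned by
  the shared k-mers ± 32, linear gap costs (match +2, mismatch −3,
  gap −5). Ties prefer the diagonal move and the row-major-first best
  cell, so results are fully deterministic. A full-matrix Smith–Waterman
  with the same scoring is exposed separately (`local_align`) and serves
  as the exactness oracle in the test suite: on seeded homologous pairs the
  banded path reproduces the full optimum's score and identity.
* **Identity** is matches / alignment columns (gaps count as columns);
  query/target coverage are aligned span over sequence length.
* **Filters.** Minimum fraction identity (default 0.3), minimum alignment
  length (default 0), minimum coverage (default 0) under a coverage mode
  (`both` = min(qcov,tcov), `either` = max, or one-sided). Self-hits are
  never filtered. Raising the identity threshold can only remove hits, so
  unique-gene counts are non-decreasing in it — the knob users turn when a
  community is too closely related to yield unique genes at defaults.
* **Reporting floor.** The engine does not report alignments scoring below
  `min_score` (default 50 ≈ 25 matched bases). With no length floor, a
  single chance 13-mer shared by two unrelated genes would otherwise
  surface as a one-seed micro-hit with identity ≈ 1.0 and misclassify both
  genes as non-unique; database search engines suppress such hits via
  prefilter and E-value statistics, and `min_score` plays that role here.
  It is a reporting property of the engine, deliberately separate from the
  user-facing stringency thresholds.
* With the linear-gap scoring above, local alignment only sustains hits at
  roughly ≥ 60 % identity over long stretches; this is well matched to the
  marker-screening use case, where the decision boundary is "essentially
  the same gene vs. not", not remote homology.

An external tabular hit file (MMseqs2/BLAST `outfmt 6`, 12 or 14 columns)
can replace the internal engine; identity is auto-detected as 0–1 or 0–100
scale (any value > 1.5 ⇒ percent), and coverage is taken from columns
13–14 or recomputed from coordinates.

## Marker classification

Unique mode: a gene is **unique** iff its only surviving hit is its
self-hit. Cross hits confined to the gene's own genome make it
**multi_copy** — a duplicated gene is excluded because it would amplify at
more than one locus and bias quantification. Any hit into another genome
makes it **non_unique**; when both kinds of evidence exist, non_unique wins
(cross-reactivity is the stronger exclusion). Otherwise-unique genes with
>5 % N become **excluded_ambiguous**. Per-genome summaries are ordered by
descending unique count (the bar-plot ordering); a genome subsumed by a
near-identical neighbour legitimately reports zero unique genes, and
downstream design warns instead of failing.

Group mode: a gene in a group genome is **group_shared** iff it has ≥1
surviving hit into every *other* group member and none outside the group
(non-target genomes included). Reciprocity is not chased
(partner-of-partner hits are not followed); the per-gene outward check is
deterministic and sufficient at marker-level stringency. Everything else
is excluded with a recorded reason (missing members vs. outside hits).

Candidates are ranked by decreasing gene length (ties: lexicographic id) —
longer genes offer more admissible primer windows.

## Primer design

The search enumerates every forward/reverse window pair satisfying the
geometry (amplicon within the product range, primers disjoint), then
applies staged hard filters and an additive penalty. Defaults:

| parameter | default | note |
|---|---|---|
| product size | 125–175 bp | reference run setting |
| primer length | 18 / 20 / 27 (min/opt/max) | |
| Tm | 59 / 62 / 65 °C | min/max = opt ∓ 3 |
| pair ΔTm | ≤ 1.5 °C | |
| GC | 30 / 50 / 70 % | |
| poly-X | ≤ 5 | |
| GC clamp | ≥1 G/C in last two 3′ bases | standard practice |
| self-any / self-end / hairpin | ≤ 8 / 3 / 8 | ungapped ±1 scores |
| cross-dimer (pair) | ≤ 8 / 3 | same scorer, fwd vs rev |
| pairs returned | 5 per genome or group | raise for primer cocktails |

Penalties: `w_tm·|Tm−62| + w_size·|len−20| + w_gc·|GC−50|/10` per primer,
plus `w_pair·|ΔTm|`; all weights default 1. This additive form is
intentionally simple and fully disclosed so every table value recomputes
exactly from the printed sequences; `primer3-py` can be used as an
external cross-check where installed, but is not a dependency. Pairs are
ranked by ascending penalty with deterministic tie-breaks (fwd_start,
rev_end); identical sequence pairs are deduplicated; overlapping
alternative pairs are allowed (useful for multi-pair cocktails on one
gene). The staged search (cheap GC/clamp/Tm checks before the O(len²)
complementarity scores, windows memoised by sequence) is proven equivalent
to exhaustive enumeration + scoring in the test suite.

Group mode designs on the group member whose copy is longest and reports,
per pair, whether both primer binding sites occur verbatim in every other
member's copy (`exact_in_all_targets` vs `mismatched`). Conservation is
reported, not enforced: divergent copies are handled by designing more
pairs rather than silently dropping candidates.

## Melting temperature

Unified nearest-neighbor model (SantaLucia 1998 / Allawi & SantaLucia
1997): ΔH°/ΔS° summed over dinucleotide stacks with per-terminus
initiation terms (A·T: ΔH 2.3 kcal/mol, ΔS 4.1 cal/mol·K; G·C: 0.1,
−2.8), `Tm = ΔH·1000/(ΔS + R·ln(C/4)) − 273.15` at 1 M Na⁺ with C the
total oligo concentration (excess-primer convention), then corrected on
the 1/Tm scale with Owczarzy's monovalent (2004) and divalent (2008)
equations, including the Mg²⁺/dNTP chelation quadratic (Ka = 3·10⁴ M⁻¹).
Default conditions: 50 mM monovalent, 1.5 mM Mg²⁺, 0.6 mM dNTPs, 250 nM
oligo — common PCR buffer values, exposed as `ThermoConditions`. The test
suite cross-checks against Biopython's independent implementation of the
same published tables (agreement well under 0.5 °C; in practice exact).

Dimer/hairpin scores are ungapped antiparallel alignment scores (match +1,
mismatch −1, floored at 0) over all offsets; the `end` variant anchors the
window at the oligo's 3′ terminus, and the hairpin variant folds a
sequence on itself with a minimum loop of 3. These are transparent,
exhaustively-checkable analogues of the classic SELF_ANY/SELF_END filters,
not thermodynamic folding energies.

## Quantification arithmetic

`copies/µL = X · 6.0221×10²³ / (N · 660 g/mol) · 10⁻⁹` for X ng/µL of an
N-bp genome. The 10⁻⁹ is the ng→g conversion: (X·10⁻⁹ g/µL) / (N·660
g/mol) mol/µL × Avogadro. Both constants are treated as exact as written
(1 ng/µL, 1 Mbp → 912 439.4 copies/µL). Equal-copy pooling assigns
volumes ∝ 1/(copies/µL), normalised to the requested total, so each
member contributes identical copies. Relative abundance divides each
member's copies/µL by the sum over retained members; a `drop` set supports
communities where some member has no usable primers (e.g. normalising
over 9 of 10 members). Droplet-level Poisson statistics of ddPCR are out
of scope — inputs are already copies/µL.

## Synthetic communities

The generator emulates the *structure* of a defined community's CDS files:
per-genome private genes, shared homolog families planted at a controlled
identity (the first listed member carries the family base sequence, other
members carry substitution-only mutants with exactly
`round(len·(1−identity))` mismatches), exact within-genome duplicates, and
unrelated background genes. Gene lengths are uniform in 400–800 bp at
GC 0.5; headers are emitted in any of the three dialects. Two fidelity
guarantees make planted truth exact: substitution-only mutation (planted
identity is exact, alignments are full-length), and 13-mer disjointness
between unrelated lineages via rejection sampling (chance micro-homologies
between random genes are common enough at community scale to otherwise
contaminate a precision/recall-of-1.0 claim). A fixed seed yields
byte-identical FASTA and manifest output.

What this does **not** emulate: codon usage and real GC structure,
indels and rearrangements between homologs, partial-coverage homology
(domain sharing), operons, or assembly artifacts such as collapsed
repeats. Passing planted-truth tests therefore demonstrates the
correctness of the classification logic under its own definitions, not
recovery of published unique-gene counts for real communities — those
depend on the actual genome downloads and the external aligner's hit set,
and can be reproduced through the external-backend adapter.

## Problem sizes and numerics

Test and acceptance runs use a 10-genome community (70 genes, 5 private +
2 all-shared per genome at 0.95 identity), a 4-genome community with one
fully subsumed member, 200 seeded aligner-oracle pairs ≤ 500 bp, and
1 000 random 18–27-mers for the Tm cross-check — sizes chosen so the
full suite exercises every code path in under a minute on one core while
keeping every check exhaustive rather than sampled. Floating-point
comparisons in tables use fixed rounding (Tm/GC to 2 decimals, penalties
to 4) so determinism is byte-level. No stage of the pipeline uses
randomness; all stochasticity lives in the generator and is seed-derived.

## Known limitations

* The internal aligner targets high-identity marker screening; it will not
  find remote homologs an amino-acid-space search would (use the external
  adapter for that).
* Group-mode membership is evaluated per gene without requiring reciprocal
  hits; pathological asymmetric hit sets could admit a gene whose partners
  would not reciprocate.
* Uniqueness is gene-level: primers are not re-screened against whole
  genomes (intergenic regions are not part of the input model).
* The penalty function is a documented simplification of Primer3's richer
  weighting; rankings can differ from Primer3's even where both accept the
  same pairs.
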