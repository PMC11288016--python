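"""Many-against-many local alignment of community CDSs.

The engine mirrors the classic seed-and-extend design: exact k-mer sharing
(k=13 by default, either strand) nominates candidate gene pairs, and each
candidate is aligned with a banded Smith–Waterman restricted to a window
around the seed diagonals (linear gaps, match +2 / mismatch −3 / gap −5).
:func:`local_align` exposes the full-matrix Smith–Waterman as the exact
reference; on any pair the seeded path is checked against it in the test
suite.

Hits are reported in an MMseqs2/BLAST outfmt-6 compatible 14-column table
(the canonical 12 columns plus query and target coverage).  Coordinates are
0-based half-open in memory and 1-based inclusive in files.  A reporting
floor (``min_score``, default 50) suppresses micro-alignments around a single
chance k-mer match, playing the role the prefilter and E-value play in
database search engines; it is deliberately separate from the user-facing
stringency thresholds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from . import _kernels
from ._seq import encode, kmers, reverse_complement
from .cds_io import CommunityCatalog
from .errors import ConfigurationError, HitParseError, HitReferenceError

DEFAULT_K = 13
DEFAULT_BAND = 32
DEFAULT_MIN_SCORE = 50

HIT_COLUMNS = (
    "query",
    "target",
    "fident",
    "alnlen",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "tstart",
    "tend",
    "evalue",
    "bits",
    "qcov",
    "tcov",
)


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap: int = -5


@dataclass(frozen=True)
class StringencyParams:
    """User-facing hit filters; defaults follow the pipeline's conventions
    (minimum fraction identity 0.3, no length or coverage floor)."""

    min_identity: float = 0.3
    min_aln_len: int = 0
    min_coverage: float = 0.0
    cov_mode: str = "both"  # both | either | query | target

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_identity <= 1.0):
            raise ConfigurationError("min_identity must be in [0, 1]")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ConfigurationError("min_coverage must be in [0, 1]")
        if self.cov_mode not in ("both", "either", "query", "target"):
            raise ConfigurationError(f"unknown cov_mode {self.cov_mode!r}")


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between two community genes."""

    query_id: str
    target_id: str
    fident: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int  # 0-based half-open on query
    qend: int
    tstart: int  # 0-based half-open on target plus strand
    tend: int
    score: int
    strand: str  # '+' or '-'
    qcov: float
    tcov: float
    evalue: Optional[float] = None

    @property
    def is_self(self) -> bool:
        return self.query_id == self.target_id

    def mirrored(self) -> "AlignmentHit":
        return replace(
            self,
            query_id=self.target_id,
            target_id=self.query_id,
            qstart=self.tstart,
            qend=self.tend,
            tstart=self.qstart,
            tend=self.qend,
            qcov=self.tcov,
            tcov=self.qcov,
        )


@dataclass(frozen=True)
class AlignmentStats:
    """Raw traceback summary of one local alignment."""

    score: int
    matches: int
    columns: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    tstart: int
    tend: int

    @property
    def fident(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _trace(P, bi, bj, a, b, banded: bool, dlo: int = 0) -> AlignmentStats:
    """Traceback with match counting.  For the banded kernel, the second
    index is a band offset and the true column is ``i + dlo + t``."""
    if banded:
        i, j = bi, bi + dlo + bj
        t = bj
    else:
        i, j = bi, bj
    matches = columns = mismatches = gapopens = 0
    prev = 0
    score = None
    while i > 0 and j > 0:
        p = P[i, t] if banded else P[i, j]
        if p == 0:
            break
        columns += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            if prev != 2:
                gapopens += 1
            i -= 1
            if banded:
                t += 1
        else:
            if prev != 3:
                gapopens += 1
            j -= 1
            if banded:
                t -= 1
        prev = p
    end_i = bi
    end_j = (bi + dlo + bj) if banded else bj
    return AlignmentStats(0, matches, columns, mismatches, gapopens, i, end_i, j, end_j)


def smith_waterman(a: str, b: str, scoring: Scoring = Scoring()) -> AlignmentStats:
    """Exact full-matrix Smith–Waterman local alignment of two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = encode(a), encode(b)
    score, bi, bj, P = _kernels.sw_full(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap
    )
    if score <= 0:
        return AlignmentStats(0, 0, 0, 0, 0, 0, 0, 0, 0)
    st = _trace(P, bi, bj, ea, eb, banded=False)
    return replace(st, score=int(score))


def seeded_align(
    a: str,
    b: str,
    scoring: Scoring = Scoring(),
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
) -> Optional[AlignmentStats]:
    """Seed-and-extend local alignment: shared k-mers define a diagonal
    window (± ``band``) in which a banded Smith–Waterman is run.  Returns
    None when the pair shares no exact k-mer."""
    index: dict[str, list[int]] = {}
    for i, w in kmers(a, k):
        index.setdefault(w, []).append(i)
    diags: list[int] = []
    for j, w in kmers(b, k):
        for i in index.get(w, ()):
            diags.append(j - i)
    if not diags:
        return None
    m, n = len(a), len(b)
    dlo = max(min(diags) - band, -(m - 1))
    dhi = min(max(diags) + band, n - 1)
    ea, eb = encode(a), encode(b)
    if dhi - dlo + 1 >= m + n - 1:  # band covers the whole matrix
        return smith_waterman(a, b, scoring)
    score, bi, bt, P = _kernels.sw_banded(
        ea, eb, dlo, dhi, scoring.match, scoring.mismatch, scoring.gap
    )
    if score <= 0:
        return None
    st = _trace(P, bi, bt, ea, eb, banded=True, dlo=dlo)
    return replace(st, score=int(score))


def local_align(
    a: str, b: str, scoring: Scoring = Scoring()
) -> AlignmentStats:
    """Best local alignment between two sequences (exact DP)."""
    return smith_waterman(a, b, scoring)


def kmer_candidate_pairs(
    catalog: CommunityCatalog, k: int = DEFAULT_K
) -> dict[tuple[str, str], set[str]]:
    """All unordered gene pairs sharing ≥1 exact k-mer on either strand.

    Returns a mapping (gene_a, gene_b) → strand set, with gene_a < gene_b.
    Any pair admitting an alignment that contains one exact k-length match is
    guaranteed to be present (exactness of the index).
    """
    if k < 8:
        raise ConfigurationError("seed k must be ≥ 8")
    fwd: dict[str, set[str]] = {}
    for rec in catalog.records:
        for _, w in kmers(rec.seq, k):
            fwd.setdefault(w, set()).add(rec.gene_id)
    pairs: dict[tuple[str, str], set[str]] = {}
    for genes in fwd.values():
        if len(genes) > 1:
            ordered = sorted(genes)
            for i, ga in enumerate(ordered):
                for gb in ordered[i + 1 :]:
                    pairs.setdefault((ga, gb), set()).add("+")
    # minus strand: a gene's reverse complement sharing a k-mer with another
    for rec in catalog.records:
        rc = reverse_complement(rec.seq)
        hit_partners: set[str] = set()
        for _, w in kmers(rc, k):
            hit_partners.update(fwd.get(w, ()))
        hit_partners.discard(rec.gene_id)
        for other in hit_partners:
            key = tuple(sorted((rec.gene_id, other)))
            pairs.setdefault(key, set()).add("-")
    return pairs


def _self_hit(gene_id: str, length: int, scoring: Scoring) -> AlignmentHit:
    return AlignmentHit(
        query_id=gene_id,
        target_id=gene_id,
        fident=1.0,
        aln_len=length,
        mismatch=0,
        gapopen=0,
        qstart=0,
        qend=length,
        tstart=0,
        tend=length,
        score=scoring.match * length,
        strand="+",
        qcov=1.0,
        tcov=1.0,
    )


def _stats_to_hit(
    st: AlignmentStats, qid: str, tid: str, qlen: int, tlen: int, strand: str
) -> AlignmentHit:
    tstart, tend = st.tstart, st.tend
    if strand == "-":
        tstart, tend = tlen - st.tend, tlen - st.tstart
    return AlignmentHit(
        query_id=qid,
        target_id=tid,
        fident=st.fident,
        aln_len=st.columns,
        mismatch=st.mismatches,
        gapopen=st.gapopens,
        qstart=st.qstart,
        qend=st.qend,
        tstart=tstart,
        tend=tend,
        score=st.score,
        strand=strand,
        qcov=(st.qend - st.qstart) / qlen,
        tcov=(st.tend - st.tstart) / tlen,
    )


def passes_stringency(hit: AlignmentHit, params: StringencyParams) -> bool:
    """Self-hits always pass; cross hits must clear identity, length, and the
    coverage rule selected by cov_mode."""
    if hit.is_self:
        return True
    if hit.fident < params.min_identity:
        return False
    if hit.aln_len < params.min_aln_len:
        return False
    c = params.min_coverage
    if params.cov_mode == "both":
        return min(hit.qcov, hit.tcov) >= c
    if params.cov_mode == "either":
        return max(hit.qcov, hit.tcov) >= c
    if params.cov_mode == "query":
        return hit.qcov >= c
    return hit.tcov >= c


def all_vs_all(
    catalog: CommunityCatalog,
    params: StringencyParams = StringencyParams(),
    scoring: Scoring = Scoring(),
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
    both_strands: bool = False,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[AlignmentHit]:
    """Align every CDS against every other CDS and filter the hits.

    Every gene's self-hit is always present; each surviving cross pair is
    reported twice (both query/target orientations).  Output is sorted by
    (query_id, descending score, target_id).
    """
    if len(catalog) == 0:
        raise ConfigurationError("catalog is empty")
    hits: list[AlignmentHit] = [
        _self_hit(rec.gene_id, rec.length, scoring) for rec in catalog.records
    ]
    for (ga, gb), strands in sorted(kmer_candidate_pairs(catalog, k).items()):
        if "+" not in strands and not both_strands:
            continue
        ra, rb = catalog.get(ga), catalog.get(gb)
        best: Optional[tuple[AlignmentStats, str, str]] = None
        strand_options = ["+"] if not both_strands else sorted(strands, reverse=True)
        for strand in strand_options:
            if strand not in strands:
                continue
            sb = rb.seq if strand == "+" else reverse_complement(rb.seq)
            st = seeded_align(ra.seq, sb, scoring, k=k, band=band)
            if st is not None and (best is None or st.score > best[0].score):
                best = (st, strand, sb)
        if best is None or best[0].score < min_score:
            continue
        st, strand, _ = best
        fwd_hit = _stats_to_hit(st, ga, gb, ra.length, rb.length, strand)
        if passes_stringency(fwd_hit, params):
            hits.append(fwd_hit)
            hits.append(fwd_hit.mirrored())
    hits.sort(key=lambda h: (h.query_id, -h.score, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# hit-table file IO (outfmt-6 compatible, plus qcov/tcov)
# ---------------------------------------------------------------------------

def write_hits(hits: Iterable[AlignmentHit], path: str | os.PathLike) -> None:
    """Write the 14-column tab-separated hit table (1-based inclusive
    coordinates; minus-strand hits use tstart > tend, BLAST convention)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            if h.strand == "+":
                ts, te = h.tstart + 1, h.tend
            else:
                ts, te = h.tend, h.tstart + 1
            ev = "NA" if h.evalue is None else f"{h.evalue:.3g}"
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.fident:.4f}\t{h.aln_len}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart + 1}\t{h.qend}\t"
                f"{ts}\t{te}\t{ev}\t{h.score}\t{h.qcov:.4f}\t{h.tcov:.4f}\n"
            )


def load_external_hits(
    path: str | os.PathLike,
    catalog: CommunityCatalog,
    strict: bool = True,
) -> list[AlignmentHit]:
    """Parse a tabular alignment file (MMseqs2/BLAST outfmt-6 convention,
    12 or 14 columns, optional header).

    Identity is accepted on either the 0–1 or 0–100 scale (auto-detected:
    any value > 1.5 means percent).  Coverage is taken from columns 13–14
    when present, otherwise computed from coordinates and catalog lengths.
    With ``strict=False``, rows whose query is not in the catalog are
    dropped instead of raising (targets outside the catalog are kept; their
    genome is recoverable from the gene-id prefix).
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fields[0] == "query" and fields[1] == "target":
                continue  # header
            if len(fields) < 12:
                raise HitParseError(
                    f"{path}: line {lineno}: expected ≥12 columns, got {len(fields)}"
                )
            rows.append([str(lineno)] + fields)

    # identity scale auto-detection over the whole file
    try:
        idents = [float(r[3]) for r in rows]
    except ValueError as e:
        raise HitParseError(f"{path}: non-numeric identity column: {e}") from None
    percent_scale = any(v > 1.5 for v in idents)

    hits: list[AlignmentHit] = []
    for r in rows:
        lineno, fields = int(r[0]), r[1:]
        q, t = fields[0], fields[1]
        try:
            fident = float(fields[2]) / (100.0 if percent_scale else 1.0)
            alnlen = int(fields[3])
            mism = int(fields[4])
            gapo = int(fields[5])
            qs, qe = int(fields[6]), int(fields[7])
            ts, te = int(fields[8]), int(fields[9])
            evalue = None if fields[10] in ("NA", "") else float(fields[10])
            bits = int(float(fields[11]))
        except ValueError as e:
            raise HitParseError(f"{path}: line {lineno}: malformed row ({e})") from None
        if q not in catalog:
            if strict:
                raise HitReferenceError(
                    f"{path}: line {lineno}: unknown query gene {q!r}"
                )
            continue
        strand = "+" if ts <= te else "-"
        if strand == "-":
            ts, te = te, ts
        qs0, qe0 = qs - 1, qe
        ts0, te0 = ts - 1, te
        if len(fields) >= 14:
            qcov, tcov = float(fields[12]), float(fields[13])
        else:
            if t not in catalog:
                if strict:
                    raise HitReferenceError(
                        f"{path}: line {lineno}: unknown target gene {t!r}"
                    )
                continue
            qcov = (qe0 - qs0) / catalog.get(q).length
            tcov = (te0 - ts0) / catalog.get(t).length
        if strict and t not in catalog:
            raise HitReferenceError(f"{path}: line {lineno}: unknown target gene {t!r}")
        if not (0.0 <= fident <= 1.0) or alnlen < 1:
            raise HitParseError(
                f"{path}: line {lineno}: identity/length out of range"
            )
        hits.append(
            AlignmentHit(
                query_id=q,
                target_id=t,
                fident=fident,
                aln_len=alnlen,
                mismatch=mism,
                gapopen=gapo,
                qstart=qs0,
                qend=qe0,
                tstart=ts0,
                tend=te0,
                score=bits,
                strand=strand,
                qcov=qcov,
                tcov=tcov,
                evalue=evalue,
            )
        )
    return hits
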