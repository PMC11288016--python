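"""Primer-pair enumeration, scoring, filtering, and ranking on candidate
marker genes.

The search is an explicit enumeration of every admissible forward/reverse
window pair (amplicon size within the product range, primers non-overlapping)
followed by hard filters (Tm and GC windows, poly-X, GC clamp, self- and
cross-complementarity) and a transparent additive penalty:

    penalty(oligo) = w_tm·|Tm − Tm_opt| + w_size·|len − len_opt| + w_gc·|GC − GC_opt|/10
    penalty(pair)  = penalty(fwd) + penalty(rev) + w_pair_diff·|Tm_fwd − Tm_rev|

Default design parameters are the settings used throughout this package's
reference runs: 125–175 bp amplicons, optimum Tm 62 °C (±3), and a maximum
pair ΔTm of 1.5 °C.  Everything is deterministic: ties break on
(fwd_start, rev_end) and identical sequence pairs are deduplicated.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._seq import max_homopolymer_run, reverse_complement
from .cds_io import CdsRecord, CommunityCatalog
from .errors import ConfigurationError
from .thermo import OligoProfile, ThermoConditions, complementarity_scores, profile_oligo

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignParams:
    product_min: int = 125
    product_max: int = 175
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    tm_min: float = 59.0
    tm_opt: float = 62.0
    tm_max: float = 65.0
    max_pair_tm_diff: float = 1.5
    gc_min: float = 30.0
    gc_opt: float = 50.0
    gc_max: float = 70.0
    max_polyx: int = 5
    n_return: int = 5
    w_tm: float = 1.0
    w_size: float = 1.0
    w_gc: float = 1.0
    w_pair_diff: float = 1.0
    max_self_any: int = 8
    max_self_end: int = 3
    max_hairpin: int = 8
    gc_clamp: bool = True
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        for lo, opt, hi, what in (
            (self.primer_len_min, self.primer_len_opt, self.primer_len_max, "length"),
            (self.tm_min, self.tm_opt, self.tm_max, "tm"),
            (self.gc_min, self.gc_opt, self.gc_max, "gc"),
        ):
            if not (lo <= opt <= hi):
                raise ConfigurationError(f"{what}: need min ≤ opt ≤ max")
        if self.product_min > self.product_max:
            raise ConfigurationError("product_min must be ≤ product_max")
        if self.product_min < 2 * self.primer_len_min:
            raise ConfigurationError("product_min must allow two primers")


@dataclass(frozen=True)
class PrimerPair:
    gene_id: str
    gene_seq: str
    fwd: OligoProfile
    rev: OligoProfile
    fwd_start: int  # 0-based half-open template coordinates
    rev_end: int
    penalty_fwd: float
    penalty_rev: float
    penalty_pair: float
    conservation: str = "n/a"  # exact_in_all_targets | mismatched | n/a

    @property
    def amplicon_bp(self) -> int:
        return self.rev_end - self.fwd_start

    @property
    def fwd_seq(self) -> str:
        return self.fwd.seq

    @property
    def rev_seq(self) -> str:
        return self.rev.seq


def enumerate_candidates(
    gene_seq: str, params: DesignParams
) -> list[tuple[int, int, int, int]]:
    """All admissible (fwd_start, fwd_len, rev_end, rev_len) window pairs.

    Admissible means: amplicon within the product range, primers disjoint on
    the template, both windows ACGT-only with no homopolymer longer than
    max_polyx.  A gene shorter than product_min yields an empty list.
    """
    n = len(gene_seq)
    if n < params.product_min:
        return []
    fwd_ok = _valid_windows(gene_seq, params, forward=True)
    rev_ok = _valid_windows(gene_seq, params, forward=False)
    rev_by_end: dict[int, list[int]] = {}
    for e, l in rev_ok:
        rev_by_end.setdefault(e, []).append(l)
    out = []
    for s, lf in fwd_ok:
        for e in range(
            max(s + params.product_min, s + lf), min(s + params.product_max, n) + 1
        ):
            for lr in rev_by_end.get(e, ()):
                if e - lr >= s + lf:  # primers must not overlap
                    out.append((s, lf, e, lr))
    return out


def _valid_windows(
    gene_seq: str, params: DesignParams, forward: bool
) -> list[tuple[int, int]]:
    """(position, length) windows passing sequence-level filters; position is
    the start for forward windows and the (half-open) end for reverse ones."""
    n = len(gene_seq)
    out = []
    for length in range(params.primer_len_min, params.primer_len_max + 1):
        for start in range(0, n - length + 1):
            w = gene_seq[start : start + length]
            if "N" in w or max_homopolymer_run(w) > params.max_polyx:
                continue
            out.append((start, length) if forward else (start + length, length))
    return out


def score_primer(
    oligo: OligoProfile, params: DesignParams
) -> tuple[Optional[float], str]:
    """(penalty, "") for an admissible oligo, or (None, violated-rule).

    Rules are checked in the order gc_clamp, gc, tm, self_any, self_end,
    hairpin (the order the staged search applies them)."""
    if params.gc_clamp and not (set(oligo.seq[-2:]) & set("GC")):
        return None, "gc_clamp"
    if not (params.gc_min <= oligo.gc_pct <= params.gc_max):
        return None, "gc"
    if not (params.tm_min <= oligo.tm_c <= params.tm_max):
        return None, "tm"
    if oligo.self_any > params.max_self_any:
        return None, "self_any"
    if oligo.self_end > params.max_self_end:
        return None, "self_end"
    if oligo.hairpin > params.max_hairpin:
        return None, "hairpin"
    penalty = (
        params.w_tm * abs(oligo.tm_c - params.tm_opt)
        + params.w_size * abs(oligo.length - params.primer_len_opt)
        + params.w_gc * abs(oligo.gc_pct - params.gc_opt) / 10.0
    )
    return penalty, ""


def _admissible_oligo(
    seq: str,
    params: DesignParams,
    cache: dict[str, tuple[Optional[OligoProfile], Optional[float]]],
    counts: dict[str, int],
) -> tuple[Optional[OligoProfile], Optional[float]]:
    """Staged hard-filter evaluation with memoisation: cheap GC/Tm checks
    first, O(len²) complementarity only for oligos that survive them.  The
    result is identical to profiling every window and calling score_primer."""
    if seq in cache:
        return cache[seq]
    from .thermo import gc_content, melting_temperature

    result: tuple[Optional[OligoProfile], Optional[float]]
    rule = ""
    if params.gc_clamp and not (set(seq[-2:]) & set("GC")):
        rule = "gc_clamp"
    else:
        gc = gc_content(seq)
        if not (params.gc_min <= gc <= params.gc_max):
            rule = "gc"
        else:
            tm = melting_temperature(seq, params.conditions)
            if not (params.tm_min <= tm <= params.tm_max):
                rule = "tm"
    if rule:
        counts[rule] = counts.get(rule, 0) + 1
        result = (None, None)
    else:
        prof = profile_oligo(seq, params.conditions)
        pen, rule = score_primer(prof, params)
        if pen is None:
            counts[rule] = counts.get(rule, 0) + 1
            result = (None, None)
        else:
            result = (prof, pen)
    cache[seq] = result
    return result


def design_pairs(
    gene: CdsRecord,
    params: DesignParams = DesignParams(),
    conservation_targets: Optional[list[CdsRecord]] = None,
    rejection_counts: Optional[dict[str, int]] = None,
) -> list[PrimerPair]:
    """Top ``n_return`` primer pairs on one gene, ascending pair penalty.

    Equivalent to exhaustively scoring :func:`enumerate_candidates` output,
    but stages the filters for speed.  In group mode, pass the other group
    members' gene copies as ``conservation_targets``: each returned pair is
    marked ``exact_in_all_targets`` only if both primer binding sites occur
    verbatim in every target copy, else ``mismatched``.
    """
    counts = rejection_counts if rejection_counts is not None else {}
    n = len(gene.seq)
    if n < params.product_min:
        counts["geometry"] = counts.get("geometry", 0) + 1
        return []
    cache: dict[str, tuple[Optional[OligoProfile], Optional[float]]] = {}
    fwd_valid: list[tuple[int, int, OligoProfile, float]] = []
    for s, lf in _valid_windows(gene.seq, params, forward=True):
        prof, pen = _admissible_oligo(gene.seq[s : s + lf], params, cache, counts)
        if prof is not None:
            fwd_valid.append((s, lf, prof, pen))
    rev_by_end: dict[int, list[tuple[int, OligoProfile, float]]] = {}
    for e, lr in _valid_windows(gene.seq, params, forward=False):
        rseq = reverse_complement(gene.seq[e - lr : e])
        prof, pen = _admissible_oligo(rseq, params, cache, counts)
        if prof is not None:
            rev_by_end.setdefault(e, []).append((lr, prof, pen))

    scored: list[tuple[float, int, int, OligoProfile, OligoProfile, float, float]] = []
    for s, lf, fprof, fpen in fwd_valid:
        e_lo = max(s + params.product_min, s + lf)
        e_hi = min(s + params.product_max, n)
        for e in range(e_lo, e_hi + 1):
            for lr, rprof, rpen in rev_by_end.get(e, ()):
                if e - lr < s + lf:  # primers must not overlap
                    continue
                dtm = abs(fprof.tm_c - rprof.tm_c)
                if dtm > params.max_pair_tm_diff:
                    counts["pair_tm_diff"] = counts.get("pair_tm_diff", 0) + 1
                    continue
                pair_pen = fpen + rpen + params.w_pair_diff * dtm
                scored.append((pair_pen, s, e, fprof, rprof, fpen, rpen))

    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    pairs: list[PrimerPair] = []
    seen_seqs: set[tuple[str, str]] = set()
    for pair_pen, s, e, fprof, rprof, fpen, rpen in scored:
        if len(pairs) >= params.n_return:
            break
        key = (fprof.seq, rprof.seq)
        if key in seen_seqs:
            continue
        x_any, x_end = complementarity_scores(fprof.seq, rprof.seq)
        if x_any > params.max_self_any or x_end > params.max_self_end:
            counts["cross_dimer"] = counts.get("cross_dimer", 0) + 1
            continue
        seen_seqs.add(key)
        conservation = "n/a"
        if conservation_targets is not None:
            site_rev = reverse_complement(rprof.seq)
            conserved = all(
                fprof.seq in t.seq and site_rev in t.seq
                for t in conservation_targets
            )
            conservation = "exact_in_all_targets" if conserved else "mismatched"
        pairs.append(
            PrimerPair(
                gene_id=gene.gene_id,
                gene_seq=gene.seq,
                fwd=fprof,
                rev=rprof,
                fwd_start=s,
                rev_end=e,
                penalty_fwd=fpen,
                penalty_rev=rpen,
                penalty_pair=pair_pen,
                conservation=conservation,
            )
        )
    if not pairs and counts:
        log.info("%s: no admissible primer pair (rejections: %s)", gene.gene_id, counts)
    return pairs


def design_for_community(
    ranked: dict[str, list[str]],
    catalog: CommunityCatalog,
    params: DesignParams = DesignParams(),
    mode: str = "unique",
    group_calls: Optional[list] = None,
) -> tuple[list[tuple[str, PrimerPair]], list[str]]:
    """Walk ranked candidate genes and design up to n_return pairs per genome
    (unique mode) or per group (group mode).

    Returns (rows, warnings) where each row is (genome-or-group label, pair).
    A genome with zero candidates or zero admissible pairs produces a warning,
    never an error.
    """
    rows: list[tuple[str, PrimerPair]] = []
    warnings: list[str] = []
    evidence_by_gene = {}
    if group_calls is not None:
        evidence_by_gene = {c.gene_id: c for c in group_calls}
    for label in sorted(ranked):
        candidates = ranked[label]
        if not candidates:
            warnings.append(f"{label}: 0 candidate genes — no primers designed")
            continue
        found = 0
        for gene_id in candidates:
            if found >= params.n_return:
                break
            gene = catalog.get(gene_id)
            conservation_targets = None
            if mode == "group":
                call = evidence_by_gene.get(gene_id)
                partner_ids = (
                    sorted({ev[0] for ev in call.evidence}) if call is not None else []
                )
                conservation_targets = [
                    catalog.get(p) for p in partner_ids if p in catalog
                ]
            remaining = DesignParams(
                **{
                    **_params_dict(params),
                    "n_return": params.n_return - found,
                }
            )
            got = design_pairs(gene, remaining, conservation_targets)
            for p in got:
                rows.append((label, p))
            found += len(got)
        if found == 0:
            warnings.append(
                f"{label}: no admissible primer pairs among "
                f"{len(candidates)} candidate genes"
            )
    return rows, warnings


def _params_dict(params: DesignParams) -> dict:
    return {
        f: getattr(params, f) for f in DesignParams.__dataclass_fields__
    }


TABLE_COLUMNS = (
    "label",
    "gene_id",
    "gene_len",
    "pair_penalty",
    "amplicon_bp",
    "fwd_seq",
    "rev_seq",
    "fwd_start",
    "rev_end",
    "fwd_len",
    "rev_len",
    "fwd_gc",
    "rev_gc",
    "fwd_tm",
    "rev_tm",
    "fwd_penalty",
    "rev_penalty",
    "conservation",
    "gene_seq",
)


def write_primer_table(
    rows: Iterable[tuple[str, PrimerPair]],
    path: str | os.PathLike,
    warnings: Iterable[str] = (),
) -> None:
    """Write the primer table TSV (UniquePrimerTable / GroupPrimerTable).

    Numeric columns use fixed rounding (Tm and GC to 2 decimals, penalties to
    4) so the table is exactly recomputable from the printed sequences.
    """
    with open(path, "w", newline="\n") as fh:
        for w in warnings:
            fh.write(f"# WARNING: {w}\n")
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for label, p in rows:
            fh.write(
                f"{label}\t{p.gene_id}\t{len(p.gene_seq)}\t{p.penalty_pair:.4f}\t"
                f"{p.amplicon_bp}\t{p.fwd_seq}\t{p.rev_seq}\t{p.fwd_start}\t"
                f"{p.rev_end}\t{p.fwd.length}\t{p.rev.length}\t{p.fwd.gc_pct:.2f}\t"
                f"{p.rev.gc_pct:.2f}\t{p.fwd.tm_c:.2f}\t{p.rev.tm_c:.2f}\t"
                f"{p.penalty_fwd:.4f}\t{p.penalty_rev:.4f}\t{p.conservation}\t"
                f"{p.gene_seq}\n"
            )
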