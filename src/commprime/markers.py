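"""Marker-gene classification from the all-vs-all hit table.

Microbe-specific (unique) mode: a gene is *unique* iff its only surviving
alignment is its self-hit.  A gene whose cross hits stay within its own genome
is *multi_copy* (a duplicated gene would amplify at more than one locus and is
excluded from primer design); a gene hitting any other genome is *non_unique*.
Group mode: a gene is *group_shared* iff it hits at least one gene in every
other group member and no gene outside the group.

Non-target genomes contribute exclusion evidence only; candidate genes are
drawn exclusively from target genomes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

from .cds_io import CommunityCatalog
from .errors import ConfigurationError, HitReferenceError
from .homology import AlignmentHit

STATUSES = ("unique", "group_shared", "non_unique", "multi_copy", "excluded_ambiguous")


@dataclass(frozen=True)
class MarkerCall:
    gene_id: str
    genome_id: str
    status: str
    evidence: tuple = ()  # (other gene_id, fident, qcov) triples
    group_members_hit: frozenset = frozenset()
    reason: str = ""


@dataclass(frozen=True)
class UniqueGeneSummary:
    genome_id: str
    n_unique: int
    n_total: int

    @property
    def fraction_unique(self) -> float:
        return self.n_unique / self.n_total if self.n_total else 0.0


def _cross_hits_by_query(
    hits: Iterable[AlignmentHit], catalog: CommunityCatalog
) -> dict[str, list[AlignmentHit]]:
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.query_id in catalog or h.target_id in catalog:
            pass
        else:
            raise HitReferenceError(
                f"hit references unknown genes {h.query_id!r}/{h.target_id!r}"
            )
        if h.is_self:
            continue
        by_query.setdefault(h.query_id, []).append(h)
    return by_query


def classify_unique(
    hits: Iterable[AlignmentHit], catalog: CommunityCatalog
) -> tuple[list[MarkerCall], list[UniqueGeneSummary]]:
    """Per-gene unique/multi_copy/non_unique calls plus per-genome summaries.

    Summaries cover target genomes only and are sorted by descending unique
    count (the bar-plot ordering), ties broken by genome_id.
    """
    by_query = _cross_hits_by_query(hits, catalog)
    calls: list[MarkerCall] = []
    for rec in catalog.records:
        if rec.genome_id not in catalog.target_genomes:
            continue
        cross = by_query.get(rec.gene_id, [])
        evidence = tuple(
            (h.target_id, round(h.fident, 4), round(h.qcov, 4)) for h in cross
        )
        other_genomes = {catalog.genome_of(h.target_id) for h in cross}
        if other_genomes - {rec.genome_id}:
            status, reason = "non_unique", "homolog in another genome"
        elif other_genomes:
            status, reason = "multi_copy", "duplicated within its own genome"
        elif not rec.primer_eligible:
            status, reason = "excluded_ambiguous", "sequence >5% ambiguous bases"
        else:
            status, reason, evidence = "unique", "", ()
        calls.append(
            MarkerCall(rec.gene_id, rec.genome_id, status, evidence, reason=reason)
        )

    summaries = []
    for g in sorted(catalog.target_genomes):
        mine = [c for c in calls if c.genome_id == g]
        summaries.append(
            UniqueGeneSummary(
                genome_id=g,
                n_unique=sum(c.status == "unique" for c in mine),
                n_total=len(mine),
            )
        )
    summaries.sort(key=lambda s: (-s.n_unique, s.genome_id))
    return calls, summaries


def classify_group(
    hits: Iterable[AlignmentHit],
    catalog: CommunityCatalog,
    group: Iterable[str],
) -> list[MarkerCall]:
    """Group-shared calls for genes of the given target-genome group.

    A gene qualifies iff (a) it has a surviving hit into every *other* group
    genome and (b) it has no surviving hit outside the group (including
    non-target genomes); anything else is excluded with a reason.
    """
    group = set(group)
    unknown = group - set(catalog.genomes)
    if unknown:
        raise ConfigurationError(f"group names unknown genomes: {sorted(unknown)}")
    if not group <= catalog.target_genomes:
        raise ConfigurationError("group members must all be target genomes")
    if len(group) < 2:
        raise ConfigurationError(
            "group mode needs ≥2 genomes (use unique mode for a single target)"
        )
    by_query = _cross_hits_by_query(hits, catalog)
    calls: list[MarkerCall] = []
    for rec in catalog.records:
        if rec.genome_id not in group:
            continue
        cross = by_query.get(rec.gene_id, [])
        genomes_hit = {catalog.genome_of(h.target_id) for h in cross}
        outside = genomes_hit - group
        missing = group - genomes_hit - {rec.genome_id}
        evidence = tuple(
            (h.target_id, round(h.fident, 4), round(h.qcov, 4)) for h in cross
        )
        members_hit = frozenset((genomes_hit & group) | {rec.genome_id})
        if outside:
            status, reason = "excluded_ambiguous", (
                "hits outside the group: " + ",".join(sorted(outside))
            )
        elif missing:
            status, reason = "excluded_ambiguous", (
                "missing in group members: " + ",".join(sorted(missing))
            )
        elif not rec.primer_eligible:
            status, reason = "excluded_ambiguous", "sequence >5% ambiguous bases"
        else:
            status, reason = "group_shared", ""
        calls.append(
            MarkerCall(
                rec.gene_id,
                rec.genome_id,
                status,
                evidence,
                group_members_hit=members_hit,
                reason=reason,
            )
        )
    return calls


def rank_candidates(
    calls: Iterable[MarkerCall],
    catalog: CommunityCatalog,
    mode: str = "unique",
) -> dict[str, list[str]]:
    """Primer-design order: eligible genes sorted by decreasing length,
    ties broken lexicographically by gene_id.

    Unique mode returns one ranked list per target genome (possibly empty —
    downstream warns rather than failing); group mode returns a single pooled
    list under the key ``"group"``.
    """
    eligible_status = "unique" if mode == "unique" else "group_shared"

    def order(gene_ids: list[str]) -> list[str]:
        return sorted(gene_ids, key=lambda g: (-catalog.get(g).length, g))

    if mode == "unique":
        per_genome: dict[str, list[str]] = {
            g: [] for g in sorted(catalog.target_genomes)
        }
        for c in calls:
            if c.status == eligible_status:
                per_genome[c.genome_id].append(c.gene_id)
        return {g: order(ids) for g, ids in per_genome.items()}
    pooled = [c.gene_id for c in calls if c.status == eligible_status]
    return {"group": order(pooled)}


def write_summaries(
    summaries: Iterable[UniqueGeneSummary], path: str | os.PathLike
) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("genome_id\tn_unique\tn_total\tfraction_unique\n")
        for s in summaries:
            fh.write(f"{s.genome_id}\t{s.n_unique}\t{s.n_total}\t{s.fraction_unique:.4f}\n")


def write_plot_data(
    summaries: Iterable[UniqueGeneSummary], path: str | os.PathLike
) -> None:
    """Data behind the unique-genes bar plot: unique vs non-unique counts per
    genome, already in descending-unique order."""
    with open(path, "w", newline="\n") as fh:
        fh.write("genome_id\tn_unique\tn_non_unique\n")
        for s in summaries:
            fh.write(f"{s.genome_id}\t{s.n_unique}\t{s.n_total - s.n_unique}\n")


def plot_unique_genes(
    summaries: list[UniqueGeneSummary], path: str | os.PathLike
) -> None:
    """Render the stacked unique/non-unique bar plot to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genomes = [s.genome_id for s in summaries]
    uniq = [s.n_unique for s in summaries]
    rest = [s.n_total - s.n_unique for s in summaries]
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(genomes)), 4))
    ax.bar(genomes, uniq, label="unique", color="#2b7bba")
    ax.bar(genomes, rest, bottom=uniq, label="non-unique", color="#c7c7c7")
    ax.set_ylabel("CDS count")
    ax.set_xlabel("genome")
    ax.legend()
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
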