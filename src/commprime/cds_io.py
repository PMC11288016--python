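"""Reading and normalising CDS FASTA inputs for a defined community.

One multi-FASTA of coding sequences per genome, with filenames like
``B_theta_VPI5482_cds.fna``: the text before the first ``_cds`` is the genome
identifier, and every FASTA header's first whitespace-delimited token becomes a
community-unique gene identifier ``<genome_id>|<token>``.  Headers may follow
the Prokka, RAST, or NCBI dialects; the dialect is auto-detected and recorded
as provenance but never changes behaviour.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from ._seq import IUPAC_CHARS, IUPAC_TO_CANONICAL
from .errors import (
    CdsFilenameError,
    CdsParseError,
    ConfigurationError,
    DuplicateGeneError,
    GenomeCollisionError,
)

GENE_ID_SEP = "|"

#: fraction of N above which a gene is ineligible for primer design
MAX_N_FRACTION = 0.05


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence, normalised to uppercase {A,C,G,T,N}."""

    genome_id: str
    gene_id: str
    seq: str
    source_dialect: str  # prokka | rast | ncbi
    role: str  # target | nontarget

    def __post_init__(self) -> None:
        if not self.seq:
            raise CdsParseError(f"{self.gene_id}: empty sequence")
        if not self.genome_id:
            raise CdsParseError(f"{self.gene_id}: empty genome_id")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_fraction(self) -> float:
        return self.seq.count("N") / len(self.seq)

    @property
    def primer_eligible(self) -> bool:
        return self.n_fraction <= MAX_N_FRACTION


@dataclass
class CommunityCatalog:
    """All CDS records of a community, indexed by genome and by gene."""

    records: list[CdsRecord] = field(default_factory=list)
    genomes: list[str] = field(default_factory=list)
    by_genome: dict[str, list[str]] = field(default_factory=dict)
    target_genomes: set[str] = field(default_factory=set)
    nontarget_genomes: set[str] = field(default_factory=set)
    _index: dict[str, CdsRecord] = field(default_factory=dict, repr=False)

    def add(self, rec: CdsRecord) -> None:
        if rec.gene_id in self._index:
            raise DuplicateGeneError(f"duplicate gene id {rec.gene_id!r}")
        self.records.append(rec)
        self._index[rec.gene_id] = rec
        if rec.genome_id not in self.by_genome:
            self.by_genome[rec.genome_id] = []
            self.genomes.append(rec.genome_id)
        self.by_genome[rec.genome_id].append(rec.gene_id)
        (self.target_genomes if rec.role == "target" else self.nontarget_genomes).add(
            rec.genome_id
        )

    def get(self, gene_id: str) -> CdsRecord:
        return self._index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self.records)

    def genome_of(self, gene_id: str) -> str:
        """Genome of a gene; falls back to the id prefix for genes outside
        the catalog (hit tables may reference non-target genes not loaded)."""
        if gene_id in self._index:
            return self._index[gene_id].genome_id
        return gene_id.split(GENE_ID_SEP, 1)[0]

    def write_combined_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        with open(path, "w", newline="\n") as fh:
            for rec in self.records:
                fh.write(f">{rec.gene_id}\n")
                for i in range(0, len(rec.seq), width):
                    fh.write(rec.seq[i : i + width] + "\n")

    def write_manifest(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="\n") as fh:
            fh.write("genome_id\trole\tn_genes\n")
            for g in self.genomes:
                role = "target" if g in self.target_genomes else "nontarget"
                fh.write(f"{g}\t{role}\t{len(self.by_genome[g])}\n")


def validate_cds_filename(path: str | os.PathLike) -> str:
    """Return the genome id encoded in a CDS filename.

    The name must end in ``.fna``, contain the substring ``cds``, and carry a
    non-empty genome label before the first ``_cds``.
    """
    name = Path(path).name
    if not name.endswith(".fna"):
        raise CdsFilenameError(f"{name!r}: CDS files must end with '.fna'")
    if "cds" not in name:
        raise CdsFilenameError(f"{name!r}: CDS filenames must contain 'cds'")
    idx = name.find("_cds")
    if idx <= 0:
        raise CdsFilenameError(
            f"{name!r}: expected a genome label before '_cds' in the filename"
        )
    return name[:idx]


def detect_dialect(header: str) -> str:
    """Classify a FASTA header line (without '>') as ncbi, rast, or prokka."""
    if header.startswith("lcl|") or "[locus_tag=" in header:
        return "ncbi"
    if header.startswith("fig|") and "_CDS_" in header:
        return "rast"
    return "prokka"


def _normalise_seq(raw: str, gene_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - IUPAC_CHARS
    if bad:
        raise CdsParseError(
            f"{gene_id}: non-IUPAC characters {sorted(bad)!r} in sequence"
        )
    return seq.translate(IUPAC_TO_CANONICAL)


def parse_cds_fasta(path: str | os.PathLike, role: str = "target") -> list[CdsRecord]:
    """Parse one genome's CDS FASTA into normalised records.

    gene_id is ``<genome_id>|<first header token>``; duplicate tokens within a
    file and empty files are errors.
    """
    if role not in ("target", "nontarget"):
        raise ConfigurationError(f"role must be target or nontarget, got {role!r}")
    genome_id = validate_cds_filename(path)
    records: list[CdsRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        token = entry.id
        if token in seen:
            raise DuplicateGeneError(
                f"{Path(path).name}: duplicate header token {token!r}"
            )
        seen.add(token)
        gene_id = f"{genome_id}{GENE_ID_SEP}{token}"
        records.append(
            CdsRecord(
                genome_id=genome_id,
                gene_id=gene_id,
                seq=_normalise_seq(str(entry.seq), gene_id),
                source_dialect=detect_dialect(entry.description),
                role=role,
            )
        )
    if not records:
        raise CdsParseError(f"{Path(path).name}: no FASTA entries found")
    return records


def _cds_files(directory: str | os.PathLike) -> list[Path]:
    return sorted(
        p
        for p in Path(directory).iterdir()
        if p.is_file() and p.name.endswith(".fna") and "cds" in p.name
    )


def build_catalog(
    target_dir: str | os.PathLike,
    nontarget_dir: Optional[str | os.PathLike] = None,
    combined_fasta: Optional[str | os.PathLike] = None,
) -> CommunityCatalog:
    """Build the community catalog from per-genome CDS files.

    Genomes are sorted lexicographically by genome_id before identifier
    assignment, so the catalog is invariant to directory listing order.
    Optionally writes the concatenated normalised FASTA used downstream.
    """
    target_files = _cds_files(target_dir)
    if not target_files:
        raise ConfigurationError(f"no CDS files (*cds*.fna) found in {target_dir}")
    nontarget_files = _cds_files(nontarget_dir) if nontarget_dir else []

    plan: list[tuple[str, Path, str]] = []
    seen_genomes: dict[str, str] = {}
    for files, role in ((target_files, "target"), (nontarget_files, "nontarget")):
        for f in files:
            gid = validate_cds_filename(f)
            if gid in seen_genomes:
                raise GenomeCollisionError(
                    f"genome id {gid!r} appears in both {seen_genomes[gid]} "
                    f"and {f.name}"
                )
            seen_genomes[gid] = f.name
            plan.append((gid, f, role))
    plan.sort(key=lambda t: t[0])

    catalog = CommunityCatalog()
    for _gid, f, role in plan:
        for rec in parse_cds_fasta(f, role=role):
            catalog.add(rec)
    if combined_fasta is not None:
        catalog.write_combined_fasta(combined_fasta)
    return catalog


def catalog_from_records(records: Iterable[CdsRecord]) -> CommunityCatalog:
    """Assemble a catalog directly from records (tests, synthetic data)."""
    catalog = CommunityCatalog()
    for rec in sorted(records, key=lambda r: (r.genome_id, r.gene_id)):
        catalog.add(rec)
    return catalog
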