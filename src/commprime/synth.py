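"""Deterministic synthetic-community generator with planted ground truth.

Writes per-genome CDS FASTA files (any of the three supported header
dialects) in which every gene has a known role: *private* (unique to one
genome), member of a *shared* homolog family planted at a controlled
identity across a set of genomes, an exact within-genome *duplicate*, or
unrelated *background*.  The planted truth is returned (and written) as a
manifest, so every pipeline stage can be tested against known answers.

Two fidelity guarantees make planted truth exact rather than probable:

* substitution-only mutation, so a family member's identity to its family
  base sequence is exactly ``round(len·(1−identity))`` mismatches;
* 13-mer disjointness between unrelated lineages (rejection sampling), so
  chance micro-homologies cannot blur the planted classes.

Same seed ⇒ byte-identical FASTA files and manifest.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._seq import kmers, reverse_complement

_BASES = np.array(list("ACGT"))
_DISJOINT_K = 13


@dataclass(frozen=True)
class SharedFamily:
    """A homolog family planted across several genomes at a given identity
    to the family base sequence."""

    name: str
    members: tuple[str, ...]
    identity: float = 0.95
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if len(self.members) < 1:
            raise ValueError("a family needs ≥1 member genome")


@dataclass
class CommunityPlan:
    seed: int = 0
    genomes: list[str] = field(default_factory=list)
    n_private: int = 5
    shared_families: list[SharedFamily] = field(default_factory=list)
    n_duplicated: int = 0
    n_background: int = 0
    length_range: tuple[int, int] = (400, 800)
    gc_target: float = 0.5
    dialect: str = "prokka"  # prokka | rast | ncbi
    private_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genomes:
            raise ValueError("plan needs ≥1 genome")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("genome names must be unique")
        lo, hi = self.length_range
        if lo < _DISJOINT_K or lo > hi:
            raise ValueError("bad length_range")
        if self.dialect not in ("prokka", "rast", "ncbi"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str  # <genome>|<header token>, as the pipeline will name it
    genome_id: str
    token: str
    role: str  # private | shared | duplicate | background
    family: str = ""
    identity: float = 1.0
    duplicate_of: str = ""


def uniform_plan(
    n_genomes: int = 10,
    n_private: int = 5,
    n_all_shared: int = 2,
    identity: float = 0.95,
    seed: int = 0,
    n_duplicated: int = 0,
    n_background: int = 0,
    dialect: str = "prokka",
    length_range: tuple[int, int] = (400, 800),
) -> CommunityPlan:
    """Symmetric community: every genome carries ``n_private`` private genes
    and a copy of each of ``n_all_shared`` families shared by all genomes."""
    genomes = [f"genome{str(i).zfill(2)}" for i in range(1, n_genomes + 1)]
    fams = [
        SharedFamily(f"fam{str(i).zfill(2)}", tuple(genomes), identity)
        for i in range(1, n_all_shared + 1)
    ]
    return CommunityPlan(
        seed=seed,
        genomes=genomes,
        n_private=n_private,
        shared_families=fams,
        n_duplicated=n_duplicated,
        n_background=n_background,
        dialect=dialect,
        length_range=length_range,
    )


def subsumed_plan(
    n_other: int = 3,
    n_genes: int = 5,
    identity: float = 0.95,
    seed: int = 0,
    dialect: str = "prokka",
) -> CommunityPlan:
    """Community in which one genome is entirely subsumed: every one of its
    genes is a high-identity copy of a gene in the first donor genome, so no
    unique gene exists for it (the zero-unique-genes scenario)."""
    genomes = [f"genome{str(i).zfill(2)}" for i in range(1, n_other + 1)]
    subsumed = "subsumed"
    fams = [
        SharedFamily(f"sub{str(i).zfill(2)}", (genomes[0], subsumed), identity)
        for i in range(1, n_genes + 1)
    ]
    return CommunityPlan(
        seed=seed,
        genomes=genomes + [subsumed],
        n_private=n_genes,
        shared_families=fams,
        dialect=dialect,
        private_overrides={subsumed: 0},
    )


def mutate_to_identity(seq: str, target_identity: float, seed: int) -> str:
    """Substitution-only mutant at exactly round(len·(1−identity)) mismatched
    positions, drawn deterministically from the seed."""
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    return _mutate(seq, target_identity, rng)


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    n_mut = round(len(seq) * (1.0 - identity))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return "".join(out)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(_BASES[idx])


class _KmerRegistry:
    """Tracks which lineage owns each k-mer (both strands) so unrelated
    lineages never share one."""

    def __init__(self, k: int = _DISJOINT_K) -> None:
        self.k = k
        self._owner: dict[str, str] = {}

    def conflicts(self, seq: str, lineage: str) -> bool:
        for s in (seq, reverse_complement(seq)):
            for _, w in kmers(s, self.k):
                owner = self._owner.get(w)
                if owner is not None and owner != lineage:
                    return True
        return False

    def register(self, seq: str, lineage: str) -> None:
        for s in (seq, reverse_complement(seq)):
            for _, w in kmers(s, self.k):
                self._owner.setdefault(w, lineage)


def _fresh_seq(
    rng: np.random.Generator,
    length: int,
    gc: float,
    registry: _KmerRegistry,
    lineage: str,
    max_tries: int = 200,
) -> str:
    for _ in range(max_tries):
        seq = _random_seq(rng, length, gc)
        if not registry.conflicts(seq, lineage):
            registry.register(seq, lineage)
            return seq
    raise RuntimeError("could not draw a k-mer-disjoint sequence")


def _fresh_mutant(
    base: str,
    identity: float,
    rng: np.random.Generator,
    registry: _KmerRegistry,
    lineage: str,
    max_tries: int = 200,
) -> str:
    for _ in range(max_tries):
        mut = _mutate(base, identity, rng)
        if not registry.conflicts(mut, lineage):
            registry.register(mut, lineage)
            return mut
    raise RuntimeError("could not draw a k-mer-disjoint mutant")


def _token(dialect: str, genome: str, idx: int) -> str:
    """First whitespace-delimited header token — exactly what the reader
    will turn into the gene id."""
    if dialect == "ncbi":
        return f"lcl|SYN_{genome}.1_cds_{idx}"
    if dialect == "rast":
        return f"fig|6666666.1.peg.{idx}_CDS_{genome}_{idx:04d}"
    return f"{genome}_{idx:05d}"


def _header(dialect: str, genome: str, token: str, idx: int, role: str) -> str:
    if dialect == "ncbi":
        return f"{token} [locus_tag={genome}_{idx:04d}] [synthetic {role} gene]"
    return f"{token} synthetic {role} gene"


def generate_community(
    plan: CommunityPlan, out_dir: str | os.PathLike
) -> list[TruthRecord]:
    """Write ``<genome>_cds.fna`` files and ``truth_manifest.tsv``; return
    the planted-truth records."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(plan.seed)
    registry = _KmerRegistry()
    lo, hi = plan.length_range

    # family base sequences are drawn first, in declaration order; the first
    # listed member genome receives the base itself, later members receive
    # substitution mutants at the planted identity to it
    family_base: dict[str, str] = {}
    for fam in plan.shared_families:
        length = fam.length or int(rng.integers(lo, hi + 1))
        family_base[fam.name] = _fresh_seq(
            rng, length, plan.gc_target, registry, lineage=f"family:{fam.name}"
        )

    truth: list[TruthRecord] = []
    genes_per_genome: dict[str, list[tuple[str, str, str]]] = {
        g: [] for g in plan.genomes
    }
    for genome in plan.genomes:
        idx = 0
        n_priv = plan.private_overrides.get(genome, plan.n_private)
        for _ in range(n_priv):
            idx += 1
            token = _token(plan.dialect, genome, idx)
            lineage = f"private:{genome}:{token}"
            seq = _fresh_seq(
                rng, int(rng.integers(lo, hi + 1)), plan.gc_target, registry, lineage
            )
            genes_per_genome[genome].append((token, seq, "private"))
            truth.append(
                TruthRecord(f"{genome}|{token}", genome, token, "private")
            )
        for fam in plan.shared_families:
            if genome not in fam.members:
                continue
            idx += 1
            token = _token(plan.dialect, genome, idx)
            if genome == fam.members[0]:
                seq, ident = family_base[fam.name], 1.0
            else:
                seq = _fresh_mutant(
                    family_base[fam.name],
                    fam.identity,
                    rng,
                    registry,
                    lineage=f"family:{fam.name}",
                )
                ident = fam.identity
            genes_per_genome[genome].append((token, seq, "shared"))
            truth.append(
                TruthRecord(
                    f"{genome}|{token}",
                    genome,
                    token,
                    "shared",
                    family=fam.name,
                    identity=ident,
                )
            )
        for d in range(plan.n_duplicated):
            idx += 1
            token_a = _token(plan.dialect, genome, idx)
            lineage = f"dup:{genome}:{token_a}"
            seq = _fresh_seq(
                rng, int(rng.integers(lo, hi + 1)), plan.gc_target, registry, lineage
            )
            idx += 1
            token_b = _token(plan.dialect, genome, idx)
            genes_per_genome[genome].append((token_a, seq, "duplicate"))
            genes_per_genome[genome].append((token_b, seq, "duplicate"))
            truth.append(
                TruthRecord(f"{genome}|{token_a}", genome, token_a, "duplicate")
            )
            truth.append(
                TruthRecord(
                    f"{genome}|{token_b}",
                    genome,
                    token_b,
                    "duplicate",
                    duplicate_of=f"{genome}|{token_a}",
                )
            )
        for _ in range(plan.n_background):
            idx += 1
            token = _token(plan.dialect, genome, idx)
            lineage = f"background:{genome}:{token}"
            seq = _fresh_seq(
                rng, int(rng.integers(lo, hi + 1)), plan.gc_target, registry, lineage
            )
            genes_per_genome[genome].append((token, seq, "background"))
            truth.append(
                TruthRecord(f"{genome}|{token}", genome, token, "background")
            )

    for genome in plan.genomes:
        path = out / f"{genome}_cds.fna"
        with open(path, "w", newline="\n") as fh:
            for i, (token, seq, role) in enumerate(genes_per_genome[genome], 1):
                fh.write(f">{_header(plan.dialect, genome, token, i, role)}\n")
                for j in range(0, len(seq), 70):
                    fh.write(seq[j : j + 70] + "\n")

    with open(out / "truth_manifest.tsv", "w", newline="\n") as fh:
        fh.write(
            "gene_id\tgenome_id\ttoken\trole\tfamily\tidentity\tduplicate_of\n"
        )
        for t in truth:
            fh.write(
                f"{t.gene_id}\t{t.genome_id}\t{t.token}\t{t.role}\t"
                f"{t.family}\t{t.identity}\t{t.duplicate_of}\n"
            )
    return truth
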