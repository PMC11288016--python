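"""Copy-number arithmetic for community pooling and ddPCR interpretation.

A gDNA concentration X (ng/µL) of a genome of N bp corresponds to

    copies/µL = X · 6.0221×10²³ / (N · 660 g/mol) · 10⁻⁹

(660 g/mol per base pair; the 10⁻⁹ converts ng to g).  Equal-copy pooling
distributes a total volume inversely to each member's copies/µL so every
member contributes the same number of genomic copies.  Absolute ddPCR counts
convert to relative abundance by dividing each member's copies/µL by the sum
over all (retained) members; members without usable primers can be dropped
from both numerator and denominator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .errors import InfeasiblePoolError, UndefinedCompositionError

AVOGADRO = 6.0221e23  # molecules per mole
BP_MOLAR_MASS = 660.0  # g per mole per base pair
NG_PER_G = 1e9


def genomic_copies(conc_ng_per_ul: float, genome_size_bp: float) -> float:
    """Genomic copies per µL from concentration (ng/µL) and genome size (bp)."""
    if conc_ng_per_ul < 0:
        raise ValueError("concentration must be ≥ 0")
    if genome_size_bp < 1:
        raise ValueError("genome size must be ≥ 1 bp")
    return conc_ng_per_ul * AVOGADRO / (genome_size_bp * BP_MOLAR_MASS) / NG_PER_G


@dataclass(frozen=True)
class GenomicSample:
    sample_id: str
    conc_ng_per_ul: float
    genome_size_bp: float

    @property
    def copies_per_ul(self) -> float:
        return genomic_copies(self.conc_ng_per_ul, self.genome_size_bp)


def equal_copy_pool(
    samples: Iterable[GenomicSample], total_volume: float
) -> dict[str, float]:
    """Per-sample volumes (µL) so each member contributes equal copies.

    volume_i ∝ 1/copies_per_ul_i, normalised to total_volume.
    """
    samples = list(samples)
    if total_volume <= 0:
        raise ValueError("total_volume must be > 0")
    copies = {}
    for s in samples:
        c = s.copies_per_ul
        if c <= 0:
            raise InfeasiblePoolError(
                f"{s.sample_id}: zero copies/µL — equal-copy pooling infeasible"
            )
        copies[s.sample_id] = c
    inv_sum = sum(1.0 / c for c in copies.values())
    return {sid: total_volume * (1.0 / c) / inv_sum for sid, c in copies.items()}


def absolute_to_relative(
    counts: Mapping[str, float], drop: Optional[Iterable[str]] = None
) -> dict[str, float]:
    """Relative abundance from absolute copies/µL.

    Members in ``drop`` are excluded from numerator and denominator (e.g. an
    organism for which no specific primers could be designed).
    """
    dropped = set(drop) if drop else set()
    kept = {m: c for m, c in counts.items() if m not in dropped}
    if any(c < 0 for c in kept.values()):
        raise ValueError("counts must be ≥ 0")
    total = sum(kept.values())
    if not kept or total <= 0:
        raise UndefinedCompositionError(
            "relative abundance undefined: no positive counts after drops"
        )
    return {m: c / total for m, c in kept.items()}


def read_samples_tsv(path: str | os.PathLike) -> list[GenomicSample]:
    """Read a (sample_id, conc_ng_per_ul, genome_size_bp) TSV with header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "conc_ng_per_ul", "genome_size_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GenomicSample(str(r.sample_id), float(r.conc_ng_per_ul), float(r.genome_size_bp))
        for r in df.itertuples(index=False)
    ]
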