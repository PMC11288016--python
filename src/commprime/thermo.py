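"""Oligo physical chemistry: melting temperature, GC content, and
complementarity (dimer/hairpin) scores used as primer hard filters.

Melting temperature follows the unified nearest-neighbor model of
SantaLucia (1998) / Allawi & SantaLucia (1997): ΔH°/ΔS° summed over
dinucleotide stacks plus per-terminus initiation terms, with

    Tm = ΔH·1000 / (ΔS + R·ln(C/4)) − 273.15

at 1 M Na+ (C = total oligo concentration, excess-primer convention), then
salt-corrected on the inverse-temperature scale with the Owczarzy (2004)
monovalent and Owczarzy (2008) divalent equations, including Mg2+ chelation
by dNTPs (Ka = 3·10⁴ M⁻¹).  Default conditions are the common PCR defaults:
50 mM monovalent, 1.5 mM Mg2+, 0.6 mM dNTPs, 250 nM oligo.

Complementarity scores are ungapped antiparallel alignment scores
(match +1, mismatch −1, floored at 0) over all offsets — the classic
SELF_ANY / SELF_END style dimer filters; the hairpin score is the self-fold
variant with a minimum loop of three bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from ._seq import reverse_complement

R_GAS = 1.987  # cal / (K · mol)

# ΔH (kcal/mol), ΔS (cal/mol·K) per propagation step; unified NN parameters.
_NN_RAW = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# duplex symmetry: XY and its reverse complement are the same stack
NN_TABLE = dict(_NN_RAW)
for _d, _v in _NN_RAW.items():
    NN_TABLE.setdefault(reverse_complement(_d), _v)

_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ThermoConditions:
    """Buffer and oligo concentrations behind the Tm model."""

    monovalent_mM: float = 50.0
    divalent_mM: float = 1.5
    dntp_mM: float = 0.6
    oligo_nM: float = 250.0

    def __post_init__(self) -> None:
        for name in ("monovalent_mM", "divalent_mM", "dntp_mM", "oligo_nM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


@dataclass(frozen=True)
class OligoProfile:
    seq: str
    tm_c: float
    gc_pct: float
    self_any: int
    self_end: int
    hairpin: int

    @property
    def length(self) -> int:
        return len(self.seq)


def _check_acgt(seq: str, minlen: int = 1, maxlen: int | None = None) -> None:
    if not seq or set(seq) - set("ACGT"):
        raise ValueError(f"oligo must be non-empty over A/C/G/T, got {seq!r}")
    if len(seq) < minlen or (maxlen is not None and len(seq) > maxlen):
        raise ValueError(f"oligo length {len(seq)} outside [{minlen}, {maxlen}]")


def gc_content(seq: str) -> float:
    """GC percentage in [0, 100] (exact rational, returned as float)."""
    _check_acgt(seq)
    gc = seq.count("G") + seq.count("C")
    return float(Fraction(100 * gc, len(seq)))


def _free_magnesium_M(cond: ThermoConditions) -> float:
    """Free Mg2+ after dNTP chelation (quadratic in total Mg, Ka=3e4/M)."""
    mg = cond.divalent_mM * 1e-3
    dntp = cond.dntp_mM * 1e-3
    if dntp <= 0:
        return mg
    ka = 3.0e4
    b = ka * dntp - ka * mg + 1.0
    return (-b + math.sqrt(b * b + 4.0 * ka * mg)) / (2.0 * ka)


def _salt_inverse_tm_correction(seq: str, cond: ThermoConditions) -> float:
    """Owczarzy correction term added to 1/Tm (units 1/K)."""
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    mon = cond.monovalent_mM * 1e-3
    mg = _free_magnesium_M(cond)

    def monovalent_only() -> float:
        return (4.29 * fgc - 3.95) * 1e-5 * math.log(mon) + 9.40e-6 * math.log(
            mon
        ) ** 2

    if mg <= 0:
        if mon <= 0:
            raise ValueError("at least one of monovalent or divalent salt required")
        return monovalent_only()

    a, b, c, d = 3.92, -0.911, 6.26, 1.42
    e, f, g = -48.2, 52.5, 8.31
    if mon > 0:
        ratio = math.sqrt(mg) / mon
        if ratio < 0.22:
            return monovalent_only()
        if ratio < 6.0:
            lnm = math.log(mon)
            a = 3.92 * (0.843 - 0.352 * math.sqrt(mon) * lnm)
            d = 1.42 * (1.279 - 4.03e-3 * lnm - 8.03e-3 * lnm**2)
            g = 8.31 * (0.486 - 0.258 * lnm + 5.25e-3 * lnm**3)
    lnmg = math.log(mg)
    n_bp = len(seq)
    return (
        a
        + b * lnmg
        + fgc * (c + d * lnmg)
        + (1.0 / (2.0 * (n_bp - 1))) * (e + f * lnmg + g * lnmg**2)
    ) * 1e-5


def melting_temperature(seq: str, cond: ThermoConditions = ThermoConditions()) -> float:
    """Duplex melting temperature (°C) of an 8–36-mer against its perfect
    complement under the given conditions."""
    _check_acgt(seq, minlen=8, maxlen=36)
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        ih, is_ = _INIT_AT if end in "AT" else _INIT_GC
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        nh, ns = NN_TABLE[seq[i : i + 2]]
        dh += nh
        ds += ns
    conc = cond.oligo_nM * 1e-9 / 4.0
    tm_kelvin = dh * 1000.0 / (ds + R_GAS * math.log(conc))
    corr = _salt_inverse_tm_correction(seq, cond)
    return 1.0 / (1.0 / tm_kelvin + corr) - 273.15


def complementarity_scores(a: str, b: str) -> tuple[int, int]:
    """(any, end) ungapped antiparallel complementarity scores of two oligos.

    ``any``: best run score over all offsets (match +1 / mismatch −1,
    negative totals floored at 0).  ``end``: same, but the scored window must
    terminate at ``a``'s 3′-terminal base.
    """
    _check_acgt(a, 8, 36)
    _check_acgt(b, 8, 36)
    la, lb = len(a), len(b)
    rb = b[::-1]  # antiparallel: a read 5'→3' against b read 3'→5'
    best_any = 0
    best_end = 0
    for off in range(-(lb - 1), la):
        lo = max(0, off)
        hi = min(la, lb + off)
        # Kadane with floor 0 for 'any'
        run = 0
        for i in range(lo, hi):
            v = 1 if _PAIR[a[i]] == rb[i - off] else -1
            run = max(0, run + v)
            if run > best_any:
                best_any = run
        # windows ending exactly at a's 3' terminus
        if hi == la:
            total = 0
            for i in range(la - 1, lo - 1, -1):
                v = 1 if _PAIR[a[i]] == rb[i - off] else -1
                total += v
                if total > best_end:
                    best_end = total
    return best_any, best_end


def hairpin_score(a: str, min_loop: int = 3) -> int:
    """Self-fold complementarity score with a minimum loop of ``min_loop``
    unpaired bases between the two arms of the stem."""
    _check_acgt(a, 8, 36)
    n = len(a)
    best = 0
    for s in range(min_loop + 1, 2 * n - min_loop - 2):
        i_min = max(0, s - (n - 1))
        i_max = (s - min_loop - 1) // 2
        run = 0
        for i in range(i_min, i_max + 1):
            j = s - i
            if j == i:
                break
            v = 1 if _PAIR[a[i]] == a[j] else -1
            run = max(0, run + v)
            if run > best:
                best = run
    return best


def profile_oligo(seq: str, cond: ThermoConditions = ThermoConditions()) -> OligoProfile:
    any_, end_ = complementarity_scores(seq, seq)
    return OligoProfile(
        seq=seq,
        tm_c=melting_temperature(seq, cond),
        gc_pct=gc_content(seq),
        self_any=any_,
        self_end=end_,
        hairpin=hairpin_score(seq),
    )
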