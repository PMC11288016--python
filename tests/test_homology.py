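"""Alignment engine: seeding, banded extension, filters, and file IO.

The independent oracle here is a deliberately naive pure-Python
Smith–Waterman (`_sw_oracle`) that scores every cell and tracks the best
local path — no seeding, no banding, no shared code with the engine.
"""

import numpy as np
import pytest

from commprime import (
    StringencyParams,
    all_vs_all,
    kmer_candidate_pairs,
    load_external_hits,
    local_align,
    write_hits,
)
from commprime._seq import reverse_complement
from commprime.cds_io import CdsRecord, catalog_from_records
from commprime.errors import HitParseError, HitReferenceError
from commprime.homology import Scoring, passes_stringency, seeded_align
from commprime.synth import mutate_to_identity

MATCH, MISMATCH, GAP = 2, -3, -5


def _sw_oracle(a, b):
    """Plain O(mn) Smith–Waterman: returns (score, matches, columns)."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            h = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + GAP, H[i][j - 1] + GAP)
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback by recomputation (prefer diagonal, then up, then left)
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return best, matches, columns


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_identity_alignment_is_perfect():
    st = local_align("ACGTACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGTACGT")
    assert st.fident == 1.0
    assert st.columns == 24
    assert st.qstart == 0 and st.qend == 24


def test_full_sw_matches_naive_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = _random_seq(rng, int(rng.integers(60, 120)))
        b = mutate_to_identity(a, 0.9, int(rng.integers(0, 2**31)))
        # occasionally align unrelated pairs too
        if rng.random() < 0.3:
            b = _random_seq(rng, int(rng.integers(60, 120)))
        st = local_align(a, b)
        score, matches, columns = _sw_oracle(a, b)
        assert st.score == score
        if score > 0:
            assert st.columns == columns
            assert st.matches == matches


def test_seeded_engine_matches_full_sw_on_mutant_pairs():
    """Seed-and-extend must recover the exact optimum for homologous pairs."""
    rng = np.random.default_rng(11)
    for _ in range(30):
        a = _random_seq(rng, int(rng.integers(100, 500)))
        b = mutate_to_identity(a, float(rng.uniform(0.85, 1.0)), int(rng.integers(2**31)))
        full = local_align(a, b)
        seeded = seeded_align(a, b)
        assert seeded is not None
        assert seeded.score == full.score
        assert abs(seeded.fident - full.fident) <= 1.0 / max(full.columns, 1)


def test_mutant_fident_matches_planted_identity():
    a = "ACGTTGCA" * 40  # 320 bp
    b = mutate_to_identity(a, 0.99, 7)
    st = local_align(a, b)
    assert st.columns == 320
    assert st.fident == pytest.approx(1 - round(320 * 0.01) / 320, abs=1e-9)


def test_unrelated_repeats_fail_min_identity():
    a = "ACGT" * 50
    b = "TTAA" * 50
    st = local_align(a, b)
    # best local run is short and weak: under a 0.3-identity/30-column rule
    assert st.columns < 30 or st.fident < 0.3


def test_kmer_pairs_identical_random_and_revcomp():
    rng = np.random.default_rng(3)
    s1 = _random_seq(rng, 300)
    s2 = _random_seq(rng, 300)
    recs = [
        CdsRecord("g1", "g1|a", s1, "prokka", "target"),
        CdsRecord("g2", "g2|b", s1, "prokka", "target"),  # identical copy
        CdsRecord("g3", "g3|c", s2, "prokka", "target"),  # unrelated
        CdsRecord("g4", "g4|d", reverse_complement(s2), "prokka", "target"),
    ]
    pairs = kmer_candidate_pairs(catalog_from_records(recs), k=13)
    assert "+" in pairs[("g1|a", "g2|b")]
    assert ("g1|a", "g3|c") not in pairs
    assert "-" in pairs[("g3|c", "g4|d")]


def test_all_vs_all_self_hits_only_for_unrelated_genes():
    rng = np.random.default_rng(9)
    recs = [
        CdsRecord("g1", f"g1|g{i}", _random_seq(rng, 300), "prokka", "target")
        for i in range(5)
    ]
    hits = all_vs_all(catalog_from_records(recs))
    assert len(hits) == 5
    assert all(h.is_self for h in hits)


def test_planted_homolog_pair_reported_both_ways(gut_catalog, gut_hits):
    cross = [h for h in gut_hits if not h.is_self]
    assert cross, "expected planted families to produce cross hits"
    keys = {(h.query_id, h.target_id) for h in cross}
    assert all((t, q) in keys for q, t in keys)  # mirrored rows present


def test_raising_min_identity_removes_cross_hits(gut_catalog):
    lax = all_vs_all(gut_catalog, StringencyParams(min_identity=0.3))
    strict = all_vs_all(gut_catalog, StringencyParams(min_identity=0.99))
    assert sum(not h.is_self for h in strict) < sum(not h.is_self for h in lax)
    # filter monotonicity: strict cross set is a subset of the lax one
    lax_keys = {(h.query_id, h.target_id) for h in lax}
    assert {(h.query_id, h.target_id) for h in strict} <= lax_keys
    # self-hits are never filtered
    assert sum(h.is_self for h in strict) == len(gut_catalog)


def test_symmetry_under_cov_mode_both(gut_catalog):
    hits = all_vs_all(gut_catalog, StringencyParams(min_coverage=0.8, cov_mode="both"))
    keys = {(h.query_id, h.target_id) for h in hits if not h.is_self}
    assert all((t, q) in keys for q, t in keys)


def test_hit_table_round_trip(gut_catalog, gut_hits, tmp_path):
    path = tmp_path / "hits.tsv"
    write_hits(gut_hits, path)
    back = load_external_hits(path, gut_catalog)
    assert len(back) == len(gut_hits)
    for orig, re in zip(gut_hits, back):
        assert (re.query_id, re.target_id) == (orig.query_id, orig.target_id)
        assert re.fident == pytest.approx(orig.fident, abs=5e-5)
        assert (re.qstart, re.qend, re.tstart, re.tend) == (
            orig.qstart, orig.qend, orig.tstart, orig.tend,
        )


def test_external_loader_spec_rows(tmp_path):
    cat = catalog_from_records(
        [CdsRecord("g1", "g1", "A" * 300, "prokka", "target")]
    )
    p = tmp_path / "hits.tsv"
    p.write_text("g1\tg1\t1.000\t300\t0\t0\t1\t300\t1\t300\t1e-50\t500\n")
    (hit,) = load_external_hits(p, cat)
    assert hit.is_self and hit.qcov == 1.0 and hit.fident == 1.0

    p.write_text("g1\tg1\t99.0\t300\t3\t0\t1\t300\t1\t300\t1e-50\t500\n")
    (hit,) = load_external_hits(p, cat)
    assert hit.fident == pytest.approx(0.99)

    p.write_text("gX\tg1\t1.0\t300\t0\t0\t1\t300\t1\t300\t1e-50\t500\n")
    with pytest.raises(HitReferenceError):
        load_external_hits(p, cat)

    p.write_text("g1\tg1\t1.0\t300\n")
    with pytest.raises(HitParseError, match="line 1"):
        load_external_hits(p, cat)


def test_passes_stringency_cov_modes():
    from commprime.homology import AlignmentHit

    h = AlignmentHit("a", "b", 0.9, 100, 10, 0, 0, 100, 0, 100, 200, "+", 0.9, 0.4)
    assert passes_stringency(h, StringencyParams(min_coverage=0.5, cov_mode="either"))
    assert not passes_stringency(h, StringencyParams(min_coverage=0.5, cov_mode="both"))
    assert passes_stringency(h, StringencyParams(min_coverage=0.5, cov_mode="query"))
    assert not passes_stringency(h, StringencyParams(min_coverage=0.5, cov_mode="target"))
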