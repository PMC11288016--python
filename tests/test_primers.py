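"""Primer pair enumeration, scoring, filtering, and community-level design.

The oracle for design_pairs is brute force: profile and score every window
pair from enumerate_candidates directly and take the same top-n."""

import numpy as np
import pytest

from commprime import (
    DesignParams,
    complementarity_scores,
    design_for_community,
    design_pairs,
    enumerate_candidates,
    gc_content,
    melting_temperature,
    profile_oligo,
    rank_candidates,
    score_primer,
)
from commprime._seq import reverse_complement
from commprime.cds_io import CdsRecord
from commprime.errors import ConfigurationError
from commprime.thermo import OligoProfile


def _gene(seq, gid="g|x", genome="g"):
    return CdsRecord(genome, gid, seq, "prokka", "target")


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _brute_force_pairs(gene, params):
    """Independent oracle: exhaustively score every enumerated window pair
    (profiles memoised per oligo sequence, with a cheap Tm/GC pre-screen so
    the exhaustive pairing stays tractable)."""
    memo = {}

    def scored_profile(seq):
        if seq not in memo:
            if (params.gc_clamp and not (set(seq[-2:]) & set("GC"))) or not (
                params.gc_min <= gc_content(seq) <= params.gc_max
            ):
                memo[seq] = (None, None)
            elif not (
                params.tm_min
                <= melting_temperature(seq, params.conditions)
                <= params.tm_max
            ):
                memo[seq] = (None, None)
            else:
                prof = profile_oligo(seq, params.conditions)
                pen, _ = score_primer(prof, params)
                memo[seq] = (prof, pen)
        return memo[seq]

    out = []
    for s, lf, e, lr in enumerate_candidates(gene.seq, params):
        fwd, fpen = scored_profile(gene.seq[s : s + lf])
        rev, rpen = scored_profile(reverse_complement(gene.seq[e - lr : e]))
        if fpen is None or rpen is None:
            continue
        dtm = abs(fwd.tm_c - rev.tm_c)
        if dtm > params.max_pair_tm_diff:
            continue
        x_any, x_end = complementarity_scores(fwd.seq, rev.seq)
        if x_any > params.max_self_any or x_end > params.max_self_end:
            continue
        out.append((fpen + rpen + params.w_pair_diff * dtm, s, e, fwd.seq, rev.seq))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    dedup, seen = [], set()
    for row in out:
        key = (row[3], row[4])
        if key not in seen:
            seen.add(key)
            dedup.append(row)
    return dedup


def test_gene_shorter_than_product_min_yields_nothing():
    assert enumerate_candidates("ACGT" * 30, DesignParams()) == []  # 120 bp
    counts = {}
    assert design_pairs(_gene("ACGT" * 30), rejection_counts=counts) == []
    assert counts.get("geometry") == 1


def test_enumerated_amplicons_within_bounds():
    params = DesignParams()
    seq = _random_seq(175, seed=1)
    for s, lf, e, lr in enumerate_candidates(seq, params):
        assert params.product_min <= e - s <= params.product_max
        assert e - lr >= s + lf  # non-overlapping primers


def test_polyx_windows_are_dropped():
    params = DesignParams(max_polyx=5)
    seq = _random_seq(200, seed=2)
    seq = seq[:50] + "AAAAAA" + seq[56:]
    for s, lf, e, lr in enumerate_candidates(seq, params):
        assert "AAAAAA" not in seq[s : s + lf]
        assert "AAAAAA" not in seq[e - lr : e]


def test_score_primer_arithmetic():
    params = DesignParams()
    ideal = OligoProfile("G" * 10 + "C" * 10, 62.0, 50.0, 0, 0, 0)
    assert score_primer(ideal, params) == (0.0, "")
    warm = OligoProfile("G" * 10 + "C" * 10, 63.2, 50.0, 0, 0, 0)
    pen, rule = score_primer(warm, params)
    assert rule == "" and pen == pytest.approx(1.2)
    hot = OligoProfile("G" * 10 + "C" * 10, 66.0, 50.0, 0, 0, 0)
    assert score_primer(hot, params) == (None, "tm")
    no_clamp = OligoProfile("G" * 10 + "C" * 8 + "AT", 62.0, 50.0, 0, 0, 0)
    assert score_primer(no_clamp, params) == (None, "gc_clamp")


def test_design_params_validation():
    with pytest.raises(ConfigurationError):
        DesignParams(tm_min=65, tm_opt=62, tm_max=59)
    with pytest.raises(ConfigurationError):
        DesignParams(product_min=200, product_max=150)


def test_design_pairs_matches_brute_force_oracle():
    params = DesignParams(n_return=8)
    for seed in (10, 11):
        gene = _gene(_random_seq(250, seed))
        got = design_pairs(gene, params)
        expected = _brute_force_pairs(gene, params)[: params.n_return]
        assert [(p.fwd_seq, p.rev_seq) for p in got] == [
            (r[3], r[4]) for r in expected
        ]
        for p, r in zip(got, expected):
            assert p.penalty_pair == pytest.approx(r[0])


def test_emitted_pairs_satisfy_run_settings():
    """Amplicon in [125, 175], |ΔTm| ≤ 1.5, and every table quantity
    recomputable from the emitted sequences."""
    params = DesignParams()
    pairs = []
    for seed in range(20, 26):
        pairs += design_pairs(_gene(_random_seq(700, seed)), params)
    assert pairs
    for p in pairs:
        assert 125 <= p.amplicon_bp <= 175
        assert abs(p.fwd.tm_c - p.rev.tm_c) <= 1.5
        # positional invariants
        assert p.gene_seq[p.fwd_start : p.fwd_start + p.fwd.length] == p.fwd_seq
        site = reverse_complement(p.rev_seq)
        assert p.gene_seq[p.rev_end - p.rev.length : p.rev_end] == site
        # thermodynamic quantities recompute exactly
        assert p.fwd.tm_c == melting_temperature(p.fwd_seq, params.conditions)
        assert p.rev.gc_pct == gc_content(p.rev_seq)
        assert p.penalty_pair == pytest.approx(
            p.penalty_fwd + p.penalty_rev + abs(p.fwd.tm_c - p.rev.tm_c)
        )


def test_design_is_deterministic():
    gene = _gene(_random_seq(500, seed=31))
    a = design_pairs(gene)
    b = design_pairs(gene)
    assert [(p.fwd_seq, p.rev_seq, p.penalty_pair) for p in a] == [
        (p.fwd_seq, p.rev_seq, p.penalty_pair) for p in b
    ]


def test_shrinking_product_range_never_adds_pairs():
    gene = _gene(_random_seq(300, seed=41))
    wide = DesignParams(product_min=125, product_max=175, n_return=10_000)
    narrow = DesignParams(product_min=140, product_max=160, n_return=10_000)
    wide_set = {(p.fwd_seq, p.rev_seq) for p in design_pairs(gene, wide)}
    narrow_set = {(p.fwd_seq, p.rev_seq) for p in design_pairs(gene, narrow)}
    assert narrow_set <= wide_set


def test_group_conservation_flags():
    gene_seq = _random_seq(400, seed=51)
    gene = _gene(gene_seq, "gA|m", "gA")
    exact = CdsRecord("gB", "gB|m", gene_seq, "prokka", "target")
    pairs = design_pairs(gene, conservation_targets=[exact])
    assert pairs and all(p.conservation == "exact_in_all_targets" for p in pairs)
    # mutate one base under the forward primer's 3' end of the first pair
    p0 = pairs[0]
    pos = p0.fwd_start + p0.fwd.length - 1
    mutated = gene_seq[:pos] + ("A" if gene_seq[pos] != "A" else "C") + gene_seq[pos + 1 :]
    diverged = CdsRecord("gB", "gB|m", mutated, "prokka", "target")
    pairs2 = design_pairs(gene, conservation_targets=[diverged])
    flag = {(p.fwd_seq, p.rev_seq): p.conservation for p in pairs2}
    assert flag[(p0.fwd_seq, p0.rev_seq)] == "mismatched"


def test_community_design_warns_on_empty_genomes(subsumed_catalog, subsumed_hits):
    from commprime import classify_unique

    calls, _ = classify_unique(subsumed_hits, subsumed_catalog)
    ranked = rank_candidates(calls, subsumed_catalog)
    rows, warnings = design_for_community(ranked, subsumed_catalog, DesignParams())
    labels = {lab for lab, _ in rows}
    assert "subsumed" not in labels
    assert any(w.startswith("subsumed:") for w in warnings)
    # donor genomes do get primers
    assert any(lab != "subsumed" for lab in labels)


def test_community_design_caps_pairs_per_genome(gut_catalog, gut_hits):
    from commprime import classify_unique

    calls, _ = classify_unique(gut_hits, gut_catalog)
    ranked = rank_candidates(calls, gut_catalog)
    params = DesignParams(n_return=3)
    rows, warnings = design_for_community(ranked, gut_catalog, params)
    per = {}
    for lab, p in rows:
        per[lab] = per.get(lab, 0) + 1
        assert gut_catalog.genome_of(p.gene_id) == lab
    assert set(per) == set(gut_catalog.target_genomes)
    assert all(n <= 3 for n in per.values())
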