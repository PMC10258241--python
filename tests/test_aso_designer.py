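"""ASO window generation, scoring oracles, ranking and mismatch controls."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from domainskip.aso_designer import (
    AsoCandidate,
    DesignCriteria,
    TargetRegion,
    TmParameters,
    antisense,
    build_target_region,
    check_design_guidelines,
    design_mismatch_control,
    ese_scan,
    filter_and_rank,
    gc_content,
    generate_windows,
    hairpin_score,
    load_ese_matrices,
    melting_temperature,
    published_aso_pairs,
    score_candidates,
    self_dimer_run,
    validate_mismatch_pair,
)
from domainskip.synthetic_fixtures import plant_ese

from test_gene_model import three_exon_gene

RNA = "ACGU"
_COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# target regions and windows
# ---------------------------------------------------------------------------

def test_region_size_and_offset(toy_tx):
    e = toy_tx.exon(4)
    region = build_target_region(toy_tx, 4, flank_nt=50)
    assert len(region.sequence) == len(e) + 100
    assert region.exon_offset == (50, 50 + len(e))
    assert region.exon_seq == e.seq


def test_truncated_flank_warns(toy_tx, caplog):
    # the fixture chromosome has 60 nt before exon 1
    with caplog.at_level("WARNING"):
        region = build_target_region(toy_tx, 1, flank_nt=500)
    assert any("truncated" in r.message for r in caplog.records)
    assert region.exon_offset[0] < 500


def test_minus_strand_region_matches_plus_twin():
    plus, minus = three_exon_gene("+"), three_exon_gene("-")
    rp = build_target_region(plus, 2, flank_nt=20)
    rm = build_target_region(minus, 2, flank_nt=20)
    assert rp.sequence == rm.sequence
    assert rp.exon_offset == rm.exon_offset


def test_window_enumeration_matches_brute_force():
    seq = "".join(random.Random(11).choice("ACGT") for _ in range(220))
    region = TargetRegion(1, seq, 50, (50, 170))
    cands = generate_windows(region, 17, 23)
    expected = set()
    for L in range(17, 24):
        for a in range(0, 220 - L + 1):
            if a + L > 50 and a < 170:
                expected.add((a, a + L))
    assert {c.window for c in cands} == expected
    for c in cands:
        a, b = c.window
        assert c.category == ("boundary" if (a < 50 < b) or (a < 170 < b) else "exonic_ese")


def test_boundary_category():
    seq = "A" * 220
    region = TargetRegion(1, seq, 50, (50, 170))
    cands = {c.window: c for c in generate_windows(region)}
    assert cands[(48, 70)].category == "boundary"
    assert cands[(60, 80)].category == "exonic_ese"


def test_antisense_is_reverse_complement():
    assert antisense("ACCTGG") == "CCAGGU"
    assert antisense("ACCUGG") == "CCAGGU"


def test_every_candidate_occurs_in_region(toy_tx):
    region = build_target_region(toy_tx, 5, flank_nt=30)
    sense_rna = region.sequence.replace("T", "U")
    for c in generate_windows(region):
        back = "".join(_COMP[b] for b in reversed(c.sequence))
        assert back in sense_rna


# ---------------------------------------------------------------------------
# GC and Tm
# ---------------------------------------------------------------------------

def test_gc_content_of_published_leads():
    pairs = {r["name"]: r["aso"] for r in published_aso_pairs()}
    assert gc_content(pairs["ASO_39D"]) == pytest.approx(10 / 19)
    assert gc_content(pairs["ASO_40A"]) == pytest.approx(9 / 23)
    assert gc_content("GGCC") == 1.0


def test_gc_content_rejects_ambiguity():
    with pytest.raises(ValueError):
        gc_content("ACGN")


# independently re-typed nearest-neighbor parameters (dH kcal/mol, dS eu)
_ORACLE_NN = {
    "AA": (-6.82, -19.0), "AU": (-9.38, -26.7), "UA": (-7.69, -20.5),
    "CU": (-10.48, -27.1), "CA": (-10.44, -26.9), "GU": (-11.40, -29.5),
    "GA": (-12.44, -32.5), "CG": (-10.64, -26.7), "GG": (-13.39, -32.7),
    "GC": (-14.88, -36.9),
}


def _oracle_tm(seq, ct=250e-9, na=0.1):
    """Spreadsheet-style hand summation of stack enthalpies/entropies."""
    dh, ds = 3.61, -1.5
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if d not in _ORACLE_NN:
            d = _COMP[seq[i + 1]] + _COMP[seq[i]]
        h, s = _ORACLE_NN[d]
        dh += h
        ds += s
    dh += 3.72 * sum(seq[k] in "AU" for k in (0, -1))
    ds += 10.5 * sum(seq[k] in "AU" for k in (0, -1))
    tm = dh * 1000 / (ds + 1.9872 * math.log(ct / 4)) - 273.15
    return tm + 16.6 * math.log10(na)


@pytest.mark.parametrize("seed", range(10))
def test_tm_matches_hand_summed_oracle(seed):
    rng = random.Random(seed)
    seq = "".join(rng.choice(RNA) for _ in range(rng.randint(10, 23)))
    assert melting_temperature(seq) == pytest.approx(_oracle_tm(seq), abs=1e-9)


def test_tm_invariant_under_duplex_reversal():
    """Reading the duplex from the other end (the complement strand 5'->3')
    visits the same stack set, so Tm is identical."""
    for seq in ("CUGGAGUUGGUAUCUGGGA", "GCGCAUAUGGCC", "AAGGCCUUAAGG"):
        rev = "".join(_COMP[b] for b in reversed(seq))
        assert melting_temperature(seq) == pytest.approx(melting_temperature(rev))


def test_tm_monotone_under_gc_extension():
    """Appending GC-rich stacks never lowers the Tm."""
    rng = random.Random(42)
    for _ in range(20):
        seq = "".join(rng.choice(RNA) for _ in range(12))
        assert melting_temperature(seq + "GC") >= melting_temperature(seq)
        assert melting_temperature("GC" + seq) >= melting_temperature(seq)


def test_tm_agrees_with_independent_nn_implementation():
    """Cross-check against Biopython's Xia-98 RNA nearest-neighbor table
    under matched conditions (1 M Na+, 125 nM per strand)."""
    from Bio.SeqUtils import MeltingTemp as mt

    for seq in ("CUGGAGUUGGUAUCUGGGA", "UAGCUUAACGAUGCAGAAGGAUU", "GCGCGCGCAU"):
        mine = melting_temperature(seq, TmParameters(na_m=1.0))
        ref = mt.Tm_NN(seq.replace("U", "T"), nn_table=mt.RNA_NN2,
                       dnac1=125, dnac2=125, Na=1000, saltcorr=0)
        assert mine == pytest.approx(ref, abs=0.05)


def test_tm_rejects_dna_only_garbage():
    with pytest.raises(ValueError):
        melting_temperature("ACGUXACGUA")


# ---------------------------------------------------------------------------
# ESE scanning
# ---------------------------------------------------------------------------

def _flat_region(exon_seq, flank=20):
    seq = "A" * flank + exon_seq + "A" * flank
    return TargetRegion(1, seq, flank, (flank, flank + len(exon_seq)))


def test_scan_scores_equal_brute_force():
    matrices = load_ese_matrices()
    rng = random.Random(7)
    exon = "".join(rng.choice("ACGT") for _ in range(30))
    region = _flat_region(exon)
    hits = ese_scan(region, matrices)
    expected = []
    for m in matrices:
        for off in range(30 - m.width + 1):
            window = exon[off : off + m.width].replace("T", "U")
            sc = sum(m.weights[i]["ACGU".index(b)] for i, b in enumerate(window))
            if sc >= m.threshold:
                expected.append((m.factor, 20 + off, pytest.approx(sc)))
    got = [(h.factor, h.position, h.score) for h in hits]
    assert sorted(got) == sorted(expected, key=lambda t: (t[1], t[0]))


def test_planted_consensus_recovered_at_offset():
    matrices = load_ese_matrices()
    srsf1 = next(m for m in matrices if m.factor == "SRSF1")
    region = _flat_region("A" * 30)
    planted = plant_ese(region, srsf1, 10)
    hits = [h for h in ese_scan(planted, [srsf1])]
    assert [(h.position, h.score) for h in hits] == [(30, pytest.approx(srsf1.max_score))]


def test_mutated_plant_drops_below_threshold():
    matrices = load_ese_matrices()
    srsf1 = next(m for m in matrices if m.factor == "SRSF1")
    region = _flat_region("A" * 30)
    planted = plant_ese(region, srsf1, 10)
    # knock the strongest position down to the worst base
    pos = 20 + 10 + 5  # matrix position 6 (G, weight 1.5 -> U, -1.9)
    seq = planted.sequence[:pos] + "T" + planted.sequence[pos + 1 :]
    mutated = TargetRegion(1, seq, 20, planted.exon_offset)
    assert ese_scan(mutated, [srsf1]) == []


def test_two_plants_give_two_hits():
    matrices = load_ese_matrices()
    srsf1 = next(m for m in matrices if m.factor == "SRSF1")
    region = _flat_region("A" * 40)
    planted = plant_ese(plant_ese(region, srsf1, 2), srsf1, 20)
    assert [h.position for h in ese_scan(planted, [srsf1])] == [22, 40]


def test_plant_in_flank_is_fatal():
    matrices = load_ese_matrices()
    srsf1 = matrices[0]
    region = _flat_region("A" * 30)
    with pytest.raises(ValueError, match="exon"):
        plant_ese(region, srsf1, 28)  # motif would run past the exon end


def test_zero_hits_on_hostile_background():
    region = _flat_region("T" * 40)
    assert ese_scan(region, load_ese_matrices()) == []


# ---------------------------------------------------------------------------
# self-structure
# ---------------------------------------------------------------------------

def _enumerate_max_pairs(s, i=0, j=None):
    """Exhaustive enumeration of nested pairings (min loop 3, WC+GU)."""
    pairs = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
    if j is None:
        j = len(s) - 1
    if i >= j:
        return 0
    best = _enumerate_max_pairs(s, i + 1, j)  # i unpaired
    for k in range(i + 4, j + 1):
        if (s[i], s[k]) in pairs:
            best = max(
                best,
                1 + _enumerate_max_pairs(s, i + 1, k - 1) + _enumerate_max_pairs(s, k + 1, j),
            )
    return best


def test_hairpin_examples():
    assert hairpin_score("AAAAAAAAAA") == 0
    assert hairpin_score("GGGGAAAACCCC") == 4
    assert self_dimer_run("AAAAAAAAAA") == 0
    assert self_dimer_run("GGGGCCCC") == 8


def test_hairpin_matches_exhaustive_enumeration():
    rng = random.Random(123)
    for _ in range(200):
        n = rng.randint(4, 12)
        s = "".join(rng.choice(RNA) for _ in range(n))
        assert hairpin_score(s) == _enumerate_max_pairs(s), s


def test_structure_bounds():
    rng = random.Random(5)
    for _ in range(50):
        n = rng.randint(8, 23)
        s = "".join(rng.choice(RNA) for _ in range(n))
        assert 0 <= hairpin_score(s) <= (n - 3) // 2
        assert 0 <= self_dimer_run(s) <= n


# ---------------------------------------------------------------------------
# filtering and ranking
# ---------------------------------------------------------------------------

def _cand(id_, tm=60.0, length=20, category="exonic_ese", window=(0, 20)):
    return AsoCandidate(id_, 1, window, "A" * length, length, category, tm_c=tm)


def test_tm_below_threshold_is_hard_filtered():
    ok = _cand("ok", tm=48.0)
    cold = _cand("cold", tm=47.9)
    kept = filter_and_rank([ok, cold])
    assert [c.id for c in kept] == ["ok"]


def test_more_ese_hits_ranks_higher():
    """Of two otherwise comparable exon-internal windows, the one covering a
    splicing-enhancer motif outranks the one that covers none."""
    srsf1 = next(m for m in load_ese_matrices() if m.factor == "SRSF1")
    region = plant_ese(_flat_region("G" * 60, flank=20), srsf1, 5)
    hits = ese_scan(region, [srsf1])
    assert len(hits) == 1
    cands = {c.window: c for c in generate_windows(region, 20, 20)}
    over = cands[(23, 43)]    # covers the motif planted at region pos 25
    away = cands[(40, 60)]    # same length, same category, no motif
    score_candidates([over, away], hits)
    assert over.ese_hits > away.ese_hits == 0
    assert over.rank_score > away.rank_score


def test_full_ranking_matches_score_oracle(toy_tx):
    """Ranking equals an independent recomputation of the documented score."""
    crit = DesignCriteria()
    region = build_target_region(toy_tx, 7, flank_nt=50)
    cands = generate_windows(region)[:60]
    hits = ese_scan(region, load_ese_matrices())
    score_candidates(cands, hits, crit)
    ranked = filter_and_rank(cands, crit)

    def oracle_score(c):
        lo, hi = crit.gc_range
        gc_pen = max(0.0, lo - c.gc_fraction, c.gc_fraction - hi)
        return (
            crit.w_boundary * (c.category == "boundary")
            + crit.w_ese * c.ese_hits
            - crit.w_gc * gc_pen
            - crit.w_structure * max(0, c.hairpin_pairs - crit.hairpin_cap)
            - crit.w_structure * max(0, c.self_dimer_run - crit.dimer_cap)
        )

    expected = sorted(
        [c for c in cands if c.tm_c >= crit.tm_min],
        key=lambda c: (-oracle_score(c), c.window[0], c.length_nt, c.id),
    )
    assert [c.id for c in ranked] == [c.id for c in expected]
    for c in ranked:
        assert c.rank_score == pytest.approx(oracle_score(c))


def test_gc_guideline_is_soft():
    """A published lead below the 40% GC floor is flagged, never rejected."""
    pairs = {r["name"]: r for r in published_aso_pairs()}
    seq = pairs["ASO_40A"]["aso"]
    c = AsoCandidate("ASO_40A", 40, (0, len(seq)), seq, len(seq), "exonic_ese")
    c.gc_fraction = gc_content(seq)
    c.tm_c = melting_temperature(seq)
    flags = check_design_guidelines(c)
    assert "gc_below_range" in flags
    assert filter_and_rank([c]) == [c]  # survives the hard filters


# ---------------------------------------------------------------------------
# mismatch controls
# ---------------------------------------------------------------------------

def test_published_pairs_validate():
    for r in published_aso_pairs():
        v = validate_mismatch_pair(r["aso"], r["mmaso"])
        assert v["n_mismatches"] == 4, r["name"]
        assert v["all_interior"], r["name"]


def test_published_39d_mismatch_positions():
    pairs = {r["name"]: r for r in published_aso_pairs()}
    v = validate_mismatch_pair(pairs["ASO_39D"]["aso"], pairs["ASO_39D"]["mmaso"])
    assert v["mismatch_positions"] == (4, 6, 10, 17)


@given(st.text(alphabet=RNA, min_size=17, max_size=23), st.integers(0, 1000))
def test_generated_controls_have_four_interior_mismatches(seq, seed):
    ctrl = design_mismatch_control(seq, seed=seed)
    v = validate_mismatch_pair(seq, ctrl.sequence)
    assert v["n_mismatches"] == 4
    assert v["all_interior"]
    assert v["mismatch_positions"] == ctrl.mismatch_positions


def test_control_generation_is_seed_reproducible():
    seq = "CUGGAGUUGGUAUCUGGGA"
    a = design_mismatch_control(seq, seed=7)
    b = design_mismatch_control(seq, seed=7)
    c = design_mismatch_control(seq, seed=8)
    assert a == b
    assert c.sequence != a.sequence or c.mismatch_positions != a.mismatch_positions


def test_control_rejects_short_oligo():
    with pytest.raises(ValueError):
        design_mismatch_control("ACGUACGUACG", seed=1)  # 11 nt

    with pytest.raises(ValueError):
        design_mismatch_control("ACGUACGUACGU", n=8, seed=1)
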