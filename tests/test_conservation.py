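"""Lift-over, sliding windows, alignment, per-method classification and call
merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncsynt import conservation as cons
from lncsynt.core_io import Chain, GenomicInterval, ScoreTrack
from lncsynt.synthetic_data import CONSERVED_CLASSES


def make_chain(blocks, t_start=0, q_start=0, q_strand="+", t_size=10_000,
               q_size=10_000, t_name="chrT", q_name="chrQ"):
    t_end = t_start + sum(s + dt for s, dt, _ in blocks)
    q_end = q_start + sum(s + dq for s, _, dq in blocks)
    c = Chain(0, t_name, t_size, "+", t_start, t_end,
              q_name, q_size, q_strand, q_start, q_end, blocks, "c")
    c.validate()
    return c


# ---------------------------------------------------------------------------
# lift_interval
# ---------------------------------------------------------------------------

def test_lift_identity_chain():
    c = make_chain([(1000, 0, 0)])
    iv = GenomicInterval("chrT", 100, 200)
    out = cons.lift_interval(iv, [c])
    assert (out.chrom, out.start, out.end) == ("chrQ", 100, 200)


def test_lift_partial_block_envelope():
    """Interval half inside a block maps to the covered half's envelope."""
    c = make_chain([(100, 0, 0)], t_start=0, q_start=500)
    iv = GenomicInterval("chrT", 50, 150)    # bases 50..99 covered
    out = cons.lift_interval(iv, [c], min_map_fraction=0.5)
    assert (out.start, out.end) == (550, 600)
    assert cons.lift_interval(iv, [c], min_map_fraction=0.6) is None


def test_lift_gap_returns_none():
    c = make_chain([(50, 100, 100), (50, 0, 0)])
    iv = GenomicInterval("chrT", 60, 140)    # inside the dt gap
    assert cons.lift_interval(iv, [c]) is None


def test_lift_minus_strand_resolves_forward_coordinates():
    c = make_chain([(100, 0, 0)], q_start=200, q_strand="-", q_size=1000)
    iv = GenomicInterval("chrT", 10, 20)
    out = cons.lift_interval(iv, [c])
    # chain-system query coords 210..220 -> forward 1000-220 .. 1000-210
    assert (out.start, out.end) == (780, 790)


def brute_lift(iv, chains, min_map_fraction):
    """Independent per-base chain walker."""
    best = None
    for ch in chains:
        if ch.t_name != iv.chrom:
            continue
        fw = []
        tpos, qpos = ch.t_start, ch.q_start
        for size, dt, dq in ch.blocks:
            for o in range(size):
                t = tpos + o
                if iv.start <= t < iv.end:
                    q = qpos + o
                    fw.append(ch.q_size - 1 - q if ch.q_strand == "-" else q)
            tpos += size + dt
            qpos += size + dq
        if fw and (best is None or len(fw) > best[0]):
            best = (len(fw), min(fw), max(fw) + 1, ch.q_name)
    if best is None or best[0] / len(iv) < min_map_fraction:
        return None
    return (best[3], best[1], best[2])


def random_chain(rng, t_name="chrT"):
    nb = int(rng.integers(1, 8))
    blocks = [
        [int(rng.integers(1, 200)), int(rng.integers(0, 100)),
         int(rng.integers(0, 100))]
        for _ in range(nb)
    ]
    blocks[-1][1] = blocks[-1][2] = 0
    blocks = [tuple(b) for b in blocks]
    return make_chain(
        blocks,
        t_start=int(rng.integers(0, 2000)),
        q_start=int(rng.integers(0, 2000)),
        q_strand="+" if rng.random() < 0.5 else "-",
        t_name=t_name,
    )


def test_lift_matches_brute_force_walker_small():
    rng = np.random.default_rng(7)
    chains = [random_chain(rng) for _ in range(5)]
    for _ in range(100):
        s = int(rng.integers(0, 4000))
        iv = GenomicInterval("chrT", s, s + int(rng.integers(1, 400)))
        got = cons.lift_interval(iv, chains, 0.5)
        want = brute_lift(iv, chains, 0.5)
        got_t = None if got is None else (got.chrom, got.start, got.end)
        assert got_t == want


# ---------------------------------------------------------------------------
# window_max_mean
# ---------------------------------------------------------------------------

def test_window_constant_array():
    assert cons.window_max_mean(np.full(300, 0.6)) == pytest.approx(0.6)


def test_window_max_of_high_block():
    arr = np.concatenate([np.ones(200), np.zeros(200)])
    assert cons.window_max_mean(arr) == pytest.approx(1.0)


def test_window_short_array_single_window():
    assert cons.window_max_mean(np.array([0.2, 0.4])) == pytest.approx(0.3)


def test_window_empty_rejected():
    with pytest.raises(ValueError):
        cons.window_max_mean(np.array([]))


def naive_window_max(arr, window=200, step=50):
    return max(
        np.mean(arr[o : o + window]) for o in range(0, len(arr), step)
    )


@settings(derandomize=True, deadline=None, max_examples=100)
@given(st.integers(1, 700), st.integers(0, 10_000))
def test_window_matches_naive_enumeration(length, seed):
    arr = np.random.default_rng(seed).random(length)
    assert cons.window_max_mean(arr) == pytest.approx(naive_window_max(arr))


# ---------------------------------------------------------------------------
# align_pair / reciprocal best hits
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def rng_seqs():
    rng = np.random.default_rng(3)

    def make(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    return rng, make


def test_identical_sequences_align_full_identity(rng_seqs):
    _, make = rng_seqs
    s = make(300)
    hit = cons.align_pair(s, s, min_identity=0.8)
    assert hit.identity == pytest.approx(1.0)
    assert hit.evalue < 1e-20


def test_unrelated_sequences_no_hit_at_evalue(rng_seqs):
    _, make = rng_seqs
    for _ in range(10):
        a, b = make(300), make(300)
        assert cons.align_pair(a, b, max_evalue=1e-5) is None


def test_reverse_complement_invisible_on_plus_strand(rng_seqs):
    from lncsynt.core_io import reverse_complement

    _, make = rng_seqs
    s = make(300)
    rc = reverse_complement(s)
    assert cons.align_pair(s, rc, max_evalue=1e-5, strand="plus") is None
    hit = cons.align_pair(s, rc, max_evalue=1e-5, strand="both")
    assert hit is not None and hit.identity == pytest.approx(1.0)


def test_non_nucleotide_rejected():
    with pytest.raises(ValueError):
        cons.align_pair("ACGT", "ACXT")


def _hit(q, t, bits, ident=1.0):
    return cons.AlignmentHit(q, t, ident, 1e-10, bits)


def test_reciprocal_best_hits_mutual_kept():
    ab = [_hit("a", "b", 100)]
    ba = [_hit("b", "a", 100)]
    assert cons.reciprocal_best_hits(ab, ba) == [("a", "b")]


def test_reciprocal_best_hits_asymmetric_dropped():
    ab = [_hit("a", "b", 100)]
    ba = [_hit("b", "c", 100)]
    assert cons.reciprocal_best_hits(ab, ba) == []
    assert cons.reciprocal_best_hits([], []) == []


def test_best_hit_tie_breaks_by_identity_then_id():
    hits = [_hit("a", "c", 100, 0.9), _hit("a", "b", 100, 0.9),
            _hit("a", "d", 100, 0.95)]
    back = [_hit("d", "a", 100)]
    assert cons.reciprocal_best_hits(hits, back) == [("a", "d")]


# ---------------------------------------------------------------------------
# symbol method
# ---------------------------------------------------------------------------

def _sym_gene(gid, symbol, species):
    from lncsynt.core_io import GeneModel, TranscriptModel

    tx = TranscriptModel(f"{gid}.t", [GenomicInterval("c", 0, 100, "+")])
    return GeneModel(gid, "lncRNA", species, [tx], symbol)


def test_symbol_whitelisted_pair_flagged():
    h = [_sym_gene("h1", "XIST", "human")]
    m = [_sym_gene("m1", "Xist", "mouse")]
    assert cons.classify_by_symbol(h, m, ["XIST"]) == [("h1", "m1")]


def test_symbol_not_whitelisted_not_flagged():
    h = [_sym_gene("h1", "FOO", "human")]
    m = [_sym_gene("m1", "Foo", "mouse")]
    assert cons.classify_by_symbol(h, m, ["XIST"]) == []
    assert cons.classify_by_symbol(h, m, []) == []


def test_symbol_duplicates_pair_all_combinations():
    h = [_sym_gene("h1", "XIST", "human"), _sym_gene("h2", "XIST", "human")]
    m = [_sym_gene("m1", "Xist", "mouse")]
    assert cons.classify_by_symbol(h, m, ["XIST"]) == [
        ("h1", "m1"), ("h2", "m1"),
    ]


# ---------------------------------------------------------------------------
# merge_calls
# ---------------------------------------------------------------------------

def test_merge_two_methods_is_high_confidence():
    calls, tiers = cons.merge_calls(
        {"global": [("h", "m")], "sequence": [("h", "m")]}
    )
    assert calls[0].tier == "high_confidence"
    assert calls[0].n_methods == 2
    assert tiers["h"] == tiers["m"] == "high_confidence"


def test_merge_single_method_is_conserved():
    calls, _ = cons.merge_calls({"promoter": [("h", "m")]})
    assert calls[0].tier == "conserved"


def test_merge_unflagged_genes_non_conserved(fixture):
    _, tiers = cons.merge_calls(
        {"symbol": []}, fixture.lnc("human"), fixture.lnc("mouse")
    )
    assert set(tiers.values()) == {"non_conserved"}


@settings(derandomize=True, deadline=None, max_examples=100)
@given(st.sets(st.sampled_from(cons.METHODS)),
       st.sampled_from(cons.METHODS))
def test_merge_tier_monotone_in_flags(flags, extra):
    """Adding a method flag never lowers the tier."""
    rank = {"non_conserved": 0, "conserved": 1, "high_confidence": 2}
    base = {m: [("h", "m")] for m in flags}
    more = {m: [("h", "m")] for m in flags | {extra}}
    t1 = cons.merge_calls(base)[0][0].tier if flags else "non_conserved"
    t2 = cons.merge_calls(more)[0][0].tier
    assert rank[t2] >= rank[t1]


# ---------------------------------------------------------------------------
# mean conservation score
# ---------------------------------------------------------------------------

def _lnc_on_track(values):
    from lncsynt.core_io import GeneModel, TranscriptModel

    tr = ScoreTrack()
    arr = tr.ensure("c", len(values))
    arr[:] = values
    tx = TranscriptModel("t", [GenomicInterval("c", 0, len(values), "+")])
    return GeneModel("g", "lncRNA", "human", [tx]), tr


def test_mean_score_constant():
    g, tr = _lnc_on_track(np.full(100, 0.3))
    assert cons.mean_conservation_score(g, tr) == pytest.approx(0.3)


def test_mean_score_half_and_half():
    g, tr = _lnc_on_track(np.concatenate([np.ones(50), np.zeros(50)]))
    assert cons.mean_conservation_score(g, tr) == pytest.approx(0.5)


def test_mean_score_missing_policy():
    vals = np.full(100, np.nan)
    vals[:50] = 1.0
    g, tr = _lnc_on_track(vals)
    assert cons.mean_conservation_score(g, tr, "zero") == pytest.approx(0.5)
    assert cons.mean_conservation_score(g, tr, "exclude") == pytest.approx(1.0)


def test_conserved_antisense_scores_exceed_nonconserved(fixture):
    """Planted elevated tracks separate the conserved and non-conserved
    antisense groups."""
    truth = fixture.truth
    cons_scores, non_scores = [], []
    for g in fixture.lnc("human"):
        if truth.position_class[g.gene_id] != "antisense":
            continue
        s = cons.mean_conservation_score(g, fixture.track_h)
        if truth.lnc_class[g.gene_id] in CONSERVED_CLASSES:
            cons_scores.append(s)
        else:
            non_scores.append(s)
    assert cons_scores and non_scores
    assert np.mean(cons_scores) > np.mean(non_scores)
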