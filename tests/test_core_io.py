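"""Domain types, format round-trips, and coordinate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncsynt.core_io import (
    Chain,
    ChainIntegrityError,
    GenomicInterval,
    interval_overlap,
    nearest_flanking,
    parse_chain,
    parse_gene_annotation,
    parse_score_track,
    write_chain,
    write_gene_annotation,
)


def make_gene(gid, chrom, exons, strand="+", biotype="coding"):
    from lncsynt.core_io import GeneModel, TranscriptModel

    tx = TranscriptModel(
        f"{gid}.t1", [GenomicInterval(chrom, s, e, strand) for s, e in exons]
    )
    return GeneModel(gid, biotype, "human", [tx])


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

def test_gtf_single_exon_coordinate_conversion(tmp_path):
    """1-based closed 11..20 becomes the half-open span (10, 20)."""
    p = tmp_path / "a.gtf"
    p.write_text(
        'chr1\tx\texon\t11\t20\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    )
    (gene,) = parse_gene_annotation(p)
    assert gene.span.start == 10 and gene.span.end == 20
    assert len(gene.transcripts) == 1
    assert len(gene.transcripts[0].exons) == 1


def test_gtf_transcript_and_exon_counts(tmp_path):
    p = tmp_path / "a.gtf"
    lines = []
    for tid, exons in (("t1", [(11, 20), (31, 40)]),
                       ("t2", [(11, 20), (31, 40), (51, 60)])):
        for s, e in exons:
            lines.append(
                f'chr1\tx\texon\t{s}\t{e}\t.\t+\t.\t'
                f'gene_id "g1"; transcript_id "{tid}";\n'
            )
    p.write_text("".join(lines))
    (gene,) = parse_gene_annotation(p)
    assert len(gene.transcripts) == 2
    assert sorted(len(t.exons) for t in gene.transcripts) == [2, 3]


def test_gtf_round_trip_preserves_models(tmp_path, fixture):
    """write -> parse -> write reproduces identical GTF text (exact 1-based
    closed coordinates)."""
    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    genes = fixture.genes_h[:30]
    write_gene_annotation(genes, p1)
    reparsed = parse_gene_annotation(p1, species="human")
    write_gene_annotation(reparsed, p2)
    assert p1.read_text() == p2.read_text()
    assert [g.gene_id for g in reparsed] == [g.gene_id for g in genes]


def test_gtf_malformed_attributes_name_line(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text("chr1\tx\texon\t1\t5\t.\t+\t.\tnonsense\n")
    with pytest.raises(ValueError, match="line 1"):
        parse_gene_annotation(p)


def test_unknown_dialect_rejected(tmp_path):
    with pytest.raises(ValueError, match="dialect"):
        parse_gene_annotation(tmp_path / "x", dialect="bed")


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

def _chain_text(t_span, blocks):
    body = "\n".join(
        f"{s} {dt} {dq}" for s, dt, dq in blocks[:-1]
    )
    if body:
        body += "\n"
    body += str(blocks[-1][0])
    q_span = sum(s + dq for s, _, dq in blocks)
    return (
        f"chain 100 chrT 1000 + 0 {t_span} chrQ 1000 + 0 {q_span} 1\n{body}\n"
    )


def test_identity_chain(tmp_path):
    p = tmp_path / "c.chain"
    p.write_text(_chain_text(100, [(100, 0, 0)]))
    (c,) = parse_chain(p)
    assert c.blocks == [(100, 0, 0)]


def test_two_block_chain_spans_accepted(tmp_path):
    """Blocks (50,10,5)(40,0,0): target span 100, query span 95."""
    p = tmp_path / "c.chain"
    p.write_text(_chain_text(100, [(50, 10, 5), (40, 0, 0)]))
    (c,) = parse_chain(p)
    assert c.t_end - c.t_start == 100
    assert c.q_end - c.q_start == 95


def test_inconsistent_chain_header_rejected(tmp_path):
    p = tmp_path / "c.chain"
    p.write_text(_chain_text(99, [(50, 10, 5), (40, 0, 0)]))
    with pytest.raises(ChainIntegrityError, match="chain 1"):
        parse_chain(p)


def test_chain_fuzz_corrupt_sums_rejected(tmp_path):
    """Every random corruption of a block sum violates the header spans."""
    rng = np.random.default_rng(0)
    for i in range(50):
        blocks = [
            (int(rng.integers(1, 50)), int(rng.integers(0, 20)),
             int(rng.integers(0, 20)))
            for _ in range(int(rng.integers(1, 5)))
        ]
        blocks[-1] = (blocks[-1][0], 0, 0)
        t_span = sum(s + dt for s, dt, _ in blocks)
        delta = int(rng.integers(1, 10))
        p = tmp_path / f"c{i}.chain"
        p.write_text(_chain_text(t_span + delta, blocks))
        with pytest.raises(ChainIntegrityError):
            parse_chain(p)


def test_chain_write_read_round_trip(tmp_path, fixture):
    p = tmp_path / "c.chain"
    write_chain(fixture.chains_h2m, p)
    back = parse_chain(p)
    assert [c.blocks for c in back] == [c.blocks for c in fixture.chains_h2m]


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

def test_bedgraph_per_base_expansion(tmp_path):
    p = tmp_path / "t.bg"
    p.write_text("chr1\t0\t3\t0.5\n")
    tr = parse_score_track(p)
    assert np.allclose(tr.values("chr1", 0, 3), 0.5)
    assert np.isnan(tr.values("chr1", 3, 4)).all()


def test_bedgraph_adjacent_records_concatenate(tmp_path):
    p = tmp_path / "t.bg"
    p.write_text("chr1\t0\t2\t0.2\nchr1\t2\t4\t0.8\n")
    tr = parse_score_track(p)
    assert np.allclose(tr.values("chr1", 0, 4), [0.2, 0.2, 0.8, 0.8])


def test_bedgraph_overlap_strict_mode_errors(tmp_path):
    p = tmp_path / "t.bg"
    p.write_text("chr1\t0\t3\t0.2\nchr1\t2\t4\t0.8\n")
    with pytest.raises(ValueError, match="overlapping"):
        parse_score_track(p, strict=True)
    parse_score_track(p)  # lenient mode accepts


def test_score_clamping_and_strict_error(tmp_path):
    p = tmp_path / "t.bg"
    p.write_text("chr1\t0\t2\t1.5\n")
    tr = parse_score_track(p)
    assert np.allclose(tr.values("chr1", 0, 2), 1.0)
    with pytest.raises(ValueError, match="outside"):
        parse_score_track(p, strict=True)


def test_fixed_step_wiggle(tmp_path):
    p = tmp_path / "t.wig"
    p.write_text("fixedStep chrom=chr2 start=11 step=1\n0.1\n0.2\n0.3\n")
    tr = parse_score_track(p, dialect="fixed_step_wig")
    assert np.allclose(tr.values("chr2", 10, 13), [0.1, 0.2, 0.3])


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,stranded,expected",
    [
        (GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 15), False, 5),
        (GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 20), False, 0),
        (
            GenomicInterval("c", 0, 10, "+"),
            GenomicInterval("c", 0, 10, "-"),
            True,
            0,
        ),
        (GenomicInterval("c", 0, 10), GenomicInterval("d", 0, 10), False, 0),
    ],
)
def test_interval_overlap_cases(a, b, stranded, expected):
    assert interval_overlap(a, b, stranded) == expected


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    s1=st.integers(0, 50), l1=st.integers(1, 50),
    s2=st.integers(0, 50), l2=st.integers(1, 50),
)
def test_interval_overlap_matches_set_intersection(s1, l1, s2, l2):
    a = GenomicInterval("c", s1, s1 + l1)
    b = GenomicInterval("c", s2, s2 + l2)
    brute = len(set(range(s1, s1 + l1)) & set(range(s2, s2 + l2)))
    assert interval_overlap(a, b) == brute == interval_overlap(b, a)
    assert interval_overlap(a, b) >= 0


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("c", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", 0, 5, "x")


def test_nearest_flanking_both_sides_within_limit():
    genes = [make_gene("up", "c", [(0, 100)]), make_gene("dn", "c", [(900, 1000)])]
    q = GenomicInterval("c", 400, 500)
    up, dn = nearest_flanking(q, genes, 500_000)
    assert up.gene_id == "up" and dn.gene_id == "dn"


def test_nearest_flanking_respects_max_dist():
    """An upstream gene 600 kb away is out of reach of the 500 kb window."""
    genes = [make_gene("far", "c", [(0, 100)])]
    q = GenomicInterval("c", 600_100, 600_200)
    up, dn = nearest_flanking(q, genes, 500_000)
    assert up is None and dn is None


def test_nearest_flanking_picks_nearest_and_excludes_overlaps():
    genes = [
        make_gene("a", "c", [(0, 90)]),
        make_gene("b", "c", [(5, 95)]),
        make_gene("ov", "c", [(80, 300)]),
    ]
    q = GenomicInterval("c", 200, 250)
    up, _ = nearest_flanking(q, genes, 500_000)
    assert up.gene_id == "b"          # end 95 beats end 90; overlap excluded
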