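"""Five-way human-mouse lncRNA conservation assessment.

A lncRNA pair can be supported by shared gene symbol, global synteny
(reciprocal chain lift-over), local synteny (shared flanking orthologs
within 500 kb), sequence homology plus phastCons sliding-window score,
or promoter homology.  Pairs supported by >=1 method are "conserved",
by >=2 methods "high-confidence".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    Chain,
    DEFAULT_CONFIG,
    GeneModel,
    GenomicInterval,
    ScoreTrack,
    interval_overlap,
    nearest_flanking,
    reverse_complement,
)

logger = logging.getLogger("lncsynt")

METHODS = ("symbol", "global", "local", "sequence", "promoter")


@dataclass
class AlignmentHit:
    query_id: str
    target_id: str
    identity: float
    evalue: float
    bitscore: float
    query_span: tuple[int, int] = (0, 0)
    target_span: tuple[int, int] = (0, 0)


@dataclass
class ConservationCall:
    human_id: str
    mouse_id: str
    evidence: dict = field(default_factory=lambda: {m: False for m in METHODS})

    @property
    def n_methods(self) -> int:
        return sum(bool(v) for v in self.evidence.values())

    @property
    def tier(self) -> str:
        n = self.n_methods
        if n >= 2:
            return "high_confidence"
        if n == 1:
            return "conserved"
        return "non_conserved"


# ---------------------------------------------------------------------------
# 1. Shared gene symbol
# ---------------------------------------------------------------------------

def classify_by_symbol(
    genes_h: Sequence[GeneModel],
    genes_m: Sequence[GeneModel],
    whitelist: Iterable[str],
) -> list[tuple[str, str]]:
    """Pairs whose case-normalized symbols match and appear in the whitelist
    of previously established conserved lncRNAs."""
    wl = {w.upper() for w in whitelist}
    by_sym_h: dict[str, list[str]] = {}
    by_sym_m: dict[str, list[str]] = {}
    for g in genes_h:
        if g.symbol:
            by_sym_h.setdefault(g.symbol.upper(), []).append(g.gene_id)
    for g in genes_m:
        if g.symbol:
            by_sym_m.setdefault(g.symbol.upper(), []).append(g.gene_id)
    pairs: list[tuple[str, str]] = []
    for sym in sorted(set(by_sym_h) & set(by_sym_m) & wl):
        hs, ms = by_sym_h[sym], by_sym_m[sym]
        if len(hs) > 1 or len(ms) > 1:
            logger.warning("ambiguous symbol %s; pairing all combinations", sym)
        pairs.extend((h, m) for h in hs for m in ms)
    return pairs


# ---------------------------------------------------------------------------
# 2. Global synteny (chain lift-over)
# ---------------------------------------------------------------------------

def lift_interval(
    iv: GenomicInterval,
    chains: Sequence[Chain],
    min_map_fraction: float = 0.5,
) -> GenomicInterval | None:
    """Map *iv* through alignment chains onto the query genome.

    Each base is mapped through the blocks of the single chain covering the
    most bases of *iv*; the returned interval is the envelope (min..max) of
    the mapped bases in forward query coordinates, or None when fewer than
    ``min_map_fraction`` of the bases map.
    """
    best: tuple[int, int, int, str] | None = None  # (mapped, qmin, qmax, qname)
    for chain in chains:
        if chain.t_name != iv.chrom:
            continue
        mapped = 0
        qmin, qmax = None, None
        tpos, qpos = chain.t_start, chain.q_start
        for size, dt, dq in chain.blocks:
            lo = max(iv.start, tpos)
            hi = min(iv.end, tpos + size)
            if hi > lo:
                mapped += hi - lo
                q_lo = qpos + (lo - tpos)
                q_hi = qpos + (hi - tpos)          # query coords, chain system
                if chain.q_strand == "-":
                    f_lo = chain.q_size - q_hi
                    f_hi = chain.q_size - q_lo
                else:
                    f_lo, f_hi = q_lo, q_hi
                qmin = f_lo if qmin is None else min(qmin, f_lo)
                qmax = f_hi if qmax is None else max(qmax, f_hi)
            tpos += size + dt
            qpos += size + dq
            if tpos >= iv.end:
                break
        if mapped and (best is None or mapped > best[0]):
            best = (mapped, qmin, qmax, chain.q_name)
    if best is None or best[0] / len(iv) < min_map_fraction:
        return None
    return GenomicInterval(best[3], best[1], best[2], ".")


def classify_global(
    lnc_h: Sequence[GeneModel],
    lnc_m: Sequence[GeneModel],
    chains_h2m: Sequence[Chain],
    chains_m2h: Sequence[Chain],
    min_map_fraction: float = 0.5,
    min_overlap: int = 1,
) -> list[tuple[str, str]]:
    """Pairs whose lift-overs overlap reciprocally (both chain directions)."""

    def one_direction(src, dst, chains):
        hits = set()
        dst_by_chrom: dict[str, list[GeneModel]] = {}
        for g in dst:
            dst_by_chrom.setdefault(g.chrom, []).append(g)
        for g in src:
            lifted = lift_interval(g.span, chains, min_map_fraction)
            if lifted is None:
                continue
            for cand in dst_by_chrom.get(lifted.chrom, []):
                if interval_overlap(lifted, cand.span) >= min_overlap:
                    hits.add((g.gene_id, cand.gene_id))
        return hits

    h2m = one_direction(lnc_h, lnc_m, chains_h2m)
    m2h = {(h, m) for m, h in one_direction(lnc_m, lnc_h, chains_m2h)}
    return sorted(h2m & m2h)


# ---------------------------------------------------------------------------
# Pairwise alignment (sequence / promoter / local case-b legs)
# ---------------------------------------------------------------------------

def _shares_word(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    words = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in words for i in range(len(b) - k + 1))


def _make_aligner(cfg: Mapping):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = cfg["aln_match"]
    aligner.mismatch_score = cfg["aln_mismatch"]
    aligner.open_gap_score = cfg["aln_open"]
    aligner.extend_gap_score = cfg["aln_extend"]
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    query_id: str = "a",
    target_id: str = "b",
    min_identity: float = 0.8,
    max_evalue: float = math.inf,
    strand: str = "plus",
    db_len: int | None = None,
    cfg: Mapping | None = None,
    _aligner=None,
    prescreen_word: int = 11,
) -> AlignmentHit | None:
    """Best local alignment of two nucleotide sequences passing the identity
    and e-value filters, or None.

    E-values use Karlin-Altschul-style scaling with the configured (lambda, K)
    constants and database length ``db_len`` (default: target length); they
    are calibrated for ranking and thresholding at fixture scale, not to
    reproduce BLAST output.
    """
    cfg = cfg or DEFAULT_CONFIG
    for s, name in ((seq_a, query_id), (seq_b, target_id)):
        if not s or set(s) - set("ACGTN"):
            raise ValueError(f"sequence {name} is empty or non-nucleotide")
    if strand not in ("plus", "both"):
        raise ValueError(f"unknown strand mode {strand!r}")
    candidates = [seq_b]
    if strand == "both":
        candidates.append(reverse_complement(seq_b))
    # seed prescreen: a genuine homologous hit shares an exact word
    if not any(_shares_word(seq_a, sb, prescreen_word) for sb in candidates):
        return None
    aligner = _aligner if _aligner is not None else _make_aligner(cfg)
    best = None
    for sb in candidates:
        if not _shares_word(seq_a, sb, prescreen_word):
            continue
        alns = aligner.align(seq_a, sb)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        if best is None or aln.score > best.score:
            best = aln
    if best is None:
        return None
    counts = best.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    if length == 0:
        return None
    identity = counts.identities / length
    lam, k = cfg["aln_lambda"], cfg["aln_k"]
    bits = (lam * best.score - math.log(k)) / math.log(2)
    n = db_len if db_len is not None else len(seq_b)
    evalue = len(seq_a) * n * 2.0 ** (-bits)
    if identity < min_identity or evalue > max_evalue:
        return None
    qs = (int(best.aligned[0][0][0]), int(best.aligned[0][-1][1]))
    ts = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1]))
    return AlignmentHit(query_id, target_id, identity, evalue, bits, qs, ts)


def best_hits(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    **params,
) -> dict[str, AlignmentHit]:
    """Top-bitscore hit per query against a target sequence set."""
    cfg = params.pop("cfg", None) or DEFAULT_CONFIG
    db_len = sum(len(s) for s in targets.values())
    aligner = _make_aligner(cfg)
    out: dict[str, AlignmentHit] = {}
    for qid, qseq in queries.items():
        best = None
        for tid, tseq in targets.items():
            hit = align_pair(
                qseq, tseq, qid, tid, db_len=db_len, cfg=cfg,
                _aligner=aligner, **params,
            )
            if hit is None:
                continue
            if (
                best is None
                or (hit.bitscore, hit.identity) > (best.bitscore, best.identity)
                or (
                    (hit.bitscore, hit.identity)
                    == (best.bitscore, best.identity)
                    and hit.target_id < best.target_id
                )
            ):
                best = hit
        if best is not None:
            out[qid] = best
    return out


def reciprocal_best_hits(
    hits_ab: Mapping[str, AlignmentHit] | Iterable[AlignmentHit],
    hits_ba: Mapping[str, AlignmentHit] | Iterable[AlignmentHit],
) -> list[tuple[str, str]]:
    """(a, b) pairs where b is a's best A->B hit and a is b's best B->A hit.

    When lists of hits are given, the best hit per query is chosen by
    bitscore, ties broken by identity then lexicographic target id.
    """

    def to_best(hits) -> dict[str, AlignmentHit]:
        if isinstance(hits, Mapping):
            return dict(hits)
        best: dict[str, AlignmentHit] = {}
        for h in hits:
            cur = best.get(h.query_id)
            if cur is None:
                best[h.query_id] = h
                continue
            # higher bitscore, then higher identity, then smaller target id
            if (h.bitscore, h.identity) > (cur.bitscore, cur.identity) or (
                (h.bitscore, h.identity) == (cur.bitscore, cur.identity)
                and h.target_id < cur.target_id
            ):
                best[h.query_id] = h
        return best

    ab, ba = to_best(hits_ab), to_best(hits_ba)
    pairs = []
    for a, hit in ab.items():
        back = ba.get(hit.target_id)
        if back is not None and back.target_id == a:
            pairs.append((a, hit.target_id))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# 3. Local synteny
# ---------------------------------------------------------------------------

def classify_local(
    lnc_h: Sequence[GeneModel],
    lnc_m: Sequence[GeneModel],
    coding_h: Sequence[GeneModel],
    coding_m: Sequence[GeneModel],
    orthologs: Iterable[tuple[str, str]],
    seqs_h: Mapping[str, str] | None = None,
    seqs_m: Mapping[str, str] | None = None,
    max_dist: int = 500_000,
    cfg: Mapping | None = None,
) -> list[tuple[str, str]]:
    """Pairs of lncRNAs sharing orthologous nearest flanking coding genes.

    A flank whose gene is absent from the ortholog table counts as
    non-conserved and disqualifies the lncRNA.  If both species have exactly
    one lncRNA between a shared ortholog flank pair the two are paired
    directly; with several, cross-species reciprocal best alignment hits
    decide the pairing (sequences required).
    """
    cfg = cfg or DEFAULT_CONFIG
    h2m = dict(orthologs)

    def flank_key(lnc, coding, to_common):
        up, down = nearest_flanking(lnc.span, coding, max_dist)
        if up is None or down is None:
            return None
        ku, kd = to_common(up.gene_id), to_common(down.gene_id)
        if ku is None or kd is None:
            return None
        return tuple(sorted((ku, kd)))      # orientation-normalized

    groups_h: dict[tuple, list[GeneModel]] = {}
    groups_m: dict[tuple, list[GeneModel]] = {}
    for lnc in lnc_h:
        key = flank_key(lnc, coding_h, lambda g: h2m.get(g))
        if key is not None:
            groups_h.setdefault(key, []).append(lnc)
    m_ids = set(h2m.values())
    for lnc in lnc_m:
        key = flank_key(lnc, coding_m, lambda g: g if g in m_ids else None)
        if key is not None:
            groups_m.setdefault(key, []).append(lnc)

    pairs: list[tuple[str, str]] = []
    for key in sorted(set(groups_h) & set(groups_m)):
        hs, ms = groups_h[key], groups_m[key]
        if len(hs) == 1 and len(ms) == 1:
            pairs.append((hs[0].gene_id, ms[0].gene_id))
        else:
            if seqs_h is None or seqs_m is None:
                logger.warning(
                    "multiple lncRNAs in shared interval %s but no sequences "
                    "given; skipped", key,
                )
                continue
            qh = {g.gene_id: seqs_h[g.gene_id] for g in hs}
            qm = {g.gene_id: seqs_m[g.gene_id] for g in ms}
            fw = best_hits(qh, qm, min_identity=cfg["lnc_min_identity"], cfg=cfg)
            bw = best_hits(qm, qh, min_identity=cfg["lnc_min_identity"], cfg=cfg)
            pairs.extend(reciprocal_best_hits(fw, bw))
    return sorted(set(pairs))


# ---------------------------------------------------------------------------
# 4. Sequence conservation (homology + phastCons sliding window)
# ---------------------------------------------------------------------------

def window_max_mean(
    scores: np.ndarray, window: int = 200, step: int = 50
) -> float:
    """Maximum sliding-window mean.

    Windows start at offsets 0, step, 2*step, ... < len; a window reaching
    past the end (or an array shorter than one window) is evaluated over the
    available bases.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score array")
    cs = np.concatenate([[0.0], np.cumsum(scores)])
    best = -np.inf
    for off in range(0, scores.size, step):
        hi = min(off + window, scores.size)
        best = max(best, (cs[hi] - cs[off]) / (hi - off))
    return float(best)


def exonic_scores(
    gene: GeneModel, track: ScoreTrack, missing: str = "zero"
) -> np.ndarray:
    vals = np.concatenate(
        [track.values(gene.chrom, s, e) for s, e in gene.exonic_intervals()]
    )
    if missing == "zero":
        return np.nan_to_num(vals, nan=0.0)
    return vals[~np.isnan(vals)]


def classify_sequence(
    lnc_h: Sequence[GeneModel],
    lnc_m: Sequence[GeneModel],
    seqs_h: Mapping[str, str],
    seqs_m: Mapping[str, str],
    track_h: ScoreTrack,
    track_m: ScoreTrack,
    cfg: Mapping | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal-best homologous pairs whose exonic conservation score
    exceeds the window threshold in at least one window of either species."""
    cfg = cfg or DEFAULT_CONFIG
    by_id_h = {g.gene_id: g for g in lnc_h}
    by_id_m = {g.gene_id: g for g in lnc_m}
    sh = {g.gene_id: seqs_h[g.gene_id] for g in lnc_h}
    sm = {g.gene_id: seqs_m[g.gene_id] for g in lnc_m}
    # mouse-to-human leg carries the e-value filter; both legs identity >= 0.8
    m2h = best_hits(
        sm, sh, min_identity=cfg["lnc_min_identity"],
        max_evalue=cfg["lnc_max_evalue"], cfg=cfg,
    )
    h2m = best_hits(sh, sm, min_identity=cfg["lnc_min_identity"], cfg=cfg)
    pairs = reciprocal_best_hits(h2m, m2h)
    flagged = []
    w, s, thr = (
        cfg["phastcons_window"], cfg["phastcons_step"], cfg["phastcons_threshold"],
    )
    policy = cfg["missing_score_policy"]
    for h, m in pairs:
        passed = False
        for gene, track in ((by_id_h[h], track_h), (by_id_m[m], track_m)):
            vals = exonic_scores(gene, track, policy)
            if vals.size and window_max_mean(vals, w, s) > thr:
                passed = True
                break
        if passed:
            flagged.append((h, m))
    return flagged


# ---------------------------------------------------------------------------
# 5. Promoter conservation
# ---------------------------------------------------------------------------

def classify_promoter(
    lnc_h: Sequence[GeneModel],
    lnc_m: Sequence[GeneModel],
    genome_h: Mapping[str, str],
    genome_m: Mapping[str, str],
    cfg: Mapping | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal best plus-strand promoter alignments (500 bp upstream)."""
    from .tf_enrichment import extract_promoters

    cfg = cfg or DEFAULT_CONFIG
    prom_h = extract_promoters(lnc_h, genome_h, cfg["promoter_len"])
    prom_m = extract_promoters(lnc_m, genome_m, cfg["promoter_len"])
    params = dict(
        min_identity=cfg["promoter_min_identity"],
        max_evalue=cfg["promoter_max_evalue"],
        strand="plus",
        cfg=cfg,
    )
    fw = best_hits(prom_h, prom_m, **params)
    bw = best_hits(prom_m, prom_h, **params)
    return reciprocal_best_hits(fw, bw)


# ---------------------------------------------------------------------------
# Merge and summary scoring
# ---------------------------------------------------------------------------

def merge_calls(
    method_pairs: Mapping[str, Iterable[tuple[str, str]]],
    lnc_h: Sequence[GeneModel] = (),
    lnc_m: Sequence[GeneModel] = (),
) -> tuple[list[ConservationCall], dict[str, str]]:
    """Union the per-method pair lists into per-pair calls with tiers, plus a
    gene-level tier map covering every supplied lncRNA.

    A gene in several pairs keeps all pairs; its gene-level tier is the
    maximum over its pairs.  Genes in no pair are non_conserved.
    """
    calls: dict[tuple[str, str], ConservationCall] = {}
    for method, pairs in method_pairs.items():
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        for h, m in pairs:
            call = calls.setdefault((h, m), ConservationCall(h, m))
            call.evidence[method] = True
    ordered = [calls[k] for k in sorted(calls)]

    rank = {"non_conserved": 0, "conserved": 1, "high_confidence": 2}
    gene_tier: dict[str, str] = {
        g.gene_id: "non_conserved" for g in list(lnc_h) + list(lnc_m)
    }
    multi: set[str] = set()
    seen: set[str] = set()
    for call in ordered:
        for gid in (call.human_id, call.mouse_id):
            if gid in seen:
                multi.add(gid)
            seen.add(gid)
            if rank[call.tier] > rank.get(gene_tier.get(gid, "non_conserved"), 0):
                gene_tier[gid] = call.tier
    if multi:
        logger.info(
            "%d lncRNAs participate in multiple pairs; gene tier = max over "
            "pairs", len(multi),
        )
    return ordered, gene_tier


def mean_conservation_score(
    gene: GeneModel,
    track: ScoreTrack,
    missing: str = "zero",
    strict: bool = False,
) -> float:
    """Mean per-base conservation score over the gene's exonic bases."""
    vals = exonic_scores(gene, track, missing)
    if missing == "exclude" and vals.size == 0:
        if strict:
            raise ValueError(f"no covered bases for {gene.gene_id}")
        logger.warning("no covered bases for %s; score 0", gene.gene_id)
        return 0.0
    return float(np.mean(vals)) if vals.size else 0.0


def calls_to_table(calls: Sequence[ConservationCall]):
    import pandas as pd

    rows = []
    for c in calls:
        row = {"human_id": c.human_id, "mouse_id": c.mouse_id}
        row.update({m: int(c.evidence[m]) for m in METHODS})
        row["n_methods"] = c.n_methods
        row["tier"] = c.tier
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["human_id", "mouse_id", *METHODS, "n_methods", "tier"],
    )
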