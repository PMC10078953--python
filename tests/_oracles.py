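"""Independent oracles shared by the unit and acceptance tests: a per-base
chain walker, naive sliding-window enumeration, random chain construction,
and exhaustive motif-score enumeration."""

import numpy as np

from lncsynt import tf_enrichment as tfe
from lncsynt.core_io import Chain, DEFAULT_CONFIG


def make_chain(blocks, t_start=0, q_start=0, q_strand="+", t_size=10_000,
               q_size=10_000, t_name="chrT", q_name="chrQ"):
    t_end = t_start + sum(s + dt for s, dt, _ in blocks)
    q_end = q_start + sum(s + dq for s, _, dq in blocks)
    c = Chain(0, t_name, t_size, "+", t_start, t_end,
              q_name, q_size, q_strand, q_start, q_end, blocks, "c")
    c.validate()
    return c


def random_chain(rng, t_name="chrT"):
    nb = int(rng.integers(1, 8))
    blocks = [
        [int(rng.integers(1, 200)), int(rng.integers(0, 100)),
         int(rng.integers(0, 100))]
        for _ in range(nb)
    ]
    blocks[-1][1] = blocks[-1][2] = 0
    return make_chain(
        [tuple(b) for b in blocks],
        t_start=int(rng.integers(0, 2000)),
        q_start=int(rng.integers(0, 2000)),
        q_strand="+" if rng.random() < 0.5 else "-",
        t_name=t_name,
    )


def brute_lift(iv, chains, min_map_fraction):
    """Per-base walk through every chain; envelope of forward-strand mapped
    positions of the chain covering the most bases."""
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
    if best is None or best[0] / (iv.end - iv.start) < min_map_fraction:
        return None
    return (best[3], best[1], best[2])


def naive_window_max(arr, window=200, step=50):
    return max(
        float(np.mean(arr[o : o + window])) for o in range(0, len(arr), step)
    )


def enumerate_tails(motif, cfg=None):
    """Exhaustive 4^w enumeration of the integer-score null distribution;
    returns (integer scores, {score: exact tail probability})."""
    cfg = cfg or DEFAULT_CONFIG
    iscores = tfe._integer_scores(
        motif, cfg["scan_pseudocount"], cfg["scan_granularity"]
    )
    w = motif.width
    words = np.stack(
        np.meshgrid(*[np.arange(4)] * w, indexing="ij"), axis=-1
    ).reshape(-1, w)
    scores = iscores[words, np.arange(w)].sum(axis=1)
    probs = motif.background[words].prod(axis=1)
    order = np.argsort(scores)[::-1]
    exact = {}
    acc = 0.0
    for s, p in zip(scores[order], probs[order]):
        acc += p
        exact[int(s)] = acc
    return iscores, exact
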