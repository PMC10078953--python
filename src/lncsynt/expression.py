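"""Expression normalization, detectability, tissue specificity, and
lncRNA-neighbor cis-correlation with a distance-matched null."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ExpressionMatrix, GeneModel, interval_overlap

logger = logging.getLogger("lncsynt")


def cpm_normalize(m: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million: counts * 1e6 / library size, per sample."""
    totals = m.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return m.counts * 1e6 / totals


def tissue_means(cpm: pd.DataFrame, labels: Mapping[str, str]) -> pd.DataFrame:
    """Mean CPM per gene per tissue."""
    tissue_of = pd.Series({s: labels[s] for s in cpm.columns})
    return cpm.T.groupby(tissue_of).mean().T


def detectability(
    cpm: pd.DataFrame,
    labels: Mapping[str, str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Gene x tissue detectability: mean CPM strictly above threshold."""
    means = tissue_means(cpm, labels)
    if means.shape[1] == 0:
        raise ValueError("no tissues")
    return means > threshold


def detectable_percentage(
    flags: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage of each group's genes detectable in each tissue."""
    grp = pd.Series({g: groups[g] for g in flags.index if g in groups})
    sub = flags.loc[grp.index]
    return sub.groupby(grp).mean().T * 100.0


# ---------------------------------------------------------------------------
# Tissue specificity
# ---------------------------------------------------------------------------

def tissue_specificity(
    cpm: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Fractional-expression profile per gene.

    The fractional expression in a tissue is that tissue's mean CPM divided
    by the summed mean CPM across all tissues; its maximum is the
    tissue-specificity score.  Genes with zero total expression are excluded.
    """
    means = tissue_means(cpm, labels)
    if means.shape[1] < 2:
        raise ValueError("tissue specificity needs >= 2 tissues")
    totals = means.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        logger.info("%d unexpressed genes excluded", int((~keep).sum()))
    frac = means.loc[keep].div(totals[keep], axis=0)
    frac["max_fraction"] = frac.max(axis=1)
    return frac


def tissue_specific_percentage(
    profiles: pd.DataFrame,
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
) -> pd.Series:
    """Fraction of genes whose tissue-specificity score exceeds each
    threshold (a non-increasing survival curve)."""
    mf = profiles["max_fraction"]
    return pd.Series(
        {t: float((mf > t).mean()) for t in thresholds}, name="pct_specific"
    )


# ---------------------------------------------------------------------------
# Neighbor correlation
# ---------------------------------------------------------------------------

@dataclass
class NeighborPair:
    lnc_id: str
    mrna_id: str
    distance: int                 # gap between spans; 0 when overlapping
    overlap_class: str            # {overlapping, nonoverlapping}
    rho: float = float("nan")


def _span_distance(a, b) -> int:
    if interval_overlap(a, b) > 0:
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def neighbor_pairs(
    lncs: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    window: int = 50_000,
) -> list[NeighborPair]:
    """All lncRNA-coding pairs whose spans overlap or lie within *window* bp
    of each other."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for l in lncs:
        lsp = l.span
        for g in by_chrom.get(l.chrom, []):
            d = _span_distance(lsp, g.span)
            if d <= window:
                cls = "overlapping" if d == 0 and interval_overlap(
                    lsp, g.span
                ) > 0 else "nonoverlapping"
                pairs.append(NeighborPair(l.gene_id, g.gene_id, d, cls))
    return pairs


def spearman(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Spearman rank correlation (average ranks for ties); None for
    constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need vectors of equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.info("constant vector; correlation undefined")
        return None
    return float(sps.spearmanr(x, y).statistic)


def pair_correlations(
    pairs: Sequence[NeighborPair], cpm: pd.DataFrame
) -> list[NeighborPair]:
    """Fill each pair's rho across samples; pairs with undefined correlation
    are dropped."""
    out = []
    for p in pairs:
        if p.lnc_id not in cpm.index or p.mrna_id not in cpm.index:
            continue
        rho = spearman(cpm.loc[p.lnc_id], cpm.loc[p.mrna_id])
        if rho is None:
            continue
        out.append(
            NeighborPair(p.lnc_id, p.mrna_id, p.distance, p.overlap_class, rho)
        )
    return out


def distance_matched_null(
    pairs: Sequence[NeighborPair],
    lncs: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    cpm: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    bin_width: int = 5000,
    exclude_observed: bool = True,
) -> pd.DataFrame:
    """Null rho distribution from random lncRNA-mRNA pairs whose distance
    falls in the same bin as a randomly chosen observed pair's distance.

    The observed pairs themselves are excluded from the candidate pool by
    default so the null is independent of the pairs under test.  Candidate
    pairs are enumerated out to the largest observed distance; empty bins
    are widened symmetrically with a warning.  Sampling is with replacement
    from each bin.
    """
    if not pairs:
        raise ValueError("no observed pairs")
    rng = np.random.default_rng(seed)
    obs_d = np.array([p.distance for p in pairs])
    observed = (
        {(p.lnc_id, p.mrna_id) for p in pairs} if exclude_observed else set()
    )
    max_d = int(obs_d.max()) + bin_width
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    candidates: dict[int, list[tuple[str, str, int]]] = {}
    for l in lncs:
        if l.gene_id not in cpm.index:
            continue
        lsp = l.span
        for g in by_chrom.get(l.chrom, []):
            if g.gene_id not in cpm.index:
                continue
            if (l.gene_id, g.gene_id) in observed:
                continue
            d = _span_distance(lsp, g.span)
            if d <= max_d:
                candidates.setdefault(d // bin_width, []).append(
                    (l.gene_id, g.gene_id, d)
                )
    if not candidates:
        raise ValueError("no candidate pairs within the observed distances")
    max_bin = max(candidates)
    rows = []
    widened = False
    for i in rng.integers(0, len(pairs), size=n):
        b = int(obs_d[i]) // bin_width
        width = 0
        pool: list = candidates.get(b, [])
        while not pool and width <= max_bin:
            width += 1
            widened = True
            pool = candidates.get(b - width, []) + candidates.get(b + width, [])
        lid, mid, d = pool[rng.integers(0, len(pool))]
        rho = spearman(cpm.loc[lid], cpm.loc[mid])
        if rho is not None:
            rows.append((lid, mid, d, rho))
    if widened:
        logger.warning("some distance bins were empty and widened")
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "distance", "rho"])
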