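"""Positional lncRNA classification, gene-structure statistics, transposable
element content, disease annotation, and resampling-based group comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import GeneModel, GenomicInterval, interval_overlap

logger = logging.getLogger("lncsynt")

POSITION_CLASSES = ("antisense", "intergenic", "intronic", "divergent", "other")


@dataclass
class LncClass:
    gene_id: str
    position_class: str


@dataclass
class DiseaseCatalog:
    """Disease-associated SNP positions and eQTL gene links, each with a
    trait and a category drawn from a declared vocabulary."""

    snps: list[tuple[GenomicInterval, str, str]]
    eqtls: list[tuple[str, str, str, str]]   # variant, gene_id, trait, category
    categories: tuple[str, ...] = ()

    def __post_init__(self):
        if self.categories:
            vocab = set(self.categories)
            bad = {c for *_, c in self.snps if c not in vocab} | {
                c for *_, c in self.eqtls if c not in vocab
            }
            if bad:
                raise ValueError(f"categories outside vocabulary: {sorted(bad)}")


# ---------------------------------------------------------------------------
# Positional classification
# ---------------------------------------------------------------------------

def _introns(gene: GeneModel) -> list[tuple[int, int]]:
    ex = gene.exonic_intervals()
    return [(a[1], b[0]) for a, b in zip(ex, ex[1:])]


def classify_lncrna_type(
    lnc: GeneModel,
    coding: Sequence[GeneModel],
    divergent_window: int = 1000,
) -> LncClass:
    """Assign one positional class relative to the protein-coding genes.

    antisense: exon-exon overlap with a coding gene on the opposite strand
    (takes precedence); intronic: fully inside one coding intron (either
    strand); divergent: non-overlapping, opposite strand, head-to-head
    TSS-to-TSS distance <= window; intergenic: no coding-gene span overlap;
    other: remaining (e.g. sense-overlapping) configurations.
    """
    span = lnc.span
    lnc_exons = lnc.exonic_intervals()
    lnc_tss = lnc.tss()
    overlapping = False
    for g in coding:
        gsp = g.span
        if gsp.chrom != span.chrom or interval_overlap(gsp, span) == 0:
            continue
        overlapping = True
        if g.strand != lnc.strand:
            gex = g.exonic_intervals()
            for ls, le in lnc_exons:
                if any(min(le, ge) > max(ls, gs) for gs, ge in gex):
                    return LncClass(lnc.gene_id, "antisense")
    for g in coding:
        if g.span.chrom != span.chrom:
            continue
        for i_s, i_e in _introns(g):
            if i_s <= span.start and span.end <= i_e:
                return LncClass(lnc.gene_id, "intronic")
    if not overlapping:
        for g in coding:
            gsp = g.span
            if gsp.chrom != span.chrom or g.strand == lnc.strand:
                continue
            if interval_overlap(gsp, span) > 0:
                continue
            # head-to-head: each gene's TSS points away from the other
            head_to_head = (
                (lnc.strand == "+" and g.strand == "-" and g.tss() <= lnc_tss)
                or (lnc.strand == "-" and g.strand == "+" and g.tss() >= lnc_tss)
            )
            if head_to_head and abs(g.tss() - lnc_tss) <= divergent_window:
                return LncClass(lnc.gene_id, "divergent")
        return LncClass(lnc.gene_id, "intergenic")
    return LncClass(lnc.gene_id, "other")


def classify_all(
    lncs: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    divergent_window: int = 1000,
) -> pd.Series:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = {
        l.gene_id: classify_lncrna_type(
            l, by_chrom.get(l.chrom, []), divergent_window
        ).position_class
        for l in lncs
    }
    return pd.Series(out, name="position_class")


# ---------------------------------------------------------------------------
# Gene structure
# ---------------------------------------------------------------------------

def structure_stats(
    genes: Sequence[GeneModel], exon_convention: str = "max"
) -> pd.DataFrame:
    """Per-gene transcript count, exon count and gene length.

    Exon count per gene is the maximum over its transcripts by default
    (``exon_convention="union"`` counts merged union exons instead).
    """
    rows = []
    for g in genes:
        if exon_convention == "max":
            exon_n = max(len(t.exons) for t in g.transcripts)
        elif exon_convention == "union":
            exon_n = len(g.exonic_intervals())
        else:
            raise ValueError(f"unknown exon convention {exon_convention!r}")
        sp = g.span
        rows.append((g.gene_id, len(g.transcripts), exon_n, sp.end - sp.start))
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_n", "exon_n", "length"]
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Transposable-element content
# ---------------------------------------------------------------------------

def _merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _covered(region: list[tuple[int, int]], repeats: list[tuple[int, int]]) -> int:
    total = 0
    for rs, re_ in region:
        for ts, te in repeats:
            total += max(0, min(re_, te) - max(rs, ts))
    return total


def te_content(
    gene: GeneModel,
    repeats: Sequence[GenomicInterval],
    region: str = "whole",
) -> float:
    """Fraction of the gene region covered by the union of repeat intervals;
    NaN when the region is empty (e.g. introns of a single-exon gene)."""
    if region == "exonic":
        reg = gene.exonic_intervals()
    elif region == "intronic":
        reg = _introns(gene)
    elif region == "whole":
        sp = gene.span
        reg = [(sp.start, sp.end)]
    else:
        raise ValueError(f"unknown region {region!r}")
    reg = [(s, e) for s, e in reg if e > s]
    if not reg:
        return float("nan")
    reps = _merge(
        (r.start, r.end) for r in repeats if r.chrom == gene.chrom
    )
    return _covered(reg, reps) / sum(e - s for s, e in reg)


# ---------------------------------------------------------------------------
# Disease annotation
# ---------------------------------------------------------------------------

def disease_by_snp(
    lncs: Sequence[GeneModel], catalog: DiseaseCatalog
) -> tuple[pd.Series, dict[str, set[str]]]:
    """Flag lncRNAs with >=1 disease SNP inside an exon (half-open
    containment); also return the per-gene category sets."""
    flags = {}
    cats: dict[str, set[str]] = {}
    for g in lncs:
        hit = set()
        for iv, _trait, category in catalog.snps:
            if iv.chrom != g.chrom:
                continue
            if any(s <= iv.start < e for s, e in g.exonic_intervals()):
                hit.add(category)
        flags[g.gene_id] = bool(hit)
        cats[g.gene_id] = hit
    return pd.Series(flags, name="disease_snp"), cats


def disease_by_eqtl(
    lncs: Sequence[GeneModel], catalog: DiseaseCatalog
) -> tuple[pd.Series, dict[str, set[str]]]:
    """Flag lncRNAs linked to >=1 disease-associated eQTL row."""
    known = {g.gene_id for g in lncs}
    cats: dict[str, set[str]] = {g.gene_id: set() for g in lncs}
    for _var, gid, _trait, category in catalog.eqtls:
        if gid in known:
            cats[gid].add(category)
        else:
            logger.info("eQTL gene %s absent from annotation; ignored", gid)
    flags = pd.Series(
        {g: bool(c) for g, c in cats.items()}, name="disease_eqtl"
    )
    return flags, cats


def category_proportion(
    gene_categories: Mapping[str, set[str]],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Normalized disease-category proportion per (category, group):
    n(category & group) / (N(category) * N(group)).

    N(category) counts genes associated with the category over all groups,
    N(group) is the group size.  Zero denominators give NaN; proportions
    over categories need not sum to 1.
    """
    cats = sorted({c for s in gene_categories.values() for c in s})
    grps = sorted(set(groups.values()))
    n_grp = {g: sum(1 for x in groups.values() if x == g) for g in grps}
    out = pd.DataFrame(index=cats, columns=grps, dtype=float)
    for c in cats:
        carriers = {g for g, s in gene_categories.items() if c in s}
        n_cat = len(carriers)
        for grp in grps:
            denom = n_cat * n_grp[grp]
            n = sum(1 for g in carriers if groups.get(g) == grp)
            out.loc[c, grp] = n / denom if denom else float("nan")
    out.index.name = "category"
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def resample_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n: int = 500,
    reps: int = 1000,
    statistic: str = "median",
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Balanced-size resampling comparison: draw *n* values from each group
    *reps* times, compute the statistic on each draw, and report the fraction
    of replicates where group a's statistic exceeds group b's."""
    if reps <= 0:
        raise ValueError("reps must be positive")
    stat = {"median": np.median, "mean": np.mean}[statistic]
    rng = np.random.default_rng(seed)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rows = []
    for arr, name in ((a, "a"), (b, "b")):
        if arr.size < n:
            logger.info(
                "group %s smaller than n=%d; sampling with replacement",
                name, n,
            )
    for _ in range(reps):
        sa = rng.choice(a, size=n, replace=a.size < n)
        sb = rng.choice(b, size=n, replace=b.size < n)
        rows.append((stat(sa), stat(sb)))
    df = pd.DataFrame(rows, columns=["stat_a", "stat_b"])
    frac = float(np.mean(df.stat_a > df.stat_b))
    return df, frac


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "mwu",
) -> tuple[float, float]:
    """Two-group comparison: KS for count-like features, Mann-Whitney U
    elsewhere.  Returns (statistic, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "ks":
        res = sps.ks_2samp(a, b)
    elif test == "mwu":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
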