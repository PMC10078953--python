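"""Promoter motif scanning, ChIP-peak binding counts, and the preferential
TF-enrichment screens.

The percentage screen compares the fraction of conserved vs non-conserved
lncRNA promoters containing a motif (PR = |(AB+R)/(CD+R)|, PM = |AB-CD|,
with R the median over the pooled per-motif percentages, significance by
two-proportions z-test with BH correction); the density screen compares
mean occurrences per promoter (DR = |(M+R)/(N+R)|, DM = |M-N|, Mann-Whitney
U with BH correction).  A TF flagged by both screens is a conserved-lncRNA-
binding TF (CLB_TF).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import fftconvolve
from statsmodels.stats.multitest import multipletests

from .core_io import (
    DEFAULT_CONFIG,
    GeneModel,
    GenomicInterval,
    interval_overlap,
    reverse_complement,
)

logger = logging.getLogger("lncsynt")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MotifModel:
    """Position frequency matrix (4 x width, A/C/G/T rows) with a background
    base distribution."""

    motif_id: str
    tf_name: str
    pfm: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 4:
            raise ValueError(
                f"motif {self.motif_id}: PFM must be 4 x width with width >= 4"
            )
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    def probabilities(self, pseudocount: float = 0.25) -> np.ndarray:
        """Column-normalized probabilities after adding *pseudocount* to
        every cell."""
        m = self.pfm + pseudocount
        return m / m.sum(axis=0, keepdims=True)

    def log_odds(self, pseudocount: float = 0.25) -> np.ndarray:
        return np.log2(
            self.probabilities(pseudocount) / self.background[:, None]
        )

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.pfm.argmax(axis=0))


@dataclass
class MotifOccurrence:
    motif_id: str
    gene_id: str
    offset: int          # 0-based start within the promoter, forward coords
    strand: str
    score: float
    p_value: float


def read_jaspar_pfms(path) -> list[MotifModel]:
    """Read JASPAR-style PFM files (">id name" header + bracketed A/C/G/T
    count rows) via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            pfm = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
            out.append(MotifModel(m.matrix_id or m.name, m.name, pfm))
    return out


def write_jaspar_pfms(motifs: Sequence[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for i, b in enumerate(_BASES):
                row = " ".join(f"{int(x):6d}" for x in m.pfm[i])
                fh.write(f"{b} [{row} ]\n")


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def extract_promoters(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    length: int = 500,
) -> dict[str, str]:
    """Strand-aware promoter sequences: *length* bp upstream of the TSS,
    minus-strand promoters reverse-complemented; truncated at contig edges
    with a warning."""
    out: dict[str, str] = {}
    for g in genes:
        contig = genome[g.chrom]
        tss = g.tss()
        if g.strand == "-":
            seq = contig[tss : min(tss + length, len(contig))]
            seq = reverse_complement(seq)
        else:
            start = max(0, tss - length)
            seq = contig[start:tss]
        if len(seq) < length:
            logger.warning(
                "promoter of %s truncated to %d bp at contig edge",
                g.gene_id, len(seq),
            )
        if seq:
            out[g.gene_id] = seq.upper()
    return out


def promoter_regions(
    genes: Sequence[GeneModel], length: int = 500
) -> dict[str, GenomicInterval]:
    """Genomic coordinates of each gene's promoter window."""
    out = {}
    for g in genes:
        tss = g.tss()
        if g.strand == "-":
            iv = GenomicInterval(g.chrom, tss, tss + length, "-")
        else:
            iv = GenomicInterval(g.chrom, max(0, tss - length), max(1, tss), "+")
        out[g.gene_id] = iv
    return out


# ---------------------------------------------------------------------------
# Motif scanning with an exact background null
# ---------------------------------------------------------------------------

def _integer_scores(motif: MotifModel, pseudocount: float, granularity: float):
    """Log-odds matrix rounded onto an integer lattice; these integers ARE
    the scores used for scanning and for the null, so tail probabilities are
    exact for the scores actually reported."""
    lo = motif.log_odds(pseudocount)
    return np.rint(lo / granularity).astype(np.int64)


def score_distribution(
    iscores: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, int]:
    """Exact distribution of the integer window score under the i.i.d.
    background: returns (probabilities, offset) where probabilities[k] is
    P(score = offset + k)."""
    dist = np.array([1.0])
    offset = 0
    for j in range(iscores.shape[1]):
        col = iscores[:, j]
        lo, hi = int(col.min()), int(col.max())
        pos = np.zeros(hi - lo + 1)
        for b in range(4):
            pos[col[b] - lo] += background[b]
        if dist.size == 1:
            new = dist[0] * pos
        elif pos.size == 1:
            new = dist * pos[0]
        else:
            new = fftconvolve(dist, pos)
        dist = np.clip(new, 0.0, None)
        offset += lo
    return dist, offset


def _tail_pvalues(dist: np.ndarray) -> np.ndarray:
    """p[k] = P(score >= offset + k), clamped against round-off above 1."""
    return np.minimum(1.0, np.cumsum(dist[::-1])[::-1])


def _motif_null(motif: MotifModel, cfg: Mapping):
    """(integer log-odds, tail p-values, offset) for one motif."""
    iscores = _integer_scores(
        motif, cfg["scan_pseudocount"], cfg["scan_granularity"]
    )
    dist, offset = score_distribution(iscores, motif.background)
    return iscores, _tail_pvalues(dist), offset


def scan_promoter(
    motif: MotifModel,
    seq: str,
    gene_id: str = "",
    p_threshold: float = 1e-4,
    cfg: Mapping | None = None,
    _null=None,
) -> list[MotifOccurrence]:
    """Report motif occurrences on both strands whose exact background
    p-value is <= *p_threshold*.

    The score threshold is the smallest integer-lattice score whose tail
    probability under the i.i.d. background is <= p_threshold; windows
    containing non-ACGT characters are skipped.
    """
    cfg = cfg or DEFAULT_CONFIG
    w = motif.width
    if len(seq) < w:
        return []
    iscores, tails, offset = _null if _null is not None else _motif_null(
        motif, cfg
    )

    def pval(iscore: int) -> float:
        k = iscore - offset
        if k < 0:
            return 1.0
        if k >= tails.size:
            return 0.0
        return float(tails[k])

    # smallest integer score whose tail probability is <= p_threshold
    passing = np.flatnonzero(tails <= p_threshold)
    if passing.size == 0:
        return []
    score_cut = offset + int(passing[0])

    granularity = cfg["scan_granularity"]
    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)
    occs: list[MotifOccurrence] = []
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    pos_idx = np.arange(w)
    for strand in ("+", "-"):
        mat = iscores if strand == "+" else iscores[::-1, ::-1]
        scores = np.where(
            valid,
            mat[np.clip(windows, 0, 3), pos_idx].sum(axis=1),
            np.iinfo(np.int64).min,
        )
        for i in np.flatnonzero(scores >= score_cut):
            occs.append(
                MotifOccurrence(
                    motif.motif_id, gene_id, int(i), strand,
                    float(scores[i] * granularity), pval(int(scores[i])),
                )
            )
    occs.sort(key=lambda o: (o.offset, o.strand))
    return occs


def scan_promoter_set(
    motifs: Sequence[MotifModel],
    promoters: Mapping[str, str],
    p_threshold: float = 1e-4,
    cfg: Mapping | None = None,
) -> list[MotifOccurrence]:
    cfg = cfg or DEFAULT_CONFIG
    out: list[MotifOccurrence] = []
    for m in motifs:
        null = _motif_null(m, cfg)
        for gid, seq in promoters.items():
            out.extend(scan_promoter(m, seq, gid, p_threshold, cfg, null))
    return out


def set_background_from_promoters(
    motifs: Sequence[MotifModel], promoters: Mapping[str, str]
) -> None:
    """Order-0 background from pooled promoter nucleotide frequencies."""
    counts = np.zeros(4)
    for seq in promoters.values():
        for b, i in _BASE_INDEX.items():
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        return
    bg = counts / counts.sum()
    for m in motifs:
        m.background = bg


# ---------------------------------------------------------------------------
# Per-promoter counting
# ---------------------------------------------------------------------------

def count_motifs(
    occurrences: Iterable[MotifOccurrence],
    promoters: Iterable[str],
    groups: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict | None]:
    """Distinct motif types and total occurrences per promoter; with a
    two-group label map, also the group-wise KS tests on both counts."""
    per: dict[str, dict[str, int]] = {p: {} for p in promoters}
    for o in occurrences:
        if o.gene_id in per:
            per[o.gene_id][o.motif_id] = per[o.gene_id].get(o.motif_id, 0) + 1
    df = pd.DataFrame(
        {
            "types": {p: len(d) for p, d in per.items()},
            "number": {p: sum(d.values()) for p, d in per.items()},
        }
    )
    df.index.name = "gene_id"
    ks = None
    if groups is not None:
        labels = sorted(set(groups.values()))
        if len(labels) == 2:
            a = df.loc[[p for p in df.index if groups.get(p) == labels[0]]]
            b = df.loc[[p for p in df.index if groups.get(p) == labels[1]]]
            ks = {}
            for col in ("types", "number"):
                stat, p = sps.ks_2samp(a[col], b[col])
                ks[col] = {"statistic": float(stat), "p": float(p)}
    return df, ks


def peak_binding_counts(
    experiments: Sequence[tuple[str, Sequence[GenomicInterval]]],
    promoter_regions: Mapping[str, GenomicInterval],
) -> pd.DataFrame:
    """TF types (distinct TF names with >=1 overlapping peak) and TFBS count
    (peak intervals overlapping the promoter, summed over experiments) per
    promoter."""
    tfs: dict[str, set[str]] = {p: set() for p in promoter_regions}
    nsites: dict[str, int] = {p: 0 for p in promoter_regions}
    for tf_name, peaks in experiments:
        if not peaks:
            logger.warning("empty peak set for TF %s", tf_name)
            continue
        for gid, region in promoter_regions.items():
            n = sum(1 for pk in peaks if interval_overlap(pk, region) > 0)
            if n:
                tfs[gid].add(tf_name)
                nsites[gid] += n
    df = pd.DataFrame(
        {
            "tf_types": {p: len(s) for p, s in tfs.items()},
            "tfbs": nsites,
        }
    )
    df.index.name = "gene_id"
    return df


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def two_proportion_z(x1, n1, x2, n2):
    """Pooled two-proportions z-test; returns (z, two-sided p).

    Accepts scalars or arrays.  Degenerate pooled proportions (0 or 1) give
    z = 0, p = 1.
    """
    x1, n1, x2, n2 = (np.asarray(v, dtype=float) for v in (x1, n1, x2, n2))
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise ValueError("group sizes must be positive")
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (x1 / n1 - x2 / n2) / np.sqrt(var), 0.0)
    p = np.where(var > 0, 2 * sps.norm.sf(np.abs(z)), 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def enrichment_percentage(
    A: Mapping[str, int],
    B: int,
    C: Mapping[str, int],
    D: int,
    percentile: float = 90,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percentage screen over all motifs.

    AB = A/B and CD = C/D per motif; R is the median of the pooled
    {AB} u {CD} multiset; PR = |(AB+R)/(CD+R)|, PM = |AB-CD|.  A motif is
    percentage_enriched when PR or PM exceeds its 90th percentile across
    motifs, AB > CD, and the BH-adjusted two-proportions z-test q < alpha.
    """
    motifs = sorted(A)
    if set(motifs) != set(C):
        raise ValueError("A and C must cover the same motifs")
    if B <= 0 or D <= 0:
        raise ValueError("group totals must be positive")
    if len(motifs) < 10:
        logger.warning("fewer than 10 motifs; percentile screen unstable")
    a = np.array([A[m] for m in motifs], dtype=float)
    c = np.array([C[m] for m in motifs], dtype=float)
    ab, cd = a / B, c / D
    r = float(np.median(np.concatenate([ab, cd])))
    pr = np.abs((ab + r) / (cd + r))
    pm = np.abs(ab - cd)
    _, p = two_proportion_z(a, np.full_like(a, B), c, np.full_like(c, D))
    q = bh_adjust(p)
    pr_cut = np.percentile(pr, percentile)
    pm_cut = np.percentile(pm, percentile)
    flag = ((pr > pr_cut) | (pm > pm_cut)) & (ab > cd) & (q < alpha)
    return pd.DataFrame(
        {
            "A": a.astype(int), "B": B, "C": c.astype(int), "D": D,
            "AB": ab, "CD": cd, "R_pct": r, "PR": pr, "PM": pm,
            "p_prop": p, "q_prop": q, "percentage_enriched": flag,
        },
        index=pd.Index(motifs, name="motif_id"),
    )


def enrichment_density(
    counts_cons: Mapping[str, np.ndarray],
    counts_non: Mapping[str, np.ndarray],
    percentile: float = 90,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Density screen: M and N are mean occurrences per promoter in the
    conserved / non-conserved groups, R the median of the pooled {M} u {N};
    DR = |(M+R)/(N+R)|, DM = |M-N|; significance by Mann-Whitney U on the
    per-promoter count vectors, BH-adjusted."""
    motifs = sorted(counts_cons)
    if set(motifs) != set(counts_non):
        raise ValueError("both groups must cover the same motifs")
    for m in motifs:
        if len(counts_cons[m]) == 0 or len(counts_non[m]) == 0:
            raise ValueError(f"empty promoter group for motif {m}")
    M = np.array([np.mean(counts_cons[m]) for m in motifs])
    N = np.array([np.mean(counts_non[m]) for m in motifs])
    r = float(np.median(np.concatenate([M, N])))
    dr = np.abs((M + r) / (N + r))
    dm = np.abs(M - N)
    p = np.empty(len(motifs))
    for i, m in enumerate(motifs):
        x, y = np.asarray(counts_cons[m]), np.asarray(counts_non[m])
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p[i] = 1.0
        else:
            p[i] = sps.mannwhitneyu(x, y, alternative="two-sided").pvalue
    q = bh_adjust(p)
    dr_cut = np.percentile(dr, percentile)
    dm_cut = np.percentile(dm, percentile)
    flag = ((dr > dr_cut) | (dm > dm_cut)) & (M > N) & (q < alpha)
    return pd.DataFrame(
        {
            "M": M, "N": N, "R_den": r, "DR": dr, "DM": dm,
            "p_den": p, "q_den": q, "density_enriched": flag,
        },
        index=pd.Index(motifs, name="motif_id"),
    )


def clb_tfs(pct: pd.DataFrame, den: pd.DataFrame) -> list[str]:
    """Motifs/TFs flagged by both the percentage and the density screen."""
    both = pct.index.intersection(den.index)
    mask = pct.loc[both, "percentage_enriched"] & den.loc[both, "density_enriched"]
    return sorted(both[mask])


def rank_tfs(
    binding: pd.DataFrame,
    marked: Iterable[str] = (),
) -> pd.DataFrame:
    """Rank TFs by (% conserved lncRNAs bound)/(% non-conserved bound) and by
    the binding-density ratio.

    *binding* needs columns pct_cons, pct_non, dens_cons, dens_non (one row
    per TF).  Zero denominators are smoothed with the median-based constants
    used by the enrichment screens.  Ranks are 1 = most conserved-biased;
    ties keep a stable order by TF id.
    """
    df = binding.sort_index().copy()
    r_pct = float(np.median(np.concatenate([df.pct_cons, df.pct_non])))
    r_den = float(np.median(np.concatenate([df.dens_cons, df.dens_non])))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_pct = np.where(
            df.pct_non > 0,
            df.pct_cons / df.pct_non,
            (df.pct_cons + r_pct) / (df.pct_non + r_pct),
        )
        ratio_den = np.where(
            df.dens_non > 0,
            df.dens_cons / df.dens_non,
            (df.dens_cons + r_den) / (df.dens_non + r_den),
        )
    df["ratio_pct"] = ratio_pct
    df["ratio_den"] = ratio_den
    df["rank_pct"] = (
        pd.Series(-df.ratio_pct, index=df.index).rank(method="first").astype(int)
    )
    df["rank_den"] = (
        pd.Series(-df.ratio_den, index=df.index).rank(method="first").astype(int)
    )
    marked = set(marked)
    df["marked"] = [t in marked for t in df.index]
    return df
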