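"""Paired-species synthetic fixture generator.

Builds a miniature human/mouse genome pair — annotations, alignment chains,
conservation tracks, sequences, repeats, motifs, ChIP peaks, disease
catalogs and count matrices — with planted, parameterized signal for every
stage of the conservation pipeline.  Planted lncRNA classes are mutually
exclusive by construction:

* ``symbol``    — shared, whitelisted gene symbol; nothing else conserved.
* ``global``    — covered reciprocally by alignment-chain blocks.
* ``local``     — alone between the same ortholog pair in both species, but
                  in a chain gap.
* ``sequence``  — high-identity exonic sequence and an elevated conservation
                  track.
* ``promoter``  — >=80%-identical 500 bp promoter, diverged gene body.
* ``nonconserved`` — none of the above; denser repeat content, elevated
                  tissue specificity.

Every planted lncRNA except the local class gets an adjacent species-specific
"guard" coding gene absent from the ortholog table, so its nearest flanks are
never a conserved ortholog pair and the local-synteny method stays specific
to its own class.  All generation is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    Chain,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    ScoreTrack,
    TranscriptModel,
    write_bed,
    write_bedgraph,
    write_chain,
    write_fasta,
    write_gene_annotation,
)
from .tf_enrichment import MotifModel, promoter_regions, write_jaspar_pfms

CLASSES = ("symbol", "global", "local", "sequence", "promoter", "nonconserved")
CONSERVED_CLASSES = ("symbol", "global", "local", "sequence", "promoter")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_coding_pairs: int = 72
    n_lnc_per_class: dict = field(
        default_factory=lambda: {c: 10 for c in CLASSES}
    )
    n_chroms: int = 2
    genome_length: int = 2_000_000          # per chromosome
    identity_conserved: float = 0.95        # sequence-class exonic identity
    promoter_identity: float = 0.90         # promoter-class promoter identity
    phastcons_high: float = 0.9
    phastcons_low: float = 0.1
    te_frac_conserved: float = 0.10
    te_frac_nonconserved: float = 0.30
    position_mix: dict = field(
        default_factory=lambda: {
            "intergenic": 0.6, "antisense": 0.2, "divergent": 0.1,
            "intronic": 0.1,
        }
    )
    # expression
    n_tissues: int = 16            # body-map-style tissue panel
    reps_per_tissue: int = 6
    libsize: int = 1_000_000
    nb_dispersion: float = 0.1
    neighbor_rho: float = 0.9
    specific_fraction: float = 0.9          # planted tissue-specific mass
    # motifs / TFs
    n_motifs: int = 50             # panel size; enriched subset stays < 10%
    motif_width: int = 8
    enriched_motif_ids: tuple = ("M01", "M02", "M03", "M04")
    background_motif_rate: float = 0.05     # embeds per promoter per motif
    enrichment_effect: float = 0.8          # added embed rate, conserved group
    n_neutral_tfs: int = 4
    n_noise_peaks: int = 30
    peak_width: int = 200
    # perturbation
    de_effect: float = 1.0                  # log2 fold change of TF targets
    perturb_reps: int = 4
    neutral_target_fraction: float = 0.15
    # disease
    disease_fraction: dict = field(
        default_factory=lambda: {"conserved": 0.3, "nonconserved": 0.1}
    )
    disease_categories: tuple = (
        "cardiovascular", "metabolic", "immune", "neurological",
    )

    def validate(self) -> None:
        if any(v < 0 for v in self.n_lnc_per_class.values()):
            raise ValueError("class counts must be >= 0")
        for f in (
            self.identity_conserved, self.promoter_identity,
            self.phastcons_high, self.phastcons_low, self.specific_fraction,
        ):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0,1]")
        bad = set(self.enriched_motif_ids) - {
            f"M{i + 1:02d}" for i in range(self.n_motifs)
        }
        if bad:
            raise ValueError(f"enriched motif ids outside motif set: {bad}")


@dataclass
class GroundTruth:
    lnc_class: dict[str, str] = field(default_factory=dict)
    pair_map: dict[str, str] = field(default_factory=dict)
    position_class: dict[str, str] = field(default_factory=dict)
    motif_enriched: dict[str, bool] = field(default_factory=dict)
    tissue_specific: dict[str, str | None] = field(default_factory=dict)
    preferential_tf: dict[str, bool] = field(default_factory=dict)
    neighbor_pairs: list[tuple[str, str]] = field(default_factory=list)
    symbol_whitelist: list[str] = field(default_factory=list)

    def pairs_of_class(self, cls: str) -> list[tuple[str, str]]:
        return sorted(
            (h, m)
            for h, m in self.pair_map.items()
            if self.lnc_class.get(h) == cls
        )


@dataclass
class GenomeFixture:
    cfg: SimulationConfig
    truth: GroundTruth
    genes_h: list[GeneModel]
    genes_m: list[GeneModel]
    chains_h2m: list[Chain]
    chains_m2h: list[Chain]
    track_h: ScoreTrack
    track_m: ScoreTrack
    genome_h: dict[str, str]
    genome_m: dict[str, str]
    orthologs: list[tuple[str, str]]
    repeats_h: list[GenomicInterval]
    repeats_m: list[GenomicInterval]

    def lnc(self, species: str) -> list[GeneModel]:
        genes = self.genes_h if species == "human" else self.genes_m
        return [g for g in genes if g.biotype == "lncRNA"]

    def coding(self, species: str) -> list[GeneModel]:
        genes = self.genes_h if species == "human" else self.genes_m
        return [g for g in genes if g.biotype == "coding"]

    def lnc_sequences(self, species: str) -> dict[str, str]:
        """Exonic (spliced) sequence per lncRNA."""
        genome = self.genome_h if species == "human" else self.genome_m
        out = {}
        for g in self.lnc(species):
            seq = "".join(
                genome[g.chrom][s:e] for s, e in g.exonic_intervals()
            )
            if g.strand == "-":
                from .core_io import reverse_complement

                seq = reverse_complement(seq)
            out[g.gene_id] = seq
        return out


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

def _random_genome(rng, chroms: Sequence[str], length: int) -> dict[str, np.ndarray]:
    return {c: rng.integers(0, 4, size=length, dtype=np.uint8) for c in chroms}


def _mutate(rng, arr: np.ndarray, rate: float) -> np.ndarray:
    out = arr.copy()
    if rate <= 0:
        return out
    hit = rng.random(arr.size) < rate
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _gene(
    gid: str, species: str, chrom: str, exons: list[tuple[int, int]],
    strand: str, biotype: str, symbol: str | None = None,
) -> GeneModel:
    tx = TranscriptModel(
        f"{gid}.t1",
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )
    return GeneModel(gid, biotype, species, [tx], symbol)


def _lnc_exons(c: int) -> list[tuple[int, int]]:
    return [(c, c + 300), (c + 700, c + 1000)]


def generate_genome_pair(cfg: SimulationConfig) -> GenomeFixture:
    """Lay out orthologous coding genes in identical order on both genomes
    and plant one lncRNA (of a class-specific construction) per
    inter-ortholog interval."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_h = _random_genome(rng, chroms, cfg.genome_length)
    genome_m = _random_genome(rng, chroms, cfg.genome_length)

    margin = 30_000
    per_chrom = [
        cfg.n_coding_pairs // cfg.n_chroms
        + (1 if i < cfg.n_coding_pairs % cfg.n_chroms else 0)
        for i in range(cfg.n_chroms)
    ]
    genes_h: list[GeneModel] = []
    genes_m: list[GeneModel] = []
    orthologs: list[tuple[str, str]] = []
    coding_pos: dict[str, list[int]] = {}       # chrom -> coding starts
    pitches: dict[str, int] = {}
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        if n < 2:
            raise ValueError("need >= 2 coding pairs per chromosome")
        pitch = (cfg.genome_length - 2 * margin) // n
        if pitch < 25_000:
            raise ValueError(
                "genome_length too small for the requested coding genes"
            )
        pitches[chrom] = pitch
        coding_pos[chrom] = []
        for k in range(n):
            s = margin + k * pitch
            coding_pos[chrom].append(s)
            hid, mid = f"HGENE{gi:03d}", f"MGENE{gi:03d}"
            exons = [(s, s + 1000), (s + 9000, s + 10_000)]
            genes_h.append(
                _gene(hid, "human", chrom, exons, "+", "coding", f"GENE{gi}")
            )
            genes_m.append(
                _gene(mid, "mouse", chrom, exons, "+", "coding", f"Gene{gi}")
            )
            orthologs.append((hid, mid))
            gi += 1

    # intervals between consecutive orthologs, as (chrom, left coding index)
    intervals = [
        (chrom, k)
        for chrom in chroms
        for k in range(len(coding_pos[chrom]) - 1)
    ]
    class_list = [c for c in CLASSES for _ in range(cfg.n_lnc_per_class[c])]
    if len(class_list) > len(intervals):
        raise ValueError(
            f"genome_length too small: {len(class_list)} lncRNAs requested "
            f"but only {len(intervals)} intervals available"
        )
    rng.shuffle(class_list)

    styles = list(cfg.position_mix)
    style_p = np.array([cfg.position_mix[s] for s in styles], dtype=float)
    style_p = style_p / style_p.sum()

    global_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    track_h, track_m = ScoreTrack(), ScoreTrack()
    repeats_h: list[GenomicInterval] = []
    repeats_m: list[GenomicInterval] = []
    extra_i = 0
    lnc_i = 0
    for (chrom, k), cls in zip(intervals, class_list):
        s_left = coding_pos[chrom][k]
        s_right = coding_pos[chrom][k + 1]
        c = s_left + 10_000 + (s_right - s_left - 10_000) // 2

        style = str(rng.choice(styles, p=style_p))
        if cls == "local" and style in ("antisense", "intronic"):
            # a styled local lncRNA must stay inside its own flanking
            # interval; fall back to the plain placements
            style = "intergenic" if rng.random() < 0.5 else "divergent"

        strand = "+"
        if cls == "local" and style == "divergent":
            e = s_right - 500
            exons = [(e - 1000, e - 700), (e - 400, e)]
            strand = "-"
        else:
            exons = _lnc_exons(c)
        hid, mid = f"HLNC{lnc_i:03d}", f"MLNC{lnc_i:03d}"
        symbol_h = symbol_m = None
        if cls == "symbol":
            symbol_h, symbol_m = f"LINCS{lnc_i}", f"Lincs{lnc_i}"
            truth.symbol_whitelist.append(symbol_h)
        lnc_h = _gene(hid, "human", chrom, exons, strand, "lncRNA", symbol_h)
        lnc_m = _gene(mid, "mouse", chrom, exons, strand, "lncRNA", symbol_m)
        genes_h.append(lnc_h)
        genes_m.append(lnc_m)
        span = lnc_h.span

        # guard / host genes (species-specific, absent from ortholog table)
        def add_extra(exons_x, strand_x):
            nonlocal extra_i
            genes_h.append(
                _gene(f"HEXTRA{extra_i:03d}", "human", chrom, exons_x,
                      strand_x, "coding")
            )
            genes_m.append(
                _gene(f"MEXTRA{extra_i:03d}", "mouse", chrom, exons_x,
                      strand_x, "coding")
            )
            extra_i += 1

        neighbor: str | None = None
        if cls != "local":
            if style == "divergent":
                gap = int(rng.integers(200, 900))           # TSS-to-TSS
                add_extra([(c - 1000 - gap, c - gap)], "-")  # head-to-head
                neighbor = f"HEXTRA{extra_i - 1:03d}"
            elif style == "antisense":
                add_extra([(c - 100, c + 1100)], "-")       # overlapping host
                d = int(rng.integers(5000, 9000))
                add_extra([(c + d, c + d + 1000)], "+")     # flank guard
                neighbor = f"HEXTRA{extra_i - 2:03d}"       # host, distance 0
            elif style == "intronic":
                add_extra(
                    [(c - 2000, c - 1500), (c + 6500, c + 7000)], "+"
                )                                           # intron host
                d = int(rng.integers(9000, 13_000))
                add_extra([(c + d, c + d + 1000)], "+")     # flank guard
                neighbor = f"HEXTRA{extra_i - 1:03d}"
            else:
                d = int(rng.integers(2000, 8000))
                add_extra([(c + d, c + d + 1000)], "+")     # flank guard
                neighbor = f"HEXTRA{extra_i - 1:03d}"
        else:
            # nearest real coding gene: the downstream flanking ortholog
            right_idx = sum(per_chrom[: chroms.index(chrom)]) + k + 1
            neighbor = f"HGENE{right_idx:03d}"

        # class-specific content
        if cls == "global":
            global_spans[chrom].append((span.start - 500, span.end + 500))
        if cls == "sequence":
            for es, ee in exons:
                genome_m[chrom][es:ee] = _mutate(
                    rng, genome_h[chrom][es:ee], 1 - cfg.identity_conserved
                )
        if cls == "promoter":
            ps, pe = span.start - 500, span.start
            if strand == "-":
                ps, pe = span.end, span.end + 500
            genome_m[chrom][ps:pe] = _mutate(
                rng, genome_h[chrom][ps:pe], 1 - cfg.promoter_identity
            )

        level = (
            cfg.phastcons_high if cls in CONSERVED_CLASSES else cfg.phastcons_low
        )
        for tr in (track_h, track_m):
            arr = tr.ensure(chrom, cfg.genome_length)
            arr[span.start : span.end] = level

        te_frac = (
            cfg.te_frac_nonconserved
            if cls == "nonconserved"
            else cfg.te_frac_conserved
        )
        te_len = int(te_frac * (span.end - span.start))
        if te_len > 0:
            iv = GenomicInterval(chrom, span.start, span.start + te_len, "+")
            repeats_h.append(iv)
            repeats_m.append(iv)

        truth.lnc_class[hid] = cls
        truth.lnc_class[mid] = cls
        truth.position_class[hid] = style
        truth.position_class[mid] = style
        if cls != "nonconserved":
            truth.pair_map[hid] = mid
        truth.tissue_specific[hid] = None       # assigned in expression step
        truth.neighbor_pairs.append((hid, neighbor))
        lnc_i += 1

    # background repeats away from genes
    for chrom in chroms:
        for _ in range(20):
            pos = int(rng.integers(0, margin - 400))
            iv = GenomicInterval(chrom, pos, pos + 300, "+")
            repeats_h.append(iv)
            repeats_m.append(iv)

    chains_h2m, chains_m2h = _build_chains(
        cfg, chroms, coding_pos, global_spans
    )
    fixture = GenomeFixture(
        cfg=cfg,
        truth=truth,
        genes_h=genes_h,
        genes_m=genes_m,
        chains_h2m=chains_h2m,
        chains_m2h=chains_m2h,
        track_h=track_h,
        track_m=track_m,
        genome_h={c: _to_str(a) for c, a in genome_h.items()},
        genome_m={c: _to_str(a) for c, a in genome_m.items()},
        orthologs=orthologs,
        repeats_h=sorted(repeats_h, key=lambda r: (r.chrom, r.start)),
        repeats_m=sorted(repeats_m, key=lambda r: (r.chrom, r.start)),
    )
    return fixture


def _build_chains(cfg, chroms, coding_pos, global_spans):
    """One chain per chromosome and direction; blocks cover ortholog coding
    spans and global-class lncRNAs, with gaps everywhere else.  Both genomes
    use identical coordinates, so the two directions are mirror images."""
    chains_h2m, chains_m2h = [], []
    for ci, chrom in enumerate(chroms):
        blocks_iv = sorted(
            [(s - 100, s + 10_100) for s in coding_pos[chrom]]
            + global_spans[chrom]
        )
        merged: list[list[int]] = []
        for s, e in blocks_iv:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        t_start, t_end = merged[0][0], merged[-1][1]
        blocks = []
        for i, (s, e) in enumerate(merged):
            gap = merged[i + 1][0] - e if i + 1 < len(merged) else 0
            blocks.append((e - s, gap, gap))
        for out, name in ((chains_h2m, "h2m"), (chains_m2h, "m2h")):
            out.append(
                Chain(
                    score=1000.0,
                    t_name=chrom, t_size=cfg.genome_length, t_strand="+",
                    t_start=t_start, t_end=t_end,
                    q_name=chrom, q_size=cfg.genome_length, q_strand="+",
                    q_start=t_start, q_end=t_end,
                    blocks=blocks, chain_id=f"{name}_{ci + 1}",
                )
            )
    return chains_h2m, chains_m2h


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _nb_params(mean: np.ndarray, disp: float):
    n = 1.0 / max(disp, 1e-9)
    p = n / (n + np.maximum(mean, 1e-12))
    return n, p


def generate_expression(
    cfg: SimulationConfig, fixture: GenomeFixture
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Negative-binomial tissue counts and perturbation-arm counts for the
    human genes.

    Non-conserved lncRNAs are planted tissue-specific (a configured fraction
    of their expression in one tissue); planted neighbor pairs follow a
    Gaussian copula targeting the configured Spearman correlation;
    perturbation arms multiply planted TF-target means by 2**de_effect
    (knockout arm of the first planted TF: 2**-de_effect); library sizes
    vary +/-30%.
    """
    if cfg.n_tissues < 2:
        raise ValueError("need >= 2 tissues")
    rng = np.random.default_rng(cfg.seed + 1)
    truth = fixture.truth
    genes = [g.gene_id for g in fixture.genes_h]
    gidx = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    T, R = cfg.n_tissues, cfg.reps_per_tissue
    S = T * R
    tissues = [f"tissue{t + 1}" for t in range(T)]

    is_lnc = np.array([g.startswith("HLNC") for g in genes])
    base = np.where(
        is_lnc,
        np.exp(rng.normal(math.log(30), 0.8, G)),
        np.exp(rng.normal(math.log(100), 0.8, G)),
    )

    # tissue weight profiles
    W = np.exp(rng.normal(0, 0.2, (G, T)))
    for g in genes:
        if truth.lnc_class.get(g) == "nonconserved":
            t = int(rng.integers(0, T))
            w = np.full(T, (1 - cfg.specific_fraction) / (T - 1))
            w[t] = cfg.specific_fraction
            W[gidx[g]] = w * T
            truth.tissue_specific[g] = tissues[t]
        elif g in truth.tissue_specific:
            truth.tissue_specific[g] = None
    W = W / W.mean(axis=1, keepdims=True)

    # planted neighbor pairs: flat tissue profile, shared copula
    planted_pairs = [
        (l, m)
        for l, m in truth.neighbor_pairs
        if truth.lnc_class.get(l) in CONSERVED_CLASSES and m in gidx
    ]
    in_pair = set()
    for l, m in planted_pairs:
        W[gidx[l]] = 1.0
        W[gidx[m]] = 1.0
        in_pair.update((l, m))

    tissue_of_sample = np.repeat(np.arange(T), R)
    lib = rng.uniform(0.7, 1.3, S)
    mean = base[:, None] * W[:, tissue_of_sample] * lib[None, :]
    n, p = _nb_params(mean, cfg.nb_dispersion)
    counts = rng.negative_binomial(n, p)

    r_latent = 2 * math.sin(math.pi * cfg.neighbor_rho / 6)
    for l, m in planted_pairs:
        z1 = rng.normal(size=S)
        z2 = r_latent * z1 + math.sqrt(1 - r_latent**2) * rng.normal(size=S)
        for g, z in ((l, z1), (m, z2)):
            i = gidx[g]
            u = sps.norm.cdf(z)
            nn, pp = _nb_params(mean[i], cfg.nb_dispersion)
            counts[i] = sps.nbinom.ppf(u, nn, pp).astype(np.int64)

    sample_ids = [
        f"{tissues[tissue_of_sample[s]]}_r{s % R + 1}" for s in range(S)
    ]
    tissue_em = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids),
        {s: tissues[tissue_of_sample[i]] for i, s in enumerate(sample_ids)},
    )

    # ------------------------------------------------------------------
    # perturbation arms
    # ------------------------------------------------------------------
    planted_tfs = [f"TF{int(m[1:]):02d}" for m in cfg.enriched_motif_ids]
    neutral_tfs = [
        f"TF{len(planted_tfs) + i + 1:02d}" for i in range(cfg.n_neutral_tfs)
    ]
    for tf in planted_tfs:
        truth.preferential_tf[tf] = True
    for tf in neutral_tfs:
        truth.preferential_tf[tf] = False

    conserved = np.array(
        [truth.lnc_class.get(g) in CONSERVED_CLASSES for g in genes]
    )
    arms: dict[str, np.ndarray] = {"control": np.ones(G)}
    for tf in planted_tfs:
        eff = np.ones(G)
        eff[conserved] = 2.0**cfg.de_effect
        arms[f"oe_{tf}"] = eff
    for tf in neutral_tfs:
        eff = np.ones(G)
        targets = rng.random(G) < cfg.neutral_target_fraction
        eff[targets] = 2.0**cfg.de_effect
        arms[f"oe_{tf}"] = eff
    # the knockout is a separate experiment with its own control arm
    arms["ko_control"] = np.ones(G)
    ko = np.ones(G)
    ko[conserved] = 2.0**-cfg.de_effect
    arms[f"ko_{planted_tfs[0]}"] = ko

    cols, labels, mats = [], {}, []
    for arm, eff in arms.items():
        for r in range(cfg.perturb_reps):
            lib_f = rng.uniform(0.7, 1.3)
            m_arm = base * eff * lib_f
            nn, pp = _nb_params(m_arm, cfg.nb_dispersion)
            mats.append(rng.negative_binomial(nn, pp))
            sid = f"{arm}_r{r + 1}"
            cols.append(sid)
            labels[sid] = arm
    perturb_em = ExpressionMatrix(
        pd.DataFrame(np.column_stack(mats), index=genes, columns=cols), labels
    )
    return tissue_em, perturb_em


# ---------------------------------------------------------------------------
# motifs, promoters, peaks
# ---------------------------------------------------------------------------

def generate_motif_data(
    cfg: SimulationConfig, fixture: GenomeFixture
) -> tuple[list[MotifModel], dict[str, str], dict[str, str],
           list[tuple[str, list[GenomicInterval]]]]:
    """Random informative PFMs, i.i.d. background promoters per species with
    enriched motifs embedded at rate background+effect in conserved-class
    promoters only, and per-TF peak files covering the human embeddings plus
    uniform noise peaks."""
    rng = np.random.default_rng(cfg.seed + 2)
    truth = fixture.truth
    w = cfg.motif_width
    prom_len = 500
    if w > prom_len:
        raise ValueError("motif longer than promoter")
    motifs: list[MotifModel] = []
    for i in range(cfg.n_motifs):
        consensus = rng.integers(0, 4, w)
        pfm = np.full((4, w), 5.0)
        pfm[consensus, np.arange(w)] = 85.0
        mid = f"M{i + 1:02d}"
        motifs.append(MotifModel(mid, f"TF{i + 1:02d}", pfm))
        truth.motif_enriched[mid] = mid in cfg.enriched_motif_ids

    def sample_instance(m: MotifModel) -> str:
        # planted sites are high-affinity: the consensus word, so a scanner
        # with a stringent p-value threshold can recover every embedding
        return m.consensus()

    regions = promoter_regions(fixture.lnc("human"), prom_len)
    embeds: dict[str, list[tuple[str, int]]] = {m.motif_id: [] for m in motifs}
    proms: dict[str, dict[str, str]] = {}
    for species in ("human", "mouse"):
        out: dict[str, str] = {}
        for g in fixture.lnc(species):
            seq = _to_str(rng.integers(0, 4, prom_len, dtype=np.uint8))
            arr = list(seq)
            used: list[tuple[int, int]] = []
            cls = truth.lnc_class[g.gene_id]
            for m in motifs:
                rate = cfg.background_motif_rate
                if (
                    truth.motif_enriched[m.motif_id]
                    and cls in CONSERVED_CLASSES
                ):
                    rate += cfg.enrichment_effect
                for _ in range(rng.poisson(rate)):
                    for _try in range(20):
                        off = int(rng.integers(0, prom_len - m.width + 1))
                        if all(
                            off + m.width <= s or off >= e for s, e in used
                        ):
                            break
                    else:
                        continue
                    used.append((off, off + m.width))
                    inst = sample_instance(m)
                    arr[off : off + m.width] = list(inst)
                    if species == "human":
                        embeds[m.motif_id].append((g.gene_id, off))
            out[g.gene_id] = "".join(arr)
        proms[species] = out

    peaks: list[tuple[str, list[GenomicInterval]]] = []
    half = cfg.peak_width // 2
    chroms = sorted(fixture.genome_h)
    for m in motifs:
        ivs: list[GenomicInterval] = []
        for gid, off in embeds[m.motif_id]:
            reg = regions[gid]
            center = reg.start + off + m.width // 2
            ivs.append(
                GenomicInterval(
                    reg.chrom,
                    max(0, center - half),
                    center + half,
                    "+",
                )
            )
        for _ in range(cfg.n_noise_peaks):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(0, cfg.genome_length - cfg.peak_width))
            ivs.append(GenomicInterval(chrom, pos, pos + cfg.peak_width, "+"))
        peaks.append((m.tf_name, ivs))
    return motifs, proms["human"], proms["mouse"], peaks


# ---------------------------------------------------------------------------
# disease catalog
# ---------------------------------------------------------------------------

def generate_disease_catalog(cfg: SimulationConfig, fixture: GenomeFixture):
    """SNPs planted inside exons of a configured fraction of each class, and
    eQTL rows linking an independent random subset."""
    from .annotation_features import DiseaseCatalog

    rng = np.random.default_rng(cfg.seed + 3)
    snps, eqtls = [], []
    cats = cfg.disease_categories
    for g in fixture.lnc("human"):
        cls = truth_group = (
            "nonconserved"
            if fixture.truth.lnc_class[g.gene_id] == "nonconserved"
            else "conserved"
        )
        frac = cfg.disease_fraction[truth_group]
        if rng.random() < frac:
            s, e = g.exonic_intervals()[0]
            pos = int(rng.integers(s, e))
            cat = cats[int(rng.integers(0, len(cats)))]
            snps.append(
                (GenomicInterval(g.chrom, pos, pos + 1, "."), f"trait_{cat}", cat)
            )
        if rng.random() < frac:
            cat = cats[int(rng.integers(0, len(cats)))]
            eqtls.append(
                (f"rs{rng.integers(1e6):06d}", g.gene_id, f"trait_{cat}", cat)
            )
    return DiseaseCatalog(snps, eqtls, cats)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fixture(fixture: GenomeFixture, outdir: str | Path) -> None:
    """Write the complete fixture tree (annotations, chains, tracks,
    genomes, orthologs, repeats, truth table) as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_annotation(fixture.genes_h, out / "human.gtf")
    write_gene_annotation(fixture.genes_m, out / "mouse.gtf")
    write_chain(fixture.chains_h2m, out / "human_to_mouse.chain")
    write_chain(fixture.chains_m2h, out / "mouse_to_human.chain")
    write_bedgraph(fixture.track_h, out / "human.phastcons.bedgraph")
    write_bedgraph(fixture.track_m, out / "mouse.phastcons.bedgraph")
    write_fasta(fixture.genome_h, out / "human.fa")
    write_fasta(fixture.genome_m, out / "mouse.fa")
    with open(out / "orthologs.tsv", "w") as fh:
        for h, m in fixture.orthologs:
            fh.write(f"{h}\t{m}\n")
    write_bed(
        ((iv, f"TE{i}") for i, iv in enumerate(fixture.repeats_h)),
        out / "human.repeats.bed",
    )
    write_bed(
        ((iv, f"TE{i}") for i, iv in enumerate(fixture.repeats_m)),
        out / "mouse.repeats.bed",
    )
    truth = fixture.truth
    with open(out / "truth.tsv", "w") as fh:
        fh.write("gene_id\tclass\tposition\tpartner\n")
        pair_rev = {m: h for h, m in truth.pair_map.items()}
        for gid in sorted(truth.lnc_class):
            partner = truth.pair_map.get(gid) or pair_rev.get(gid) or "."
            fh.write(
                f"{gid}\t{truth.lnc_class[gid]}\t"
                f"{truth.position_class.get(gid, '.')}\t{partner}\n"
            )
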