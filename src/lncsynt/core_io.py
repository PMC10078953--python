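"""Domain types, coordinate arithmetic, and readers/writers for the
annotation, alignment-chain, conservation-track, sequence, interval and
count-matrix formats the conservation pipeline consumes.

All internal coordinates are 0-based half-open; 1-based closed GTF/GFF3
coordinates are converted at the parse/write boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lncsynt")

STRANDS = ("+", "-", ".")

#: Every tunable threshold of the pipeline, overridable from a YAML/TOML
#: key-value file via :func:`load_config`.
DEFAULT_CONFIG: dict = {
    # conservation
    "min_map_fraction": 0.5,        # lift-over: mapped bases / interval length
    "min_liftover_overlap": 1,      # bp overlap after lift-over (global synteny)
    "flank_max_dist": 500_000,      # bp, local-synteny ortholog search
    "phastcons_window": 200,        # bp sliding window
    "phastcons_step": 50,           # bp step
    "phastcons_threshold": 0.58,    # max window mean must exceed this
    "lnc_min_identity": 0.80,       # lncRNA body alignment
    "lnc_max_evalue": 1e-5,         # mouse-to-human leg
    "promoter_len": 500,            # bp upstream of TSS
    "promoter_min_identity": 0.80,
    "promoter_max_evalue": 1e-10,
    "promoter_word_size": 6,
    "missing_score_policy": "zero",  # or "exclude"
    # alignment e-value model (Karlin-Altschul-style scaling)
    "aln_match": 2.0,
    "aln_mismatch": -3.0,
    "aln_open": -5.0,
    "aln_extend": -2.0,
    "aln_lambda": 0.625,
    "aln_k": 0.41,
    # annotation features
    "divergent_window": 1000,       # bp TSS-to-TSS for divergent class
    "resample_n": 500,
    "resample_reps": 1000,
    # expression
    "cpm_detect_threshold": 0.5,
    "neighbor_window": 50_000,      # bp
    "null_pairs": 1000,
    "distance_bin": 5000,           # bp, distance-matched null binning
    "ts_thresholds": (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
    # TF enrichment
    "scan_pseudocount": 0.25,
    "scan_p_threshold": 1e-4,
    "scan_granularity": 1e-4,       # integer-lattice rounding of log-odds
    "enrich_percentile": 90,
    "enrich_alpha": 0.05,
    # perturbation
    "de_alpha": 0.05,
    "cpm_floor": 0.5,
    "log2fc_pseudocount": 0.5,
}


def load_config(path: str | Path | None = None) -> dict:
    """Return the default configuration, updated from a YAML (or flat
    ``key = value``) file when *path* is given."""
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    import yaml

    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    unknown = set(loaded) - set(cfg)
    if unknown:
        logger.warning("unknown config keys ignored: %s", sorted(unknown))
    cfg.update({k: v for k, v in loaded.items() if k in cfg})
    return cfg


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval]

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def span(self) -> GenomicInterval:
        first, last = self.exons[0], self.exons[-1]
        return GenomicInterval(first.chrom, first.start, last.end, first.strand)


@dataclass
class GeneModel:
    gene_id: str
    biotype: str                      # {lncRNA, coding, other}
    species: str
    transcripts: list[TranscriptModel]
    symbol: str | None = None

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {e.chrom for t in self.transcripts for e in t.exons}
        strands = {e.strand for t in self.transcripts for e in t.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"gene {self.gene_id}: transcripts must share chrom and strand"
            )

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        e0 = self.transcripts[0].exons[0]
        return GenomicInterval(e0.chrom, start, end, e0.strand)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].exons[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].exons[0].strand

    def tss(self) -> int:
        """Strand-aware transcription start (5' end of the gene span)."""
        sp = self.span
        return sp.start if self.strand != "-" else sp.end

    def exonic_intervals(self) -> list[tuple[int, int]]:
        """Union of exon intervals over all transcripts (merged, sorted)."""
        ivs = sorted(
            (e.start, e.end) for t in self.transcripts for e in t.exons
        )
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exonic_intervals())


@dataclass
class Chain:
    """One UCSC pairwise-alignment chain: co-linear gapped blocks mapping a
    target-genome span onto a query-genome span."""

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]   # (size, dt, dq); last has dt=dq=0
    chain_id: str = "1"

    def validate(self) -> None:
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if self.blocks and (self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0):
            raise ChainIntegrityError(
                f"chain {self.chain_id}: last block must have dt=dq=0"
            )
        if sizes + dts != self.t_end - self.t_start:
            raise ChainIntegrityError(
                f"chain {self.chain_id}: target span {self.t_end - self.t_start}"
                f" != blocks {sizes}+{dts}"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ChainIntegrityError(
                f"chain {self.chain_id}: query span {self.q_end - self.q_start}"
                f" != blocks {sizes}+{dqs}"
            )


class ChainIntegrityError(ValueError):
    pass


class ScoreTrack:
    """Per-base conservation scores in [0,1] per chromosome; uncovered bases
    are NaN (missing)."""

    def __init__(self, arrays: dict[str, np.ndarray] | None = None):
        self.arrays: dict[str, np.ndarray] = arrays or {}

    def ensure(self, chrom: str, size: int) -> np.ndarray:
        arr = self.arrays.get(chrom)
        if arr is None or arr.size < size:
            new = np.full(size, np.nan, dtype=np.float32)
            if arr is not None:
                new[: arr.size] = arr
            self.arrays[chrom] = new
        return self.arrays[chrom]

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); bases beyond the stored array are NaN."""
        out = np.full(end - start, np.nan, dtype=np.float32)
        arr = self.arrays.get(chrom)
        if arr is not None and start < arr.size:
            hi = min(end, arr.size)
            out[: hi - start] = arr[start:hi]
        return out


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with a tissue/condition label per sample."""

    counts: pd.DataFrame                 # index: gene_ids, columns: sample_ids
    sample_labels: dict[str, str]

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_labels)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.sample_labels[s], None)
        return list(seen)


# ---------------------------------------------------------------------------
# Annotation I/O (GTF / GFF3)
# ---------------------------------------------------------------------------

_LNC_BIOTYPES = {"lncrna", "lincrna", "antisense", "lnc_rna"}
_CODING_BIOTYPES = {"protein_coding", "coding", "mrna"}


def _normalize_biotype(raw: str | None) -> str:
    if raw is None:
        return "other"
    r = raw.lower()
    if r in _LNC_BIOTYPES:
        return "lncRNA"
    if r in _CODING_BIOTYPES:
        return "coding"
    return "other"


def _parse_attributes(attr: str, dialect: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    attr = attr.strip().rstrip(";")
    if not attr:
        return out
    if dialect == "gtf":
        for chunk in attr.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if " " not in chunk:
                raise ValueError(
                    f"malformed GTF attribute {chunk!r} at line {lineno}"
                )
            key, val = chunk.split(" ", 1)
            out[key] = val.strip().strip('"')
    else:
        for chunk in attr.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            if "=" not in chunk:
                raise ValueError(
                    f"malformed GFF3 attribute {chunk!r} at line {lineno}"
                )
            key, val = chunk.split("=", 1)
            out[key] = val
    return out


def parse_gene_annotation(
    path: str | Path, dialect: str = "gtf", species: str = ""
) -> list[GeneModel]:
    """Read a GTF or GFF3 file into :class:`GeneModel` objects.

    1-based closed coordinates become 0-based half-open.  Genes lacking exon
    records are dropped with a warning.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    gene_meta: dict[str, dict] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx2parent: dict[str, str] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"expected 9 columns at line {lineno} of {path}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr = cols
            attrs = _parse_attributes(attr, dialect, lineno)
            start0, end1 = int(start) - 1, int(end)
            if dialect == "gtf":
                gid = attrs.get("gene_id")
                tid = attrs.get("transcript_id")
            else:
                if ftype == "gene":
                    gid, tid = attrs.get("ID"), None
                elif ftype in ("transcript", "mRNA", "lnc_RNA"):
                    gid, tid = attrs.get("Parent"), attrs.get("ID")
                else:
                    gid, tid = None, attrs.get("Parent")
            if ftype == "gene":
                if gid is None:
                    raise ValueError(f"gene without gene_id at line {lineno}")
                gene_meta[gid] = {
                    "symbol": attrs.get("gene_name") or attrs.get("Name"),
                    "biotype": _normalize_biotype(
                        attrs.get("gene_biotype")
                        or attrs.get("gene_type")
                        or attrs.get("biotype")
                    ),
                }
                if gid not in gene_order:
                    gene_order.append(gid)
            elif ftype in ("transcript", "mRNA", "lnc_RNA"):
                if tid is not None and gid is not None:
                    tx2parent[tid] = gid
            elif ftype == "exon":
                if tid is None:
                    raise ValueError(
                        f"exon without transcript id at line {lineno}"
                    )
                gid = gid or tx2parent.get(tid)
                if gid is None:
                    raise ValueError(f"exon without gene id at line {lineno}")
                tx_exons.setdefault(tid, []).append(
                    GenomicInterval(chrom, start0, end1, strand)
                )
                tx_gene[tid] = gid
                if gid not in gene_order:
                    gene_order.append(gid)

    genes: list[GeneModel] = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, exons in tx_exons.items():
        by_gene.setdefault(tx_gene[tid], []).append(TranscriptModel(tid, exons))
    for gid in gene_order:
        txs = by_gene.get(gid)
        if not txs:
            logger.warning("gene %s has no exons; dropped", gid)
            continue
        meta = gene_meta.get(gid, {})
        genes.append(
            GeneModel(
                gene_id=gid,
                biotype=meta.get("biotype", "other"),
                species=species,
                transcripts=sorted(txs, key=lambda t: t.transcript_id),
                symbol=meta.get("symbol"),
            )
        )
    return genes


_BIOTYPE_OUT = {"lncRNA": "lncRNA", "coding": "protein_coding", "other": "other"}


def write_gene_annotation(
    genes: Sequence[GeneModel], path: str | Path, dialect: str = "gtf"
) -> None:
    """Write gene models as GTF (gene/transcript/exon rows, 1-based closed)."""
    if dialect != "gtf":
        raise ValueError("only the gtf dialect is written")
    with open(path, "w") as fh:
        for g in genes:
            sp = g.span
            base = (
                f'gene_id "{g.gene_id}"; gene_biotype '
                f'"{_BIOTYPE_OUT[g.biotype]}";'
            )
            if g.symbol:
                base += f' gene_name "{g.symbol}";'
            fh.write(
                f"{sp.chrom}\tlncsynt\tgene\t{sp.start + 1}\t{sp.end}\t.\t"
                f"{sp.strand}\t.\t{base}\n"
            )
            for t in g.transcripts:
                tsp = t.span
                tattr = (
                    f'gene_id "{g.gene_id}"; transcript_id '
                    f'"{t.transcript_id}";'
                )
                fh.write(
                    f"{tsp.chrom}\tlncsynt\ttranscript\t{tsp.start + 1}\t"
                    f"{tsp.end}\t.\t{tsp.strand}\t.\t{tattr}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\tlncsynt\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{tattr}\n"
                    )


# ---------------------------------------------------------------------------
# Chain I/O
# ---------------------------------------------------------------------------

def parse_chain(path: str | Path) -> list[Chain]:
    """Read a UCSC chain file; every chain is validated against its header."""
    chains: list[Chain] = []
    cur: Chain | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("chain"):
                parts = line.split()
                if len(parts) != 13:
                    raise ValueError(f"malformed chain header: {line!r}")
                cur = Chain(
                    score=float(parts[1]),
                    t_name=parts[2], t_size=int(parts[3]),
                    t_strand=parts[4], t_start=int(parts[5]),
                    t_end=int(parts[6]),
                    q_name=parts[7], q_size=int(parts[8]),
                    q_strand=parts[9], q_start=int(parts[10]),
                    q_end=int(parts[11]),
                    blocks=[], chain_id=parts[12],
                )
                chains.append(cur)
            else:
                if cur is None:
                    raise ValueError("chain block line before any header")
                nums = [int(x) for x in line.split()]
                if len(nums) == 1:
                    cur.blocks.append((nums[0], 0, 0))
                elif len(nums) == 3:
                    cur.blocks.append((nums[0], nums[1], nums[2]))
                else:
                    raise ValueError(f"malformed chain block line: {line!r}")
    for c in chains:
        c.validate()
    return chains


def write_chain(chains: Sequence[Chain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:.0f} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# Conservation score tracks
# ---------------------------------------------------------------------------

def parse_score_track(
    path: str | Path, dialect: str = "bedgraph", strict: bool = False
) -> ScoreTrack:
    """Expand a bedGraph or fixedStep wiggle file to per-base scores.

    Scores outside [0,1] are clamped with a warning (strict mode: error);
    overlapping bedGraph records are an error in strict mode, last-wins
    otherwise.
    """
    if dialect not in ("bedgraph", "fixed_step_wig"):
        raise ValueError(f"unknown score-track dialect {dialect!r}")
    track = ScoreTrack()

    def put(chrom: str, start: int, end: int, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            if strict:
                raise ValueError(
                    f"score {value} outside [0,1] at {chrom}:{start}"
                )
            logger.warning("clamping score %s at %s:%d", value, chrom, start)
            value = min(1.0, max(0.0, value))
        arr = track.ensure(chrom, end)
        if strict and not np.isnan(arr[start:end]).all():
            raise ValueError(f"overlapping records at {chrom}:{start}-{end}")
        arr[start:end] = value

    with open(path) as fh:
        if dialect == "bedgraph":
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, end, val = line.split()[:4]
                put(chrom, int(start), int(end), float(val))
        else:
            chrom, pos, step = None, 0, 1
            for line in fh:
                line = line.strip()
                if not line or line.startswith("track"):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(p.split("=") for p in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1      # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                else:
                    if chrom is None:
                        raise ValueError("wiggle data before fixedStep header")
                    put(chrom, pos, pos + span, float(line))
                    pos += step
    return track


def write_bedgraph(track: ScoreTrack, path: str | Path) -> None:
    """Write per-base scores as run-length-merged bedGraph records."""
    with open(path, "w") as fh:
        for chrom in sorted(track.arrays):
            arr = track.arrays[chrom]
            covered = ~np.isnan(arr)
            if not covered.any():
                continue
            # run boundaries where coverage or value changes
            change = np.empty(arr.size, dtype=bool)
            change[0] = True
            same_val = (arr[1:] == arr[:-1]) | (
                np.isnan(arr[1:]) & np.isnan(arr[:-1])
            )
            change[1:] = ~same_val
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], arr.size)
            for s, e in zip(starts, ends):
                if covered[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak / FASTA / tables
# ---------------------------------------------------------------------------

def parse_bed(path: str | Path) -> list[GenomicInterval]:
    """BED6 (or BED3) records; narrowPeak files parse identically (extra
    columns ignored)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            cols = line.split()
            strand = cols[5] if len(cols) >= 6 and cols[5] in STRANDS else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(
    intervals: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_orthologs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return list(zip(df[0], df[1]))


def read_expression_matrix(
    counts_path: str | Path, labels_path: str | Path
) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts, labels.iloc[:, 0].to_dict())


# ---------------------------------------------------------------------------
# Coordinate arithmetic
# ---------------------------------------------------------------------------

def interval_overlap(
    a: GenomicInterval, b: GenomicInterval, stranded: bool = False
) -> int:
    """Overlap length in bases; 0 when chroms (or strands, if stranded) differ."""
    if a.chrom != b.chrom:
        return 0
    if stranded and a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def nearest_flanking(
    query: GenomicInterval,
    candidates: Sequence[GeneModel],
    max_dist: int = 500_000,
) -> tuple[GeneModel | None, GeneModel | None]:
    """Nearest non-overlapping candidate genes left and right of *query*
    (genomic left/right, not transcription-relative), within *max_dist*."""
    up: GeneModel | None = None
    down: GeneModel | None = None
    for g in candidates:
        sp = g.span
        if sp.chrom != query.chrom:
            continue
        if interval_overlap(sp, query) > 0:
            continue
        if sp.end <= query.start:
            if query.start - sp.end <= max_dist and (
                up is None or sp.end > up.span.end
            ):
                up = g
        elif sp.start >= query.end:
            if sp.start - query.end <= max_dist and (
                down is None or sp.start < down.span.start
            ):
                down = g
    return up, down


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
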