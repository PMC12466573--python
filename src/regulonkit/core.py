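"""Shared coordinate system, annotation/peak I/O and genomic arithmetic.

All internal coordinates are 0-based half-open.  Text formats keep their
native conventions: GFF3 is 1-based inclusive, BED/narrowPeak are 0-based
half-open.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")
_SEQ_ALPHABET = frozenset("ACGTN")
_LOCUS_TAG_RE = re.compile(r"^(?P<prefix>.+)_(?P<number>\d+)$")


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def split_locus_tag(tag: str) -> tuple[str, int]:
    """Split ``prefix_NNNNN`` into ``(prefix, int(NNNNN))``."""
    m = _LOCUS_TAG_RE.match(tag)
    if m is None:
        raise ValueError(f"locus tag {tag!r} is not of the form prefix_NNNNN")
    return m.group("prefix"), int(m.group("number"))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping nucleotides (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene with a strand-bearing interval."""

    locus_tag: str
    interval: GenomicInterval
    product: str = ""

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.locus_tag}: strand must be + or -")
        split_locus_tag(self.locus_tag)  # validates the tag format

    @property
    def tag_prefix(self) -> str:
        return split_locus_tag(self.locus_tag)[0]

    @property
    def tag_number(self) -> int:
        return split_locus_tag(self.locus_tag)[1]

    @property
    def start_codon_pos(self) -> int:
        """Genomic position of the translational start (strand-aware)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class Operon:
    """A run of >= 2 co-transcribed genes, ordered 5'->3' on the coding strand."""

    genes: tuple[GeneRecord, ...]
    strand: str

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("an operon needs at least 2 genes")
        if any(g.interval.strand != self.strand for g in self.genes):
            raise ValueError("operon genes must share one strand")
        chroms = {g.interval.chrom for g in self.genes}
        if len(chroms) != 1:
            raise ValueError("operon genes must share one chromosome")

    @property
    def locus_tags(self) -> tuple[str, ...]:
        return tuple(g.locus_tag for g in self.genes)


@dataclass(frozen=True)
class Peak:
    """A called ChIP peak with its summit and enrichment statistics."""

    interval: GenomicInterval
    summit: int
    fold_enrichment: float
    neg_log10_q: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"peak {self.name or '?'}: summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        if self.neg_log10_q < 0:
            raise ValueError("neg_log10_q must be >= 0")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with published defaults."""

    deg_fc_min: float = 1.5
    deg_fdr_max: float = 0.05
    peak_q_max: float = 0.05
    peak_fc_min: float = 1.5
    motif_fe_min: float = 1.75
    summit_flank: int = 100
    shared_min_overlap: int = 50
    promoter_upstream: int = 350
    promoter_downstream: int = 50
    scan_p_max: float = 1e-4
    relaxed_p_max: float = 1.04e-4
    motif_width: int = 15
    strong_response_frac: float = 0.5
    operon_max_gap: int = 50
    min_total_reads: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "rng_seed":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"config field {f.name} must be > 0")

    @property
    def promoter_window_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                fh,
                sort_keys=False,
            )

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered ``{chrom: SEQUENCE}`` map.

    Sequences are uppercased and validated against the {A,C,G,T,N} alphabet.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty FASTA file")
    first = text.lstrip().splitlines()[0]
    if not first.startswith(">"):
        raise ValueError(f"{path}: malformed header, first line {first[:40]!r}")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        if rec.id in genome:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("gene", "CDS")) -> list[GeneRecord]:
    """Read gene/CDS features carrying ``locus_tag`` attributes from GFF3.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Features without a locus_tag are skipped with a warning; duplicate
    locus_tags raise.
    """
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    seen_feature_ids: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype not in feature_types:
                continue
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start ({end1} < {start1})")
            attr_map = _parse_gff_attrs(attrs)
            tag = attr_map.get("locus_tag")
            if tag is None:
                logger.warning("%s:%d: %s feature without locus_tag skipped", path, lineno, ftype)
                continue
            key = (tag, ftype)
            if key in seen_feature_ids:
                raise ValueError(f"{path}:{lineno}: duplicate locus_tag {tag!r}")
            seen_feature_ids.add(key)
            if tag in seen:
                # same locus_tag appearing as both gene and CDS is normal;
                # the first feature type wins
                continue
            seen.add(tag)
            genes.append(
                GeneRecord(
                    locus_tag=tag,
                    interval=GenomicInterval(chrom, start1 - 1, end1, strand),
                    product=attr_map.get("product", ""),
                )
            )
    _check_unique_tags(genes, str(path))
    return genes


def _parse_gff_attrs(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        if k in out:
            raise ValueError(f"duplicate GFF3 attribute {k!r}")
        out[k] = v
    return out


def _check_unique_tags(genes: Sequence[GeneRecord], source: str) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.locus_tag in seen:
            raise ValueError(f"{source}: duplicate locus_tag {g.locus_tag!r}")
        seen.add(g.locus_tag)


def write_gff3(genes: Iterable[GeneRecord], path: str | Path, source: str = "regulonkit") -> None:
    """Write genes as GFF3 ``gene`` features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        source,
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# narrowPeak (ENCODE BED6+4)
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read a 10-column ENCODE narrowPeak file.

    Column 7 is the fold enrichment, column 9 the -log10(q-value) and column
    10 the summit offset relative to ``start``.  An offset of -1 (MACS "no
    summit") falls back to the interval midpoint with a warning.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(parts)}"
                )
            chrom, start_s, end_s, name, _score, _strand, fe_s, _p_s, q_s, off_s = parts
            start, end, offset = int(start_s), int(end_s), int(off_s)
            if offset == -1:
                summit = (start + end) // 2
                logger.warning(
                    "%s:%d: summit offset -1, falling back to midpoint %d",
                    path,
                    lineno,
                    summit,
                )
            else:
                summit = start + offset
                if not (start <= summit < end):
                    raise ValueError(
                        f"{path}:{lineno}: summit offset {offset} outside peak"
                    )
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, "."),
                    summit=summit,
                    fold_enrichment=float(fe_s),
                    neg_log10_q=float(q_s),
                    name=name,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name or ".",
                        "0",
                        ".",
                        f"{p.fold_enrichment:.5g}",
                        "-1",
                        f"{p.neg_log10_q:.5g}",
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


def write_bed6(
    intervals: Iterable[tuple[GenomicInterval, str, float]], path: str | Path
) -> None:
    """Write ``(interval, name, score)`` triples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), name, f"{score:.5g}", iv.strand]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genomic arithmetic
# ---------------------------------------------------------------------------

def promoter_window(
    gene: GeneRecord, cfg: PipelineConfig, chrom_len: int
) -> GenomicInterval:
    """Strand-aware promoter window around the translational start.

    For a + strand gene starting at ``s`` the window is
    ``[s - upstream, s + downstream)``; for a - strand gene ending at ``e``
    it is ``[e - downstream, e + upstream)``.  Clipped to ``[0, chrom_len)``.
    """
    iv = gene.interval
    if iv.end > chrom_len:
        raise ValueError(
            f"gene {gene.locus_tag} extends past chromosome end ({iv.end} > {chrom_len})"
        )
    if iv.strand == "+":
        lo = iv.start - cfg.promoter_upstream
        hi = iv.start + cfg.promoter_downstream
    else:
        lo = iv.end - cfg.promoter_downstream
        hi = iv.end + cfg.promoter_upstream
    lo = max(0, lo)
    hi = min(chrom_len, hi)
    return GenomicInterval(iv.chrom, lo, hi, iv.strand)


def promoter_windows(
    genes: Iterable[GeneRecord],
    cfg: PipelineConfig,
    chrom_lens: Mapping[str, int],
) -> dict[str, GenomicInterval]:
    """Promoter windows for many genes, keyed by locus tag."""
    return {
        g.locus_tag: promoter_window(g, cfg, chrom_lens[g.interval.chrom])
        for g in genes
    }


def infer_operons(genes: Sequence[GeneRecord], cfg: PipelineConfig) -> list[Operon]:
    """Group same-strand adjacent genes with gaps <= ``operon_max_gap``.

    Overlapping same-strand genes are treated as gap 0 with a warning.
    Runs of length 1 are not operons.  Genes on the - strand are ordered
    5'->3' on the coding strand (descending genomic coordinate).
    """
    operons: list[Operon] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        ordered = sorted(chrom_genes, key=lambda g: g.interval.start)
        run: list[GeneRecord] = []
        for g in ordered:
            if not run:
                run = [g]
                continue
            prev = run[-1]
            gap = g.interval.start - prev.interval.end
            if gap < 0 and g.interval.strand == prev.interval.strand:
                logger.warning(
                    "overlapping same-strand genes %s/%s treated as gap 0",
                    prev.locus_tag,
                    g.locus_tag,
                )
                gap = 0
            if g.interval.strand == prev.interval.strand and gap <= cfg.operon_max_gap:
                run.append(g)
            else:
                if len(run) >= 2:
                    operons.append(_make_operon(run))
                run = [g]
        if len(run) >= 2:
            operons.append(_make_operon(run))
    return operons


def _make_operon(run: Sequence[GeneRecord]) -> Operon:
    strand = run[0].interval.strand
    ordered = tuple(run) if strand == "+" else tuple(reversed(run))
    return Operon(genes=ordered, strand=strand)


def genes_in_locus_range(
    first_tag: str, last_tag: str, annotation: Sequence[GeneRecord]
) -> list[GeneRecord]:
    """All genes whose numeric locus-tag suffix lies in the closed range.

    Both boundary tags must share the annotation's prefix.  A boundary tag
    absent from the annotation only triggers a warning; range arithmetic
    still applies to the genes that are present.
    """
    pfx_a, num_a = split_locus_tag(first_tag)
    pfx_b, num_b = split_locus_tag(last_tag)
    if pfx_a != pfx_b:
        raise ValueError(f"locus-tag prefixes differ: {pfx_a!r} vs {pfx_b!r}")
    if num_a > num_b:
        raise ValueError(f"reversed locus range {first_tag}..{last_tag}")
    present = {g.locus_tag for g in annotation}
    for tag in (first_tag, last_tag):
        if tag not in present:
            logger.warning("boundary tag %s absent from annotation", tag)
    hits = [
        g
        for g in annotation
        if g.tag_prefix == pfx_a and num_a <= g.tag_number <= num_b
    ]
    return sorted(hits, key=lambda g: g.tag_number)
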