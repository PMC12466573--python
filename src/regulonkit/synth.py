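"""Synthetic genomes, annotations, planted motifs, peaks and NB counts.

Every generator is a pure function of its seed and parameters, and records
enough ground truth (:class:`SyntheticTruth`) to score motif recovery, DEG
recovery and direct-regulon recovery downstream without re-reading generator
internals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneRecord,
    GenomicInterval,
    Operon,
    Peak,
    PipelineConfig,
    promoter_window,
)
from .motif import PWM, decode, revcomp

logger = logging.getLogger(__name__)

CHROM = "synchr1"
TAG_PREFIX = "syn"


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    planted_pwm: PWM
    planted_sites: list[tuple[GenomicInterval, str, str]]  # interval, strand, site seq
    direct_targets: set[str]
    deg_truth: dict[str, float]  # locus_tag -> true log2FC (0 for nulls)
    peak_truth: list[Peak] = field(default_factory=list)

    def site_for_target(self, tag: str, windows: Mapping[str, GenomicInterval]) -> bool:
        win = windows[tag]
        return any(win.overlap(iv) > 0 for iv, _, _ in self.planted_sites)


def generate_genome(seed: int, length: int, gc: float) -> dict[str, str]:
    """I.i.d. genome with P(G) = P(C) = gc/2 on a single chromosome."""
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    p = np.array([at, gc / 2, gc / 2, at])  # A, C, G, T
    seq = decode(rng.choice(4, size=length, p=p))
    return {CHROM: seq}


def generate_annotation(
    seed: int,
    n_genes: int,
    genome_length: int,
    mean_len: int = 900,
    operon_frac: float = 0.3,
    operon_max_gap: int = 50,
) -> tuple[list[GeneRecord], list[Operon]]:
    """Lay out genes with step-5 locus tags; ~operon_frac of genes sit in
    same-strand runs with intra-run gaps <= operon_max_gap.

    Returns the annotation together with the generator's own operon truth
    (runs of >= 2 genes, ordered 5'->3' on the coding strand).
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    blocks: list[list[GeneRecord]] = []
    pos = 600
    placed = 0
    tag_num = 0
    while placed < n_genes:
        if rng.random() < operon_frac:
            block_size = int(rng.integers(2, 5))
        else:
            block_size = 1
        block_size = min(block_size, n_genes - placed)
        strand = "+" if rng.random() < 0.5 else "-"
        block: list[GeneRecord] = []
        for k in range(block_size):
            length = max(300, int(rng.normal(mean_len, mean_len / 5)))
            tag_num += 5
            tag = f"{TAG_PREFIX}_{tag_num:05d}"
            block.append(
                GeneRecord(tag, GenomicInterval(CHROM, pos, pos + length, strand))
            )
            pos += length
            if k < block_size - 1:
                pos += int(rng.integers(3, operon_max_gap + 1))
        placed += block_size
        blocks.append(block)
        pos += int(rng.integers(500, 900))
        genes.extend(block)
        if pos > genome_length - 600:
            raise ValueError(
                f"{n_genes} genes do not fit in a {genome_length} bp genome"
            )
    operons = [
        Operon(
            genes=tuple(b) if b[0].interval.strand == "+" else tuple(reversed(b)),
            strand=b[0].interval.strand,
        )
        for b in blocks
        if len(b) >= 2
    ]
    return genes, operons


def operon_leaders_and_singletons(
    genes: Sequence[GeneRecord], operons: Sequence[Operon]
) -> list[str]:
    """Genes that own a promoter: operon-leading genes plus singletons."""
    in_operon = {t for op in operons for t in op.locus_tags}
    leaders = {op.genes[0].locus_tag for op in operons}
    return sorted(
        g.locus_tag
        for g in genes
        if g.locus_tag in leaders or g.locus_tag not in in_operon
    )


def default_planted_pwm(background: np.ndarray | None = None) -> PWM:
    """An information-rich 15-bp PWM with a conserved core and a degenerate
    3' tail, echoing the structure of real bacterial regulator motifs."""
    if background is None:
        background = np.full(4, 0.25)
    consensus = "TGGCCGAATCCGAAC"  # fixed letters get 0.97, rest split the rest
    degenerate = {6: "AG", 8: "AT", 9: "ACT", 10: "CT", 11: "GC", 12: "AG", 13: "ACT"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    probs = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        if j in degenerate:
            allowed = degenerate[j]
            for b in allowed:
                probs[idx[b], j] = 0.94 / len(allowed)
            rest = [b for b in "ACGT" if b not in allowed]
            for b in rest:
                probs[idx[b], j] = 0.06 / len(rest)
        else:
            probs[:, j] = 0.01
            probs[idx[base], j] = 0.97
    probs /= probs.sum(axis=0, keepdims=True)
    return PWM(probs=probs, background=np.asarray(background, float))


def plant_motifs(
    genome: Mapping[str, str],
    annotation: Sequence[GeneRecord],
    pwm: PWM,
    targets: set[str],
    seed: int,
    cfg: PipelineConfig | None = None,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write one PWM-sampled site into each target's promoter window.

    Offsets are uniform within the window, strands uniform random; the
    reverse strand plants the site's reverse complement on the forward
    sequence.  Positions and sampled sequences are recorded in the truth.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    by_tag = {g.locus_tag: g for g in annotation}
    unknown = targets - set(by_tag)
    if unknown:
        raise ValueError(f"targets absent from annotation: {sorted(unknown)[:5]}")
    mutable = {chrom: list(seq) for chrom, seq in genome.items()}
    sites: list[tuple[GenomicInterval, str, str]] = []
    for tag in sorted(targets):
        gene = by_tag[tag]
        chrom = gene.interval.chrom
        win = promoter_window(gene, cfg, len(genome[chrom]))
        if len(win) < pwm.width:
            raise ValueError(f"promoter window of {tag} shorter than the motif")
        offset = int(rng.integers(0, len(win) - pwm.width + 1))
        start = win.start + offset
        site = pwm.sample(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = site if strand == "+" else revcomp(site)
        mutable[chrom][start : start + pwm.width] = list(written)
        sites.append(
            (GenomicInterval(chrom, start, start + pwm.width, "."), strand, site)
        )
    new_genome = {chrom: "".join(chars) for chrom, chars in mutable.items()}
    truth = SyntheticTruth(
        planted_pwm=pwm,
        planted_sites=sites,
        direct_targets=set(targets),
        deg_truth={g.locus_tag: 0.0 for g in annotation},
    )
    return new_genome, truth


def assign_deg_truth(
    truth: SyntheticTruth,
    seed: int,
    lfc_range: tuple[float, float] = (1.0, 3.0),
    extra_deg_tags: Sequence[str] = (),
) -> None:
    """Give each direct target (and any extra indirect DEGs) a true log2FC
    with |log2FC| uniform in ``lfc_range`` and a random sign (50/50)."""
    rng = np.random.default_rng(seed)
    for tag in sorted(set(truth.direct_targets) | set(extra_deg_tags)):
        mag = rng.uniform(*lfc_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.deg_truth[tag] = sign * mag


def simulate_peaks(
    truth: SyntheticTruth,
    n_noise: int,
    chrom_lens: Mapping[str, int],
    seed: int,
    width_mean: int = 1050,
    fe_range: tuple[float, float] = (1.0, 3.0),
    signal_fe_range: tuple[float, float] = (2.0, 8.0),
    max_retries: int = 1000,
) -> list[Peak]:
    """One peak per planted site (summit within +/-20 bp of the site
    midpoint, FE from ``signal_fe_range``) plus ``n_noise`` peaks at
    motif-free positions with FE drawn from ``fe_range``.

    Widths are Normal(width_mean, width_mean/5) truncated at 200 bp.
    """
    rng = np.random.default_rng(seed)
    peaks: list[Peak] = []
    site_mids: dict[str, list[int]] = {}
    for iv, _, _ in truth.planted_sites:
        site_mids.setdefault(iv.chrom, []).append(int(iv.midpoint))

    def _peak(chrom: str, summit: int, fe: float, name: str) -> Peak:
        width = max(200, int(rng.normal(width_mean, width_mean / 5)))
        clen = chrom_lens[chrom]
        start = max(0, summit - width // 2)
        end = min(clen, start + width)
        start = min(start, summit)  # keep the summit inside after clipping
        end = max(end, summit + 1)
        return Peak(
            interval=GenomicInterval(chrom, start, end, "."),
            summit=summit,
            fold_enrichment=fe,
            neg_log10_q=float(rng.uniform(1.5, 10.0)),
            name=name,
        )

    for i, (iv, _, _) in enumerate(truth.planted_sites):
        summit = int(iv.midpoint) + int(rng.integers(-20, 21))
        summit = min(max(summit, 0), chrom_lens[iv.chrom] - 1)
        fe = float(rng.uniform(*signal_fe_range))
        peaks.append(_peak(iv.chrom, summit, fe, f"signal_{i}"))

    for i in range(n_noise):
        chrom = list(chrom_lens)[int(rng.integers(len(chrom_lens)))]
        clen = chrom_lens[chrom]
        for attempt in range(max_retries):
            summit = int(rng.integers(300, clen - 300))
            if all(abs(summit - m) > 400 for m in site_mids.get(chrom, [])):
                break
        else:
            raise RuntimeError("could not place a motif-free noise peak")
        fe = float(rng.uniform(*fe_range))
        peaks.append(_peak(chrom, summit, fe, f"noise_{i}"))

    truth.peak_truth = peaks
    return peaks


def simulate_counts(
    annotation: Sequence[GeneRecord],
    deg_truth: Mapping[str, float],
    seed: int,
    n_reps: int = 3,
    dispersion: float = 0.02,
    lib_sizes: Sequence[float] | None = None,
    baseline_range: tuple[float, float] = (50.0, 5000.0),
    group_names: tuple[str, str] = ("complemented", "mutant"),
) -> tuple[pd.DataFrame, list[str]]:
    """Negative-binomial counts for reference vs mutant groups.

    Means are baseline * 2^log2FC in the mutant group with baselines
    log-uniform over ``baseline_range``; variance is mu + dispersion * mu^2.
    ``lib_sizes`` are relative per-sample depth factors (default all 1).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    n_samples = 2 * n_reps
    if lib_sizes is None:
        lib_sizes = [1.0] * n_samples
    lib_sizes = list(lib_sizes)
    if len(lib_sizes) != n_samples:
        raise ValueError(f"need {n_samples} lib_sizes, got {len(lib_sizes)}")
    if any(s <= 0 for s in lib_sizes):
        raise ValueError("lib_sizes must be positive")
    rng = np.random.default_rng(seed)
    tags = [g.locus_tag for g in annotation]
    lo, hi = np.log(baseline_range[0]), np.log(baseline_range[1])
    baselines = np.exp(rng.uniform(lo, hi, size=len(tags)))
    lfc = np.array([deg_truth.get(t, 0.0) for t in tags])
    ref_mean = baselines
    mut_mean = baselines * 2.0 ** lfc
    r = 1.0 / dispersion
    cols = {}
    names = []
    for rep in range(n_reps):
        name = f"{group_names[0]}_{rep + 1}"
        mu = ref_mean * lib_sizes[rep]
        cols[name] = rng.negative_binomial(r, r / (r + mu))
        names.append(group_names[0])
    for rep in range(n_reps):
        name = f"{group_names[1]}_{rep + 1}"
        mu = mut_mean * lib_sizes[n_reps + rep]
        cols[name] = rng.negative_binomial(r, r / (r + mu))
        names.append(group_names[1])
    counts = pd.DataFrame(cols, index=pd.Index(tags, name="locus_tag"))
    return counts, names


# ---------------------------------------------------------------------------
# Bundled dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, plus the truth to score it."""

    genome: dict[str, str]
    annotation: list[GeneRecord]
    operons: list[Operon]
    truth: SyntheticTruth
    peaks: list[Peak]
    counts: pd.DataFrame
    groups: list[str]
    cfg: PipelineConfig

    @property
    def chrom_lens(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def generate_dataset(
    seed: int,
    n_genes: int = 200,
    n_targets: int = 50,
    n_noise_peaks: int = 100,
    dispersion: float = 0.02,
    gc: float = 0.72,
    mean_len: int = 900,
    operon_frac: float = 0.3,
    n_extra_degs: int = 0,
    cfg: PipelineConfig | None = None,
    pwm: PWM | None = None,
) -> SyntheticDataset:
    """Generate a complete, internally consistent synthetic dataset.

    Direct targets are drawn from promoter-owning genes (operon leaders and
    singletons) so that planted sites sit in the promoter that the pipeline
    will attribute the binding to.
    """
    cfg = cfg or PipelineConfig()
    # generous upper bound on the span of the laid-out genes
    genome_length = int(n_genes * (mean_len * 1.4 + 900) + 4000)
    genome = generate_genome(seed, genome_length, gc)
    annotation, operons = generate_annotation(
        seed + 1,
        n_genes,
        genome_length,
        mean_len=mean_len,
        operon_frac=operon_frac,
        operon_max_gap=cfg.operon_max_gap,
    )
    rng = np.random.default_rng(seed + 2)
    eligible = operon_leaders_and_singletons(annotation, operons)
    if n_targets > len(eligible):
        raise ValueError(
            f"{n_targets} targets requested but only {len(eligible)} promoter-owning genes"
        )
    targets = set(rng.choice(eligible, size=n_targets, replace=False).tolist())
    pwm = pwm or default_planted_pwm()
    genome, truth = plant_motifs(genome, annotation, pwm, targets, seed + 3, cfg)
    non_targets = [g.locus_tag for g in annotation if g.locus_tag not in targets]
    extra = (
        rng.choice(non_targets, size=min(n_extra_degs, len(non_targets)), replace=False).tolist()
        if n_extra_degs
        else []
    )
    assign_deg_truth(truth, seed + 4, extra_deg_tags=extra)
    chrom_lens = {c: len(s) for c, s in genome.items()}
    peaks = simulate_peaks(truth, n_noise_peaks, chrom_lens, seed + 5)
    counts, groups = simulate_counts(
        annotation, truth.deg_truth, seed + 6, dispersion=dispersion
    )
    return SyntheticDataset(
        genome=genome,
        annotation=annotation,
        operons=operons,
        truth=truth,
        peaks=peaks,
        counts=counts,
        groups=groups,
        cfg=cfg,
    )


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def truth_to_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_pwm": {
            "probs": truth.planted_pwm.probs.tolist(),
            "background": truth.planted_pwm.background.tolist(),
        },
        "planted_sites": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "strand": strand, "seq": seq}
            for iv, strand, seq in truth.planted_sites
        ],
        "direct_targets": sorted(truth.direct_targets),
        "deg_truth": truth.deg_truth,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def truth_from_json(path: str | Path) -> SyntheticTruth:
    data = json.loads(Path(path).read_text())
    pwm = PWM(
        probs=np.array(data["planted_pwm"]["probs"]),
        background=np.array(data["planted_pwm"]["background"]),
    )
    sites = [
        (
            GenomicInterval(s["chrom"], s["start"], s["end"], "."),
            s["strand"],
            s["seq"],
        )
        for s in data["planted_sites"]
    ]
    return SyntheticTruth(
        planted_pwm=pwm,
        planted_sites=sites,
        direct_targets=set(data["direct_targets"]),
        deg_truth={k: float(v) for k, v in data["deg_truth"].items()},
    )
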