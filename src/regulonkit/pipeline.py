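"""End-to-end orchestration: peaks -> motif -> promoters -> DEGs -> regulon."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    GeneRecord,
    GenomicInterval,
    Operon,
    Peak,
    PipelineConfig,
    infer_operons,
    promoter_windows,
)
from .de import DEGRecord, run_de
from .motif import PWM, MotifHit, em_discover, prep_peaks, scan_regions, scan_sequences
from .regulon import (
    DirectRegulonEntry,
    PromoterAssignment,
    assign_hits_to_promoters,
    build_direct_regulon,
    operon_attribution,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one integration run produces."""

    fragments: list[GenomicInterval]
    pwm: PWM
    stringent_hits: list[MotifHit]
    windows: dict[str, GenomicInterval]
    operons: list[Operon]
    assignments: list[PromoterAssignment]
    degs: list[DEGRecord]
    entries: list[DirectRegulonEntry]
    bound_only: list[str]


def run_pipeline(
    genome: Mapping[str, str],
    annotation: Sequence[GeneRecord],
    peaks: Sequence[Peak],
    counts: pd.DataFrame,
    groups: Sequence[str],
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    restarts: int = 8,
    timepoint: str = "t1",
    pwm: PWM | None = None,
    degs: Sequence[DEGRecord] | None = None,
    reference: str | None = None,
) -> PipelineResult:
    """Run the full integration for one time point.

    Peaks are summit-centered/trimmed/FE-filtered; a motif is discovered on
    the fragments by EM (unless a PWM is supplied); fragments are scanned at
    the stringent threshold (p < scan_p_max); hits are assigned to promoter
    windows with operon-aware attribution; and bound genes are intersected
    with classified DEGs (computed here unless supplied).
    """
    cfg = cfg or PipelineConfig()
    chrom_lens = {c: len(s) for c, s in genome.items()}
    fragments = prep_peaks(peaks, cfg, chrom_lens)
    logger.info("%d/%d peaks retained after FE filter", len(fragments), len(peaks))
    if pwm is None:
        frag_seqs = [genome[f.chrom][f.start : f.end] for f in fragments]
        pwm, _ = em_discover(frag_seqs, cfg.motif_width, restarts=restarts, seed=seed)
    hits = scan_regions(
        pwm, genome, fragments, cfg.scan_p_max, both_strands=True, inclusive=False
    )
    windows = promoter_windows(annotation, cfg, chrom_lens)
    operons = infer_operons(list(annotation), cfg)
    assignments, _unassigned = assign_hits_to_promoters(hits, windows)
    assignments = operon_attribution(assignments, operons, annotation)
    if degs is None:
        degs = run_de(counts, groups, cfg, reference=reference)
    entries, bound_only = build_direct_regulon(assignments, degs, timepoint)
    return PipelineResult(
        fragments=fragments,
        pwm=pwm,
        stringent_hits=hits,
        windows=windows,
        operons=operons,
        assignments=assignments,
        degs=list(degs),
        entries=entries,
        bound_only=bound_only,
    )


def relaxed_genome_scan(
    pwm: PWM, genome: Mapping[str, str], cfg: PipelineConfig | None = None
) -> list[MotifHit]:
    """Genome-wide scan at the relaxed threshold (p <= relaxed_p_max)."""
    cfg = cfg or PipelineConfig()
    return scan_sequences(
        pwm, dict(genome), cfg.relaxed_p_max, both_strands=True, inclusive=True
    )
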