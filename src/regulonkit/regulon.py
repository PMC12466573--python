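"""Promoter assignment of motif hits, operon-aware attribution and the
direct-regulon construction that integrates binding with expression."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import GeneRecord, GenomicInterval, Operon, round_half_up, split_locus_tag
from .de import DEGRecord
from .motif import MotifHit

logger = logging.getLogger(__name__)


@dataclass
class PromoterAssignment:
    """A motif hit together with every gene whose promoter window it touches."""

    hit: MotifHit
    genes: list[str]
    co_regulated: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DirectRegulonEntry:
    """A gene that is both promoter-bound and differentially expressed.

    ``mode='activated'`` corresponds to ``deg_status='down'``: the gene loses
    expression when the regulator is deleted.
    """

    locus_tag: str
    timepoint: str
    hits: tuple[MotifHit, ...]
    deg_status: str
    mode: str

    def __post_init__(self) -> None:
        if self.deg_status not in ("up", "down"):
            raise ValueError("direct-regulon entries require status up or down")
        expected = "activated" if self.deg_status == "down" else "repressed"
        if self.mode != expected:
            raise ValueError(f"mode {self.mode!r} inconsistent with status {self.deg_status!r}")
        if not self.hits:
            raise ValueError("direct-regulon entries require >= 1 hit")


def assign_hits_to_promoters(
    hits: Sequence[MotifHit],
    windows: Mapping[str, GenomicInterval],
    full_containment: bool = False,
) -> tuple[list[PromoterAssignment], list[MotifHit]]:
    """Assign each hit to every gene whose promoter window it overlaps.

    The default criterion is >= 1 nt of overlap; ``full_containment``
    requires the hit to lie entirely inside the window.  Hits touching no
    window are returned separately as unassigned.
    """
    assignments: list[PromoterAssignment] = []
    unassigned: list[MotifHit] = []
    items = sorted(windows.items(), key=lambda kv: (kv[1].chrom, kv[1].start))
    for hit in hits:
        genes = []
        for tag, win in items:
            if full_containment:
                ok = win.contains(hit.interval)
            else:
                ok = win.overlap(hit.interval) >= 1
            if ok:
                genes.append(tag)
        if genes:
            assignments.append(PromoterAssignment(hit=hit, genes=genes))
        else:
            unassigned.append(hit)
    return assignments, unassigned


def operon_attribution(
    assignments: Sequence[PromoterAssignment],
    operons: Sequence[Operon],
    annotation: Sequence[GeneRecord],
) -> list[PromoterAssignment]:
    """Keep only the operon gene nearest each hit; record the rest.

    When two or more genes of one operon appear in a hit's gene list, only
    the gene whose start codon is closest to the hit midpoint survives
    (ties break toward the smaller locus suffix, logged).  The displaced
    members are kept as ``co_regulated`` — putatively co-transcribed but
    excluded from the strict regulon.  Genes outside operons are untouched.
    """
    operon_of: dict[str, int] = {}
    for i, op in enumerate(operons):
        for tag in op.locus_tags:
            operon_of[tag] = i
    start_of = {g.locus_tag: g.start_codon_pos for g in annotation}
    out: list[PromoterAssignment] = []
    for a in assignments:
        by_operon: dict[int, list[str]] = {}
        solo: list[str] = []
        for tag in a.genes:
            if tag in operon_of:
                by_operon.setdefault(operon_of[tag], []).append(tag)
            else:
                solo.append(tag)
        kept = list(solo)
        dropped: list[str] = []
        mid = a.hit.interval.midpoint
        for tags in by_operon.values():
            if len(tags) == 1:
                kept.append(tags[0])
                continue
            ranked = sorted(
                tags,
                key=lambda t: (abs(start_of[t] - mid), split_locus_tag(t)[1]),
            )
            dists = [abs(start_of[t] - mid) for t in ranked]
            if len(dists) > 1 and dists[0] == dists[1]:
                logger.info(
                    "distance tie at hit %s; keeping %s (smaller suffix)",
                    a.hit.interval,
                    ranked[0],
                )
            kept.append(ranked[0])
            dropped.extend(ranked[1:])
        out.append(
            PromoterAssignment(
                hit=a.hit,
                genes=sorted(kept, key=lambda t: split_locus_tag(t)[1]),
                co_regulated=sorted(dropped, key=lambda t: split_locus_tag(t)[1]),
            )
        )
    return out


def build_direct_regulon(
    assignments: Sequence[PromoterAssignment],
    degs: Sequence[DEGRecord],
    timepoint: str = "t1",
) -> tuple[list[DirectRegulonEntry], list[str]]:
    """Intersect promoter-bound genes with classified DEGs.

    Returns one entry per gene with >= 1 assigned hit and a non-ns DEG
    status, plus the side list of bound-but-not-differentially-expressed
    genes.  A gene is counted once regardless of its number of hits.
    """
    status = {d.locus_tag: d.status for d in degs}
    hits_by_gene: dict[str, list[MotifHit]] = {}
    for a in assignments:
        for tag in a.genes:
            hits_by_gene.setdefault(tag, []).append(a.hit)
    entries: list[DirectRegulonEntry] = []
    bound_only: list[str] = []
    for tag in sorted(hits_by_gene, key=lambda t: split_locus_tag(t)[1]):
        st = status.get(tag, "ns")
        if st == "ns":
            bound_only.append(tag)
            continue
        entries.append(
            DirectRegulonEntry(
                locus_tag=tag,
                timepoint=timepoint,
                hits=tuple(hits_by_gene[tag]),
                deg_status=st,
                mode="activated" if st == "down" else "repressed",
            )
        )
    return entries, bound_only


def regulon_summary(
    entries_t1: Sequence[DirectRegulonEntry],
    entries_t2: Sequence[DirectRegulonEntry],
    degs_t1: Sequence[DEGRecord],
    degs_t2: Sequence[DEGRecord],
    labels: tuple[str, str] = ("t1", "t2"),
) -> dict:
    """Per-time-point regulon size, activated fraction and share of DEGs.

    Percentages are rounded half-up to integers; None when undefined.
    """
    out: dict = {"timepoints": {}}
    sets = []
    for label, entries, degs in zip(labels, (entries_t1, entries_t2), (degs_t1, degs_t2)):
        n = len(entries)
        n_act = sum(1 for e in entries if e.mode == "activated")
        n_deg = sum(1 for d in degs if d.status != "ns")
        out["timepoints"][label] = {
            "n_entries": n,
            "n_activated": n_act,
            "pct_activated": round_half_up(100 * n_act / n) if n else None,
            "pct_of_degs": round_half_up(100 * n / n_deg) if n_deg else None,
        }
        sets.append({e.locus_tag for e in entries})
    out["n_shared"] = len(sets[0] & sets[1])
    return out


def relaxed_regulon(
    relaxed_hits: Sequence[MotifHit],
    windows: Mapping[str, GenomicInterval],
    degs: Sequence[DEGRecord],
    stringent_entries: Sequence[DirectRegulonEntry] = (),
    full_containment: bool = False,
) -> dict[str, set[str]]:
    """Nested gene sets from a relaxed genome-wide scan.

    Returns ``relaxed_bound`` (genes with any relaxed promoter hit),
    ``relaxed_deg`` (the subset that are DEGs), and ``stringent`` (the strict
    direct regulon, asserted to be contained in ``relaxed_deg`` when one is
    supplied).
    """
    assignments, _ = assign_hits_to_promoters(relaxed_hits, windows, full_containment)
    bound = {tag for a in assignments for tag in a.genes}
    deg_tags = {d.locus_tag for d in degs if d.status != "ns"}
    relaxed_deg = bound & deg_tags
    stringent = {e.locus_tag for e in stringent_entries}
    if stringent and not stringent <= relaxed_deg:
        missing = sorted(stringent - relaxed_deg)
        raise AssertionError(
            f"stringent regulon not nested in relaxed scan: {missing[:5]}..."
        )
    return {"relaxed_bound": bound, "relaxed_deg": relaxed_deg, "stringent": stringent}


def regulon_to_rows(entries: Sequence[DirectRegulonEntry], degs: Sequence[DEGRecord]) -> list[dict]:
    """Flatten entries for the TSV report."""
    by_tag = {d.locus_tag: d for d in degs}
    rows = []
    for e in entries:
        d = by_tag[e.locus_tag]
        rows.append(
            {
                "locus_tag": e.locus_tag,
                "timepoint": e.timepoint,
                "n_hits": len(e.hits),
                "best_p": min(h.p_value for h in e.hits),
                "deg_log2fc": d.log2fc,
                "deg_fdr": d.fdr,
                "mode": e.mode,
            }
        )
    return rows
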