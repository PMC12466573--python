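"""Per-cluster summaries of expression changes and binding sites, plus a
hypergeometric over-representation stand-in for pathway enrichment."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .core import (
    GeneRecord,
    GenomicInterval,
    PipelineConfig,
    genes_in_locus_range,
    round_half_up,
    split_locus_tag,
)
from .de import DEGRecord, bh_fdr
from .motif import MotifHit

logger = logging.getLogger(__name__)

_BGC_COLUMNS = ("bgc_id", "bgc_type", "first_tag", "last_tag")


@dataclass(frozen=True)
class BGCRecord:
    """One biosynthetic gene cluster defined by a locus-tag range."""

    bgc_id: int
    bgc_type: str
    first_tag: str
    last_tag: str
    product: str = ""

    def __post_init__(self) -> None:
        pfx_a, num_a = split_locus_tag(self.first_tag)
        pfx_b, num_b = split_locus_tag(self.last_tag)
        if pfx_a != pfx_b:
            raise ValueError(f"BGC {self.bgc_id}: mixed locus-tag prefixes")
        if num_a > num_b:
            raise ValueError(f"BGC {self.bgc_id}: reversed gene range")

    @property
    def suffix_range(self) -> tuple[int, int]:
        return split_locus_tag(self.first_tag)[1], split_locus_tag(self.last_tag)[1]


@dataclass
class BGCSummary:
    """Table-row summary of one cluster across time points."""

    bgc_id: int
    bgc_type: str
    n_genes: int
    pct_down: dict[str, int]
    pct_up: dict[str, int]
    n_sites: int
    n_promoter_sites: int
    strong_response: dict[str, bool]
    local_regulator_affected: bool = False


def load_bgc_table(
    path: str | Path,
    annotation: Sequence[GeneRecord] | None = None,
    allow_overlap: bool = False,
) -> list[BGCRecord]:
    """Read a BGC definition TSV with columns bgc_id, bgc_type, first_tag,
    last_tag (and optionally product).

    Ranges are validated against the annotation's locus-tag prefix when an
    annotation is given; overlapping ranges are rejected unless
    ``allow_overlap`` is set.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_BGC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing BGC columns {sorted(missing)}")
    records: list[BGCRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(
                BGCRecord(
                    bgc_id=int(row["bgc_id"]),
                    bgc_type=str(row["bgc_type"]),
                    first_tag=str(row["first_tag"]),
                    last_tag=str(row["last_tag"]),
                    product=str(row.get("product", "") or ""),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed BGC row {i + 1}: {exc}") from exc
    if annotation:
        prefix = annotation[0].tag_prefix
        for rec in records:
            if split_locus_tag(rec.first_tag)[0] != prefix:
                raise ValueError(
                    f"BGC {rec.bgc_id}: prefix does not match annotation ({prefix!r})"
                )
    if not allow_overlap:
        spans = sorted((r.suffix_range, r.bgc_id) for r in records)
        for (a, id_a), (b, id_b) in zip(spans, spans[1:]):
            if b[0] <= a[1]:
                raise ValueError(
                    f"BGC ranges overlap (BGC {id_a} and BGC {id_b}); "
                    "pass allow_overlap=True to accept"
                )
    return records


def bgc_span(bgc: BGCRecord, annotation: Sequence[GeneRecord]) -> GenomicInterval:
    """Genomic interval covered by the cluster's member genes."""
    members = genes_in_locus_range(bgc.first_tag, bgc.last_tag, annotation)
    if not members:
        raise ValueError(f"BGC {bgc.bgc_id}: no member genes in annotation")
    chrom = members[0].interval.chrom
    return GenomicInterval(
        chrom,
        min(g.interval.start for g in members),
        max(g.interval.end for g in members),
        ".",
    )


def bgc_summary(
    bgc: BGCRecord,
    annotation: Sequence[GeneRecord],
    degs_by_timepoint: Mapping[str, Sequence[DEGRecord]],
    hits: Sequence[MotifHit],
    promoter_assigned_tags: set[str] | None = None,
    cfg: PipelineConfig | None = None,
) -> BGCSummary:
    """Summarize one cluster: rounded %down/%up per time point, raw motif
    occurrences inside the cluster's genomic span, and the strong-response
    flag ((n_down + n_up)/n_genes strictly > strong_response_frac).
    """
    cfg = cfg or PipelineConfig()
    members = genes_in_locus_range(bgc.first_tag, bgc.last_tag, annotation)
    if not members:
        raise ValueError(f"BGC {bgc.bgc_id}: no member genes in annotation")
    tags = {g.locus_tag for g in members}
    n_genes = len(members)
    span = bgc_span(bgc, annotation)
    n_sites = sum(1 for h in hits if span.contains(h.interval))
    n_promoter_sites = 0
    if promoter_assigned_tags is not None:
        n_promoter_sites = len(tags & promoter_assigned_tags)
    pct_down: dict[str, int] = {}
    pct_up: dict[str, int] = {}
    strong: dict[str, bool] = {}
    for label, degs in degs_by_timepoint.items():
        n_down = sum(1 for d in degs if d.locus_tag in tags and d.status == "down")
        n_up = sum(1 for d in degs if d.locus_tag in tags and d.status == "up")
        frac_deg = (n_down + n_up) / n_genes
        if frac_deg > 1:
            raise AssertionError(f"BGC {bgc.bgc_id}: DEG fraction {frac_deg} > 1")
        pct_down[label] = round_half_up(100 * n_down / n_genes)
        pct_up[label] = round_half_up(100 * n_up / n_genes)
        strong[label] = frac_deg > cfg.strong_response_frac
    return BGCSummary(
        bgc_id=bgc.bgc_id,
        bgc_type=bgc.bgc_type,
        n_genes=n_genes,
        pct_down=pct_down,
        pct_up=pct_up,
        n_sites=n_sites,
        n_promoter_sites=n_promoter_sites,
        strong_response=strong,
    )


def count_strong_responses(summaries: Sequence[BGCSummary]) -> dict[str, int]:
    """Number of clusters flagged strong per time point."""
    out: dict[str, int] = {}
    for s in summaries:
        for label, flag in s.strong_response.items():
            out[label] = out.get(label, 0) + int(flag)
    return out


def ora_enrichment(
    gene_set: set[str],
    pathway_map: Mapping[str, Sequence[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway, BH-adjusted.

    p = P(X >= k) with k = |gene_set ∩ pathway|, K = |pathway ∩ universe|,
    n = |gene_set|, N = |universe|.  This is an ORA stand-in, not a GSEA.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if not pathway_map:
        raise ValueError("no pathways supplied")
    pathways: dict[str, set[str]] = {}
    for gene, labels in pathway_map.items():
        if gene not in universe:
            continue
        for label in labels:
            pathways.setdefault(label, set()).add(gene)
    big_n = len(universe)
    n = len(gene_set)
    rows = []
    for label, members in sorted(pathways.items()):
        big_k = len(members)
        k = len(gene_set & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        rows.append({"pathway": label, "overlap": k, "pathway_size": big_k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("pathway")
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def render_report(
    summaries: Sequence[BGCSummary],
    regulon_summary: Mapping,
    deg_summary: Mapping,
    out_prefix: str | Path,
    timepoints: Sequence[str] = ("t1", "t2"),
) -> tuple[Path, Path]:
    """Write the per-cluster table as TSV plus a machine-readable JSON twin.

    Output is deterministic: clusters are ordered by id and column order is
    fixed, so re-rendering identical inputs is byte-identical.
    """
    out_prefix = Path(out_prefix)
    rows = []
    for s in sorted(summaries, key=lambda s: s.bgc_id):
        row = {"bgc_id": s.bgc_id, "bgc_type": s.bgc_type, "n_genes": s.n_genes}
        for tp in timepoints:
            row[f"pct_down_{tp}"] = s.pct_down.get(tp, 0)
            row[f"pct_up_{tp}"] = s.pct_up.get(tp, 0)
            row[f"strong_{tp}"] = int(s.strong_response.get(tp, False))
        row["n_sites"] = s.n_sites
        row["n_promoter_sites"] = s.n_promoter_sites
        rows.append(row)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    payload = {
        "bgc_summaries": rows,
        "strong_response_counts": count_strong_responses(summaries),
        "regulon_summary": dict(regulon_summary),
        "deg_summary": dict(deg_summary),
        "note": "pathway enrichment, when present, is hypergeometric ORA (not GSEA)",
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path
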