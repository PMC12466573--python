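"""Differential expression: TMM normalization, a fold-change-threshold
negative-binomial test, BH correction and DEG classification/summaries.

The threshold test is a documented stand-in for an edgeR-style
quasi-likelihood fit: per-gene NB means with method-of-moments tagwise
dispersions shrunk 50/50 toward the common value, and a Wald statistic
measured against the nearer boundary of |log2FC| = log2(fc_min) (the
shifted-null convention), so genes whose observed fold change sits inside
the threshold band get p >= 0.5 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PipelineConfig, round_half_up

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression verdict.

    ``log2fc`` is mutant minus complemented; ``status='down'`` therefore
    means the gene is activated by the regulator.
    """

    locus_tag: str
    log2fc: float
    p_value: float
    fdr: float
    status: str  # up | down | ns

    def __post_init__(self) -> None:
        if self.status not in ("up", "down", "ns"):
            raise ValueError(f"invalid DEG status {self.status!r}")


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    M-values are trimmed by ``trim_m`` on each tail and A-values by
    ``trim_a``; the weighted mean of the surviving M-values (inverse
    asymptotic-variance weights) gives each sample's log2 factor relative to
    a reference column.  Factors are rescaled to geometric mean 1.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("counts must be a genes x samples matrix with >= 2 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample in count matrix")
    # reference: sample whose upper quartile of scaled counts is most typical
    uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    log_factors = np.array(
        [_tmm_pair(x[:, j], lib[j], x[:, ref_idx], lib[ref_idx], trim_m, trim_a)
         for j in range(x.shape[1])]
    )
    factors = 2.0 ** (log_factors - log_factors.mean())
    return factors


def _tmm_pair(
    obs: np.ndarray,
    n_obs: float,
    ref: np.ndarray,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 0.0
    p_obs, p_ref = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    if np.ptp(m) < 1e-10:  # identical profiles after library scaling
        return 0.0
    # asymptotic binomial variance of each M-value
    w = (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


# ---------------------------------------------------------------------------
# Fold-change-threshold NB test
# ---------------------------------------------------------------------------

def treat_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    cfg: PipelineConfig | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Test each gene against H0: |log2FC| <= log2(deg_fc_min).

    ``groups`` labels each column of ``counts`` with one of two levels;
    ``reference`` names the baseline level (default: first label seen) and
    log2fc is the non-reference level relative to it.  Genes with fewer than
    ``cfg.min_total_reads`` reads across all libraries are dropped.
    Returns a DataFrame indexed by gene with columns log2fc, p_value.
    """
    cfg = cfg or PipelineConfig()
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly 2 group levels required, got {levels}")
    ref = levels[0] if reference is None else reference
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among group labels {levels}")
    other = next(l for l in levels if l != ref)
    groups = np.asarray(groups)
    idx_ref = np.nonzero(groups == ref)[0]
    idx_alt = np.nonzero(groups == other)[0]
    if len(idx_ref) < 2 or len(idx_alt) < 2:
        raise ValueError("each group needs >= 2 replicates")

    keep = counts.sum(axis=1) >= cfg.min_total_reads
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d low-expression genes (< %d total reads)",
                    dropped, cfg.min_total_reads)
    mat = counts.loc[keep]
    x = mat.to_numpy(dtype=float)

    lib = x.sum(axis=0)
    factors = tmm_factors(x)
    eff_lib = lib * factors
    size = eff_lib / np.exp(np.mean(np.log(eff_lib)))  # geometric-mean-1 sizes

    alpha = _shrunken_dispersions(x, size, idx_ref, idx_alt)

    prior = 0.125
    c_ref = (x[:, idx_ref] / size[idx_ref]).mean(axis=1)
    c_alt = (x[:, idx_alt] / size[idx_alt]).mean(axis=1)
    log2fc = np.log2(c_alt + prior) - np.log2(c_ref + prior)

    var_ln_ref = _var_log_group_mean(np.maximum(c_ref, prior), size[idx_ref], alpha)
    var_ln_alt = _var_log_group_mean(np.maximum(c_alt, prior), size[idx_alt], alpha)
    se_ln = np.sqrt(var_ln_ref + var_ln_alt)

    tau = np.log(cfg.deg_fc_min)
    abs_lnfc = np.abs(log2fc) * np.log(2.0)
    # shifted null: statistic against the nearer threshold boundary
    z_near = (abs_lnfc - tau) / se_ln
    z_far = (abs_lnfc + tau) / se_ln
    p = np.minimum(stats.norm.sf(z_near) + stats.norm.sf(z_far), 1.0)
    p = np.maximum(p, np.finfo(float).tiny)

    return pd.DataFrame({"log2fc": log2fc, "p_value": p}, index=mat.index)


def _var_log_group_mean(
    c: np.ndarray, size: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Delta-method variance of log group-mean concentration.

    With counts ~ NB(mean c*s_j, dispersion alpha) and the estimator
    mean_j(count_j / s_j): Var(log c_hat) ~= (1/n^2) * sum_j (1/(c s_j) + alpha).
    """
    n = len(size)
    return (np.sum(1.0 / np.outer(c, size), axis=1) + n * alpha) / n ** 2


def _shrunken_dispersions(
    x: np.ndarray, size: np.ndarray, idx_ref: np.ndarray, idx_alt: np.ndarray
) -> np.ndarray:
    """Method-of-moments tagwise NB dispersions shrunk toward the common value."""
    y = x / size  # normalized counts
    tag = np.zeros(x.shape[0])
    weight = np.zeros(x.shape[0])
    for idx in (idx_ref, idx_alt):
        mu = y[:, idx].mean(axis=1)
        var = y[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mu) / mu ** 2
        a = np.where(np.isfinite(a), a, 0.0)
        tag += np.clip(a, 0.0, 10.0) * (len(idx) - 1)
        weight += len(idx) - 1
    tag /= weight
    common = float(np.median(tag[tag > 0])) if (tag > 0).any() else 1e-4
    return np.maximum(0.5 * tag + 0.5 * common, 1e-6)


# ---------------------------------------------------------------------------
# FDR and classification
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_degs(
    table: pd.DataFrame, cfg: PipelineConfig | None = None
) -> list[DEGRecord]:
    """Label genes up/down/ns at FC >= fc_min (inclusive) and FDR < fdr_max
    (strict).

    ``table`` must carry log2fc plus either fdr or p_value (in which case
    BH is applied here).
    """
    cfg = cfg or PipelineConfig()
    if "fdr" in table.columns:
        fdr = table["fdr"].to_numpy(dtype=float)
    elif "p_value" in table.columns:
        fdr = bh_fdr(table["p_value"].to_numpy(dtype=float))
    else:
        raise ValueError("table needs an 'fdr' or 'p_value' column")
    p = (
        table["p_value"].to_numpy(dtype=float)
        if "p_value" in table.columns
        else fdr.copy()
    )
    lfc = table["log2fc"].to_numpy(dtype=float)
    log2_thr = np.log2(cfg.deg_fc_min)
    records = []
    for tag, l, pv, q in zip(table.index, lfc, p, fdr):
        passes = (abs(l) >= log2_thr - 1e-12) and (q < cfg.deg_fdr_max)
        status = "ns"
        if passes:
            status = "up" if l > 0 else "down"
        records.append(DEGRecord(str(tag), float(l), float(pv), float(q), status))
    return records


def run_de(
    counts: pd.DataFrame,
    groups: Sequence[str],
    cfg: PipelineConfig | None = None,
    reference: str | None = None,
) -> list[DEGRecord]:
    """Full chain: threshold test -> BH -> classification."""
    cfg = cfg or PipelineConfig()
    table = treat_test(counts, groups, cfg, reference=reference)
    table = table.assign(fdr=bh_fdr(table["p_value"].to_numpy()))
    return classify_degs(table, cfg)


def degs_to_frame(degs: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_tag": [d.locus_tag for d in degs],
            "log2fc": [d.log2fc for d in degs],
            "p": [d.p_value for d in degs],
            "fdr": [d.fdr for d in degs],
            "status": [d.status for d in degs],
        }
    ).set_index("locus_tag")


# ---------------------------------------------------------------------------
# Summary arithmetic
# ---------------------------------------------------------------------------

def deg_summary(
    degs_t1: Sequence[DEGRecord],
    degs_t2: Sequence[DEGRecord],
    genome_size: int,
    labels: tuple[str, str] = ("t1", "t2"),
) -> dict:
    """Per-time-point DEG counts/percentages plus the shared-gene overlap.

    Percentages are rounded half-up to integers (the convention the printed
    numbers follow); they are None when the denominator is zero.
    """
    out: dict = {"genome_size": genome_size, "timepoints": {}}
    sets = []
    for label, degs in zip(labels, (degs_t1, degs_t2)):
        sig = [d for d in degs if d.status != "ns"]
        n_deg = len(sig)
        n_down = sum(1 for d in sig if d.status == "down")
        n_up = n_deg - n_down
        out["timepoints"][label] = {
            "n_deg": n_deg,
            "n_down": n_down,
            "n_up": n_up,
            "pct_down": round_half_up(100 * n_down / n_deg) if n_deg else None,
            "pct_up": round_half_up(100 * n_up / n_deg) if n_deg else None,
            "pct_of_genome": round_half_up(100 * n_deg / genome_size) if n_deg else None,
        }
        sets.append({d.locus_tag for d in sig})
    shared = sets[0] & sets[1]
    out["n_shared"] = len(shared)
    for label, s in zip(labels, sets):
        out["timepoints"][label]["pct_shared"] = (
            round_half_up(100 * len(shared) / len(s)) if s else None
        )
    return out


def write_de_table(degs: Sequence[DEGRecord], path) -> None:
    degs_to_frame(degs).to_csv(path, sep="\t")


def read_de_table(path) -> list[DEGRecord]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [
        DEGRecord(str(tag), float(r["log2fc"]), float(r["p"]), float(r["fdr"]), str(r["status"]))
        for tag, r in df.iterrows()
    ]
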