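"""Assembly of significant CpG sites into ranked differentially
methylated regions (DMRs).

Site-level p-values are thresholded, consecutive significant sites are
grouped (tolerating interruptions while the running significant fraction
stays high), nearby groups are merged, and regions failing minimum-length
or minimum-CpG criteria are dropped.  Regions are ranked by the magnitude
of their area statistic — the sum of Wald statistics over the region's
significant sites — which rewards both effect size and region support.

Default thresholds mirror common WGBS practice: p < 1e-5, no minimum
effect size, >= 50 bp, >= 3 significant CpGs, merge gap 100 bp,
significant fraction >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DmrRegion", "call_dmr", "rank_regions"]


@dataclass
class DmrRegion:
    """One called region; coordinates are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    n_sig: int
    mean_mu1: float
    mean_mu2: float
    mean_diff: float
    area_stat: float

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    ok = np.isfinite(values)
    w = np.where(ok, weights, 0.0).astype(float)
    if w.sum() <= 0:
        w = ok.astype(float)
    if w.sum() == 0:
        return float("nan")
    return float(np.sum(np.where(ok, values, 0.0) * w) / w.sum())


def assemble_regions(
    chrom: np.ndarray,
    pos: np.ndarray,
    flagged: np.ndarray,
    score: np.ndarray,
    mu1: np.ndarray,
    mu2: np.ndarray,
    depth: np.ndarray,
    min_len: int = 50,
    min_cpg: int = 3,
    merge_gap: int = 100,
    sig_fraction: float = 0.5,
) -> list[DmrRegion]:
    """Group flagged sites into regions; generic over the flagging rule.

    This is the region machinery shared by the Wald-test caller and the
    baseline methods (which bring their own site scores): (1) group
    consecutive flagged sites, allowing unflagged interruptions while the
    running flagged fraction stays >= ``sig_fraction``; (2) merge groups
    separated by <= ``merge_gap`` bp; (3) drop regions shorter than
    ``min_len`` bp or with fewer than ``min_cpg`` flagged sites; the area
    statistic sums ``score`` over flagged sites.
    """
    regions: list[DmrRegion] = []
    order_guard = np.lexsort((pos, chrom))
    if not np.array_equal(order_guard, np.arange(len(pos))):
        raise ValidationError("input sites must be sorted by (chrom, pos)")

    n = len(pos)
    start_idx = 0
    while start_idx < n:
        # per-chromosome block
        end_idx = start_idx
        while end_idx < n and chrom[end_idx] == chrom[start_idx]:
            end_idx += 1
        block = slice(start_idx, end_idx)
        regions.extend(
            _assemble_block(
                chrom[start_idx],
                pos[block],
                flagged[block],
                score[block],
                mu1[block],
                mu2[block],
                depth[block],
                min_len,
                min_cpg,
                merge_gap,
                sig_fraction,
            )
        )
        start_idx = end_idx
    return regions


def _assemble_block(
    chrom_name,
    pos,
    flagged,
    score,
    mu1,
    mu2,
    depth,
    min_len,
    min_cpg,
    merge_gap,
    sig_fraction,
):
    sig_idx = np.flatnonzero(flagged)
    if len(sig_idx) == 0:
        return []
    # (1) group with interruption tolerance; a site-free bp jump beyond
    # merge_gap breaks the group (an empty gap is not an "interruption",
    # there is simply no CpG evidence across it)
    groups: list[tuple[int, int]] = []  # site-index spans, ends on flagged sites
    g_start = g_end = sig_idx[0]
    n_sig = 1
    for k in sig_idx[1:]:
        empty_jump = k == g_end + 1 and pos[k] - pos[g_end] > merge_gap
        if not empty_jump and (n_sig + 1) / (k - g_start + 1) >= sig_fraction:
            g_end = k
            n_sig += 1
        else:
            groups.append((g_start, g_end))
            g_start = g_end = k
            n_sig = 1
    groups.append((g_start, g_end))
    # (2) merge adjacent groups by bp gap
    merged: list[tuple[int, int]] = []
    for s, e in groups:
        if merged and pos[s] - pos[merged[-1][1]] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    # (3) build + filter
    out = []
    for s, e in merged:
        span = slice(s, e + 1)
        f = flagged[span]
        nsig = int(f.sum())
        length = int(pos[e] - pos[s] + 1)
        frac = nsig / (e - s + 1)
        if length < min_len or nsig < min_cpg or frac < sig_fraction:
            continue
        area = float(np.nansum(np.where(f, score[span], 0.0)))
        out.append(
            DmrRegion(
                chrom=str(chrom_name),
                start=int(pos[s]),
                end=int(pos[e]),
                n_cpg=int(e - s + 1),
                n_sig=nsig,
                mean_mu1=_weighted_mean(mu1[span], depth[span]),
                mean_mu2=_weighted_mean(mu2[span], depth[span]),
                mean_diff=_weighted_mean(mu1[span] - mu2[span], depth[span]),
                area_stat=area,
            )
        )
    return out


def call_dmr(
    dml: pd.DataFrame,
    p_threshold: float = 1e-5,
    delta: float = 0.0,
    min_len: int = 50,
    min_cpg: int = 3,
    merge_gap: int = 100,
    sig_fraction: float = 0.5,
) -> list[DmrRegion]:
    """Call DMRs from a Wald-test site table (output of ``wald_test``).

    A site is flagged when its p-value is below ``p_threshold`` and the
    smoothed-mean difference magnitude exceeds ``delta``.  Returns regions
    ranked by descending |area statistic| (see :func:`rank_regions`).
    """
    chrom = dml["chrom"].to_numpy()
    pos = dml["pos"].to_numpy()
    pval = dml["pval"].to_numpy(dtype=float)
    diff = dml["diff"].to_numpy(dtype=float)
    stat = dml["stat"].to_numpy(dtype=float)
    if {"n1", "n2"}.issubset(dml.columns):
        depth = dml["n1"].to_numpy(dtype=float) + dml["n2"].to_numpy(dtype=float)
    else:
        depth = np.ones(len(dml))
    with np.errstate(invalid="ignore"):
        flagged = (pval < p_threshold) & (np.abs(diff) > delta) & np.isfinite(stat)
    regions = assemble_regions(
        chrom,
        pos,
        flagged,
        stat,
        dml["mu1"].to_numpy(dtype=float),
        dml["mu2"].to_numpy(dtype=float),
        depth,
        min_len=min_len,
        min_cpg=min_cpg,
        merge_gap=merge_gap,
        sig_fraction=sig_fraction,
    )
    return rank_regions(regions)


def rank_regions(regions: list[DmrRegion]) -> list[DmrRegion]:
    """Stable descending sort by |area statistic|.

    Ties break by region length (longer first) then genomic position.
    """
    return sorted(
        regions,
        key=lambda r: (-abs(r.area_stat), -r.length_bp, r.chrom, r.start),
    )
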