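"""Count-table, DML-table and DMR-interval input/output.

The on-disk count format is the four-column whitespace/tab-delimited table
used throughout bisulfite-sequencing pipelines::

    chr  pos  N  X

with ``pos`` a 1-based genomic coordinate, ``N`` the total read count and
``X`` the methylated read count at one CpG site.  An optional header line
is auto-detected.  Internally everything is 1-based inclusive; BED export
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCounts",
    "CountPair",
    "read_count_table",
    "join_groups",
    "write_count_table",
    "write_dml_table",
    "read_dml_table",
    "write_dmr_bed",
]

COUNT_COLUMNS = ("chrom", "pos", "n_total", "n_meth")
DML_COLUMNS = ("chrom", "pos", "mu1", "mu2", "diff", "se", "stat", "pval")


@dataclass
class SiteCounts:
    """Per-CpG counts for one sample: (chrom, pos, N, X) per site.

    Sites are sorted by (chrom, pos), positions strictly increasing within
    a chromosome.  Sites with N = 0 are retained (they carry no data but
    keep the site index aligned); they are excluded from per-site testing.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing count columns: {missing}")
        df = df.loc[:, list(COUNT_COLUMNS)].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["n_total"] = df["n_total"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        if (df["n_total"] < 0).any() or (df["n_meth"] < 0).any():
            raise ValidationError("negative read counts")
        bad = df["n_meth"] > df["n_total"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = df.iloc[i]
            raise ValidationError(
                f"methylated count exceeds total at {row.chrom}:{row.pos} "
                f"(X={row.n_meth} > N={row.n_total})"
            )
        if not pd.MultiIndex.from_frame(df[["chrom", "pos"]]).is_monotonic_increasing:
            logger.info("count table not sorted by (chrom, pos); sorting")
            df = df.sort_values(["chrom", "pos"], kind="mergesort")
        if df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise ValidationError(f"duplicate site {dup.chrom}:{dup.pos}")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @classmethod
    def from_arrays(cls, chrom, pos, n_total, n_meth) -> "SiteCounts":
        n = len(pos)
        chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n,))
        return cls(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.asarray(pos),
                    "n_total": np.asarray(n_total),
                    "n_meth": np.asarray(n_meth),
                }
            )
        )

    # -- array views ------------------------------------------------------
    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def n_total(self) -> np.ndarray:
        return self.df["n_total"].to_numpy()

    @property
    def n_meth(self) -> np.ndarray:
        return self.df["n_meth"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def chrom_slices(self):
        """Yield (chrom_name, slice) pairs of contiguous per-chromosome blocks."""
        chrom = self.chrom
        n = len(chrom)
        start = 0
        for i in range(1, n + 1):
            if i == n or chrom[i] != chrom[start]:
                yield chrom[start], slice(start, i)
                start = i


@dataclass
class CountPair:
    """Two samples on one shared, sorted (chrom, pos) site index."""

    group1: SiteCounts
    group2: SiteCounts

    def __post_init__(self) -> None:
        a, b = self.group1, self.group2
        if len(a) != len(b) or not (
            np.array_equal(a.pos, b.pos) and np.array_equal(a.chrom, b.chrom)
        ):
            raise ValidationError("groups are not on an identical site index")

    def __len__(self) -> int:
        return len(self.group1)


def read_count_table(path, chrom_filter: str | None = None) -> SiteCounts:
    """Read a 4-column count table; see module docstring for the format.

    A first line whose columns 2-4 fail integer parsing is treated as a
    header.  Malformed rows raise :class:`ParseError` naming the line;
    unsorted input is sorted with a logged notice.
    """
    chroms, poss, ns, xs = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                p, n, x = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError:
                if lineno == 1:  # header auto-detection
                    continue
                raise ParseError(
                    f"{path}:{lineno}: non-integer pos/N/X fields {parts[1:4]!r}"
                ) from None
            chroms.append(parts[0])
            poss.append(p)
            ns.append(n)
            xs.append(x)
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms, dtype=object),
            "pos": poss,
            "n_total": ns,
            "n_meth": xs,
        }
    )
    if chrom_filter is not None:
        df = df[df["chrom"] == chrom_filter]
    return SiteCounts(df)


def write_count_table(counts: SiteCounts, path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("chr\tpos\tN\tX\n")
        counts.df.to_csv(fh, sep="\t", header=False, index=False)


def join_groups(a: SiteCounts, b: SiteCounts, policy: str = "union") -> CountPair:
    """Place two samples on a common site index.

    ``union`` (default) keeps every site seen in either sample, filling the
    missing sample with N = 0 (a site uncovered in one group can still get
    a smoothed mean there, though it is excluded from the per-site test).
    ``intersection`` keeps only shared sites.
    """
    if policy not in ("union", "intersection"):
        raise ValueError(f"unknown join policy {policy!r}")
    how = "outer" if policy == "union" else "inner"
    merged = a.df.merge(
        b.df, on=["chrom", "pos"], how=how, suffixes=("_1", "_2"), sort=False
    )
    if policy == "intersection" and merged.empty:
        raise EmptyOverlapError("no shared (chrom, pos) sites between groups")
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    for col in ("n_total_1", "n_meth_1", "n_total_2", "n_meth_2"):
        merged[col] = merged[col].fillna(0).astype(np.int64)
    g1 = SiteCounts.from_arrays(
        merged["chrom"].to_numpy(), merged["pos"], merged["n_total_1"], merged["n_meth_1"]
    )
    g2 = SiteCounts.from_arrays(
        merged["chrom"].to_numpy(), merged["pos"], merged["n_total_2"], merged["n_meth_2"]
    )
    return CountPair(g1, g2)


def write_dml_table(dml: pd.DataFrame, path) -> None:
    """Write the per-site test table (one row per CpG, TSV, NaN as 'NA')."""
    dml.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_dml_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in DML_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing DML columns {missing}")
    return df


def write_dmr_bed(regions, path, tsv_path=None) -> None:
    """Write regions as BED6 (0-based half-open) plus an optional full TSV.

    ``regions`` must be sorted and disjoint within each chromosome; the BED
    score column carries the area statistic and the name column a region id.
    """
    regions = list(regions)
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        for prev, nxt in zip(rs, rs[1:]):
            if nxt.start <= prev.end:
                raise ValidationError(
                    f"overlapping regions on {chrom}: "
                    f"[{prev.start},{prev.end}] and [{nxt.start},{nxt.end}]"
                )
    ordered = [r for chrom in sorted(by_chrom) for r in by_chrom[chrom]]
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, r in enumerate(ordered, start=1):
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\tdmr_{i}\t{r.area_stat:.6g}\t.\n"
            )
    if tsv_path is not None:
        rows = [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "length_bp": r.length_bp,
                "n_cpg": r.n_cpg,
                "n_sig": r.n_sig,
                "mean_mu1": r.mean_mu1,
                "mean_mu2": r.mean_mu2,
                "mean_diff": r.mean_diff,
                "area_stat": r.area_stat,
            }
            for r in ordered
        ]
        pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "start",
                "end",
                "length_bp",
                "n_cpg",
                "n_sig",
                "mean_mu1",
                "mean_mu2",
                "mean_diff",
                "area_stat",
            ],
        ).to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
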