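"""End-to-end convenience wrappers: counts -> site tests -> regions."""

from __future__ import annotations

import pandas as pd

from .dispersion import estimate_dispersion_field
from .dml import wald_test
from .dmr import DmrRegion, call_dmr
from .io import SiteCounts, join_groups
from .smoothing import smooth_moving_average

__all__ = ["call_dml", "pipeline"]


def call_dml(
    group1: SiteCounts,
    group2: SiteCounts,
    half_width: int = 500,
    min_sites: int = 1,
    dispersion_mode: str = "single",
    join_policy: str = "union",
) -> pd.DataFrame:
    """Smooth both samples, estimate dispersions and Wald-test every site.

    Returns the per-site table (one row per joined site; untestable sites
    carry NaN statistics).
    """
    pair = join_groups(group1, group2, policy=join_policy)
    m1 = smooth_moving_average(pair.group1, half_width, min_sites)
    m2 = smooth_moving_average(pair.group2, half_width, min_sites)
    f1 = estimate_dispersion_field(pair.group1, m1, mode=dispersion_mode)
    f2 = estimate_dispersion_field(pair.group2, m2, mode=dispersion_mode)
    return wald_test(pair, m1, m2, f1, f2)


def pipeline(
    group1: SiteCounts,
    group2: SiteCounts,
    half_width: int = 500,
    min_sites: int = 1,
    dispersion_mode: str = "single",
    **dmr_kwargs,
) -> tuple[pd.DataFrame, list[DmrRegion]]:
    """Full run: site tests plus ranked DMRs."""
    dml = call_dml(
        group1,
        group2,
        half_width=half_width,
        min_sites=min_sites,
        dispersion_mode=dispersion_mode,
    )
    return dml, call_dmr(dml, **dmr_kwargs)
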