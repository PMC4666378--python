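"""Frozen simulation profiles for the benchmark experiments.

Three named designs exercise the method end to end on synthetic data:

* ``table1`` — mean-recovery: how well does the moving-average smoother
  recover a true mean curve generated at a given smoothing span, as a
  function of the span used in estimation (including none at all)?
* ``table2_fig1`` — dispersion-recovery: Pearson correlation and MSE of
  the EB dispersion estimates against truth, for one and three replicates
  per condition and several read depths, plus the constant-dispersion
  reference (the median of the true dispersions, ~exp(-2.5) = 0.08).
* ``fig3`` — DML/DMR calling: site-level and region-level true discovery
  rates of the Wald-test pipeline against the Fisher-exact and
  mean-difference baselines on a spike-in design.

Default problem sizes are desk-scale: 20,000 sites per simulation and, for
``fig3``, 20 spiked regions (the same site:region ratio as a 100,000-site
/ 100-region design).  Each profile function returns one tidy DataFrame
row per (seed, condition); ``summarize`` reduces over seeds by the median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dispersion import estimate_dispersion_field, estimate_dispersion_multi
from .dml import wald_test
from .dmr import call_dmr
from .evaluate import (
    MIN_TRUE_EFFECT,
    fisher_baseline,
    meandiff_baseline,
    recovery_metrics,
    region_tdr,
    regions_from_scores,
    site_tdr,
    true_dml_mask,
)
from .io import CountPair
from .simulate import simulate_counts, spike_in_dmrs, synth_template
from .smoothing import smooth_moving_average

__all__ = ["Profile", "PROFILES", "run_profile", "summarize"]


@dataclass(frozen=True)
class Profile:
    """Immutable named simulation design."""

    name: str
    n_sites: int = 20_000
    depth: float = 10.0
    phi_m0: float = -2.5
    phi_r0sq: float = 1.0
    truth_spans: tuple[int, ...] = (500,)
    est_spans: tuple[int, ...] = (500, 1000, 2000)
    depths: tuple[float, ...] = (10.0,)
    rep_arms: tuple[int, ...] = (1,)
    n_dmr: int = 0
    n_seeds: int = 10
    top_k: int = 1000
    top_bp: int = 20_000
    p_threshold: float = 1e-5


PROFILES: dict[str, Profile] = {
    "table1": Profile(
        name="table1",
        truth_spans=(500, 2000),
        est_spans=(500, 1000, 2000),
    ),
    "table2_fig1": Profile(
        name="table2_fig1",
        depths=(10.0, 20.0, 30.0),
        rep_arms=(1, 3),
    ),
    "fig3": Profile(
        name="fig3",
        n_dmr=20,
        top_k=1000,
        top_bp=20_000,
    ),
}


# ---------------------------------------------------------------------------
# per-seed experiment runners
# ---------------------------------------------------------------------------

def run_table1_seed(
    seed: int,
    n_sites: int = 20_000,
    depth: float = 10.0,
    truth_span: int = 500,
    est_spans: tuple[int, ...] = (500, 1000, 2000),
    phi_m0: float = -2.5,
    phi_r0sq: float = 1.0,
) -> dict[str, float]:
    """One mean-recovery simulation; returns Pearson r per estimator."""
    template = synth_template(n_sites, seed, span=truth_span)
    truth = spike_in_dmrs(template, n_dmr=0, seed=seed)
    sim = simulate_counts(
        truth, depth=depth, phi_m0=phi_m0, phi_r0sq=phi_r0sq, seed=seed, n_reps=1
    )
    counts = sim.counts1[0]
    mu_true = truth.mu_true_1
    out: dict[str, float] = {"seed": seed, "truth_span": truth_span}
    covered = counts.n_total > 0
    raw = np.where(covered, counts.n_meth / np.maximum(counts.n_total, 1), np.nan)
    out["r_none"], _ = recovery_metrics(raw, np.where(covered, mu_true, np.nan))
    for span in est_spans:
        means = smooth_moving_average(counts, half_width=span)
        est = np.where(means.usable, means.mu_hat, np.nan)
        out[f"r_ma{span}"], _ = recovery_metrics(
            est, np.where(means.usable, mu_true, np.nan)
        )
    return out


def run_table2_seed(
    seed: int,
    n_sites: int = 20_000,
    depth: float = 10.0,
    rep_arms: tuple[int, ...] = (1, 3),
    span: int = 500,
    phi_m0: float = -2.5,
    phi_r0sq: float = 1.0,
) -> dict[str, float]:
    """One dispersion-recovery simulation at one depth.

    Simulates max(rep_arms) replicates per condition; smaller arms reuse
    the leading replicates (same marginal law, half the runtime).  Returns
    Pearson r and MSE per arm plus the constant-dispersion MSE, pooling
    both conditions' sites.
    """
    template = synth_template(n_sites, seed, span=span)
    truth = spike_in_dmrs(template, n_dmr=0, seed=seed)
    n_max = max(rep_arms)
    sim = simulate_counts(
        truth, depth=depth, phi_m0=phi_m0, phi_r0sq=phi_r0sq, seed=seed, n_reps=n_max
    )
    phi_true = np.concatenate([sim.phi1, sim.phi2])
    out: dict[str, float] = {"seed": seed, "depth": depth}
    for n_rep in rep_arms:
        est_parts = []
        for reps in (sim.counts1, sim.counts2):
            use = reps[:n_rep]
            if n_rep == 1:
                means = smooth_moving_average(use[0], half_width=span)
                fld = estimate_dispersion_field(use[0], means, mode="single")
            else:
                pooled = _pool_replicates(use)
                means = smooth_moving_average(pooled, half_width=span)
                fld = estimate_dispersion_multi(use, means)
            est_parts.append(fld.phi_hat)
        est = np.concatenate(est_parts)
        r, mse = recovery_metrics(est, phi_true)
        out[f"r_{n_rep}rep"] = r
        out[f"mse_{n_rep}rep"] = mse
    const = float(np.median(phi_true))
    out["const_phi"] = const
    out["mse_const"] = float(np.mean((const - phi_true) ** 2))
    return out


def _pool_replicates(reps):
    from .io import SiteCounts

    base = reps[0]
    n_tot = sum(r.n_total for r in reps)
    x_tot = sum(r.n_meth for r in reps)
    return SiteCounts.from_arrays(base.chrom, base.pos, n_tot, x_tot)


def run_fig3_seed(
    seed: int,
    n_sites: int = 20_000,
    n_dmr: int = 20,
    depth: float = 10.0,
    span: int = 500,
    top_k: int = 1000,
    top_bp: int = 20_000,
    p_threshold: float = 1e-5,
    phi_m0: float = -2.5,
    phi_r0sq: float = 1.0,
) -> dict[str, float]:
    """One spike-in DML/DMR benchmark: TDRs of the method and baselines."""
    template = synth_template(n_sites, seed, span=span)
    truth = spike_in_dmrs(template, n_dmr=n_dmr, seed=seed)
    sim = simulate_counts(
        truth, depth=depth, phi_m0=phi_m0, phi_r0sq=phi_r0sq, seed=seed, n_reps=1
    )
    pair = sim.pair()
    m1 = smooth_moving_average(pair.group1, half_width=span)
    m2 = smooth_moving_average(pair.group2, half_width=span)
    f1 = estimate_dispersion_field(pair.group1, m1)
    f2 = estimate_dispersion_field(pair.group2, m2)
    dml = wald_test(pair, m1, m2, f1, f2)
    truth_mask = true_dml_mask(truth)

    out: dict[str, float] = {
        "seed": seed,
        "true_site_fraction": float(truth_mask.mean()),
    }

    # --- site-level rankings -------------------------------------------
    stat = dml["stat"].to_numpy(dtype=float)
    wald_rank = _rank_desc(np.abs(stat))
    fisher_p = fisher_baseline(pair)
    fisher_rank = _rank_asc(fisher_p)
    md_score = meandiff_baseline(m1, m2)
    md_rank = _rank_desc(md_score)
    for label, rank in (
        ("wald", wald_rank),
        ("fisher", fisher_rank),
        ("meandiff", md_rank),
    ):
        curve = site_tdr(rank, truth_mask, k_grid=[top_k])
        out[f"site_tdr_{label}"] = float(curve.tdr[0])

    # --- region-level rankings ----------------------------------------
    # each method calls regions at its natural operating point (the
    # shared p threshold for the Wald test and Fisher; the analogous
    # |smoothed diff| > 0.1 rule for the scoreless mean-difference
    # baseline); curves are then compared at the largest total-bp prefix
    # all non-empty rankings reach, capped at ``top_bp``
    chrom = dml["chrom"].to_numpy()
    pos = dml["pos"].to_numpy()
    depth_w = pair.group1.n_total + pair.group2.n_total
    regions_wald = call_dmr(dml, p_threshold=p_threshold)
    with np.errstate(invalid="ignore"):
        rawdiff = _raw_diff(pair)
        fisher_flag = (fisher_p < p_threshold) & np.isfinite(fisher_p)
        fisher_score = np.sign(np.nan_to_num(rawdiff)) * norm.isf(
            np.clip(fisher_p, 1e-300, 1.0) / 2.0
        )
        md_flag = np.isfinite(md_score) & (md_score > 0.1)
    regions_fisher = regions_from_scores(
        chrom, pos, fisher_flag, np.nan_to_num(fisher_score), m1.mu_hat, m2.mu_hat, depth_w
    )
    regions_md = regions_from_scores(
        chrom, pos, md_flag, np.nan_to_num(md_score), m1.mu_hat, m2.mu_hat, depth_w
    )
    curves = {
        "wald": region_tdr(regions_wald, truth, min_effect=MIN_TRUE_EFFECT),
        "fisher": region_tdr(regions_fisher, truth, min_effect=MIN_TRUE_EFFECT),
        "meandiff": region_tdr(regions_md, truth, min_effect=MIN_TRUE_EFFECT),
    }
    totals = [c.axis[-1] for c in curves.values() if len(c.axis)]
    prefix = float(min([top_bp] + totals)) if totals else float(top_bp)
    out["region_prefix_bp"] = prefix
    for label, curve in curves.items():
        out[f"region_tdr_{label}"] = curve.at(prefix) if len(curve.axis) else 0.0
    out["n_regions_wald"] = len(regions_wald)
    out["n_regions_fisher"] = len(regions_fisher)
    out["n_regions_meandiff"] = len(regions_md)
    return out


def _raw_diff(pair: CountPair) -> np.ndarray:
    n1 = np.maximum(pair.group1.n_total, 1)
    n2 = np.maximum(pair.group2.n_total, 1)
    return pair.group1.n_meth / n1 - pair.group2.n_meth / n2


def _rank_desc(score: np.ndarray) -> np.ndarray:
    """Site indexes ordered by descending score, NaN last, position-stable."""
    key = np.where(np.isfinite(score), -score, np.inf)
    return np.argsort(key, kind="stable")


def _rank_asc(score: np.ndarray) -> np.ndarray:
    key = np.where(np.isfinite(score), score, np.inf)
    return np.argsort(key, kind="stable")


# ---------------------------------------------------------------------------
# profile driver
# ---------------------------------------------------------------------------

def run_profile(name: str, seeds, n_sites: int | None = None, **overrides) -> pd.DataFrame:
    """Run a named profile over the given seeds; one row per condition."""
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    prof = PROFILES[name]
    n_sites = n_sites or prof.n_sites
    rows = []
    if name == "table1":
        for seed in seeds:
            for truth_span in overrides.get("truth_spans", prof.truth_spans):
                rows.append(
                    run_table1_seed(
                        seed,
                        n_sites=n_sites,
                        depth=prof.depth,
                        truth_span=truth_span,
                        est_spans=overrides.get("est_spans", prof.est_spans),
                        phi_m0=prof.phi_m0,
                        phi_r0sq=prof.phi_r0sq,
                    )
                )
    elif name == "table2_fig1":
        for seed in seeds:
            for depth in overrides.get("depths", prof.depths):
                rows.append(
                    run_table2_seed(
                        seed,
                        n_sites=n_sites,
                        depth=depth,
                        rep_arms=overrides.get("rep_arms", prof.rep_arms),
                        phi_m0=prof.phi_m0,
                        phi_r0sq=prof.phi_r0sq,
                    )
                )
    elif name == "fig3":
        for seed in seeds:
            rows.append(
                run_fig3_seed(
                    seed,
                    n_sites=n_sites,
                    n_dmr=overrides.get("n_dmr", prof.n_dmr),
                    depth=prof.depth,
                    top_k=overrides.get("top_k", prof.top_k),
                    top_bp=overrides.get("top_bp", prof.top_bp),
                    p_threshold=prof.p_threshold,
                    phi_m0=prof.phi_m0,
                    phi_r0sq=prof.phi_r0sq,
                )
            )
    df = pd.DataFrame(rows)
    df.insert(0, "profile", name)
    return df


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Median over seeds, grouped by every non-seed design column."""
    group_cols = [
        c for c in ("profile", "truth_span", "depth") if c in df.columns
    ]
    metric_cols = [
        c
        for c in df.columns
        if c not in group_cols + ["seed"] and pd.api.types.is_numeric_dtype(df[c])
    ]
    return df.groupby(group_cols, as_index=False)[metric_cols].median()
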