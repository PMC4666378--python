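"""Synthetic two-group WGBS data with known truth.

The generator emulates the structure of whole-genome bisulfite data from
a human embryonic stem cell-like methylome:

* irregular CpG spacing — gaps drawn from a heavy-tailed log-normal,
  denser inside island segments (median ~40 bp) than in the methylated
  bulk (median ~120 bp), since CpG islands are by definition CpG-dense;
* a spatially smooth, strongly bimodal mean-methylation curve — a
  two-state process alternates hypermethylated "sea" segments (level
  ~0.93, mean run ~60 sites, ~7 kb) with hypomethylated island-like
  segments (level ~0.03, mean run ~25 sites, ~1 kb), mirroring the
  sharp bimodality of an ESC methylome (genome bulk >0.9 methylated,
  CpG-island troughs <0.05); beta-distributed site noise is added and
  the profile is moving-average smoothed to produce the true mean curve;
* differential regions "spiked in" by swapping stretches of the raw
  profile between random source and target regions before re-smoothing,
  so the second group's curve stays smooth and DMR edges taper naturally;
* beta-binomial counts at Poisson read depths, with per-site dispersions
  drawn from log-normal(-2.5, 1) — so the median true dispersion is
  exp(-2.5) ~ 0.08.

All randomness flows from one integer seed through numpy's seed-sequence
mechanism; distinct stages use distinct stream tags so outputs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .betabinom import PHI_MAX, PHI_MIN, bb_sample
from .errors import SimulationError
from .io import CountPair, SiteCounts
from .smoothing import window_mean

__all__ = [
    "Template",
    "SimTruth",
    "SimData",
    "synth_template",
    "spike_in_dmrs",
    "simulate_counts",
]

_MU_CLAMP = (0.01, 0.99)


@dataclass
class Template:
    """CpG positions and a smooth mean-methylation curve for one genome."""

    chrom: str
    positions: np.ndarray
    raw: np.ndarray        # unsmoothed site-level profile
    mu_curve: np.ndarray   # moving-average smooth of `raw`, clamped
    span: int              # smoothing half-width used to build mu_curve
    seed: int


@dataclass
class SimTruth:
    """Ground truth of one two-group simulation.

    ``dmr_intervals`` lists (start_bp, end_bp, (i0, i1)) target regions
    (1-based inclusive bp; i0..i1 inclusive site indexes).  Because the
    spiked groups are re-smoothed, the mean curves can differ slightly
    within one smoothing span of an interval boundary; sites are labelled
    truly differential by interval membership plus a minimum effect size
    (see ``evaluate.true_dml_mask``).
    """

    chrom: str
    positions: np.ndarray
    mu_true_1: np.ndarray
    mu_true_2: np.ndarray
    dmr_intervals: list[tuple[int, int, tuple[int, int]]]
    span: int
    seed: int
    raw1: np.ndarray = field(repr=False, default=None)
    raw2: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        iv = sorted(self.dmr_intervals)
        for (s1, e1, _), (s2, e2, _) in zip(iv, iv[1:]):
            if s2 <= e1:
                raise SimulationError("truth DMR intervals overlap")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def in_dmr(self) -> np.ndarray:
        """Boolean per-site mask of membership in any truth interval."""
        mask = np.zeros(self.n_sites, dtype=bool)
        for _, _, (i0, i1) in self.dmr_intervals:
            mask[i0 : i1 + 1] = True
        return mask

    def effective_intervals(self, min_effect: float = 0.01):
        """Maximal runs of sites where the true curves actually differ.

        The swap-then-re-smooth construction tapers effects across target
        boundaries and can null parts of a target whose source resembles
        it, so the bp truly differential (|mu1 - mu2| > ``min_effect``)
        need not coincide with the recorded target spans.  Returns
        (start_bp, end_bp, (i0, i1)) tuples like ``dmr_intervals``.
        """
        d = np.abs(self.mu_true_1 - self.mu_true_2) > min_effect
        out = []
        i = 0
        n = self.n_sites
        while i < n:
            if d[i]:
                j = i
                while j + 1 < n and d[j + 1]:
                    j += 1
                out.append(
                    (int(self.positions[i]), int(self.positions[j]), (i, j))
                )
                i = j + 1
            else:
                i += 1
        return out


@dataclass
class SimData:
    """Simulated counts plus the dispersions they were drawn with."""

    truth: SimTruth
    counts1: list[SiteCounts]
    counts2: list[SiteCounts]
    phi1: np.ndarray
    phi2: np.ndarray
    depth: float
    seed: int

    def pair(self, rep: int = 0) -> CountPair:
        """The two groups' ``rep``-th replicates as a joined pair."""
        return CountPair(self.counts1[rep], self.counts2[rep])


def synth_template(
    n_sites: int,
    seed: int,
    median_gap_hyper: float = 120.0,
    median_gap_hypo: float = 40.0,
    gap_sigma_hyper: float = 1.0,
    gap_sigma_hypo: float = 0.6,
    span: int = 500,
    level_hyper: float = 0.93,
    level_hypo: float = 0.03,
    mean_run_hyper: float = 60.0,
    mean_run_hypo: float = 25.0,
    level_conc: float = 60.0,
    chrom: str = "chr1",
) -> Template:
    """Generate CpG positions and a smooth bimodal true-mean curve.

    The methylation state (hypermethylated sea / hypomethylated island)
    alternates in geometric runs of CpG sites; gaps are log-normal with a
    state-dependent median (islands are CpG-dense, minimum gap 2 bp) and
    a heavy upper tail.  The raw profile adds beta noise around the state
    level (concentration ``level_conc``); the true curve is its
    unweighted moving average over the +/- ``span`` bp window, clamped
    to [0.01, 0.99].
    """
    if n_sites < 100:
        raise ValueError("n_sites must be >= 100")
    rng = np.random.default_rng([seed, 101])

    # alternating geometric runs of the two methylation states
    state = np.empty(n_sites, dtype=np.int8)
    cur = int(rng.random() < mean_run_hypo / (mean_run_hypo + mean_run_hyper))
    i = 0
    while i < n_sites:
        mean_run = mean_run_hypo if cur == 1 else mean_run_hyper
        run = rng.geometric(1.0 / mean_run)
        state[i : i + run] = cur
        i += run
        cur = 1 - cur

    med = np.where(state == 1, median_gap_hypo, median_gap_hyper)
    sig = np.where(state == 1, gap_sigma_hypo, gap_sigma_hyper)
    gaps = np.maximum(
        2, np.round(rng.lognormal(np.log(med), sig)).astype(np.int64)
    )
    positions = 1 + np.cumsum(gaps)

    level = np.where(state == 1, level_hypo, level_hyper)
    raw = rng.beta(level * level_conc, (1.0 - level) * level_conc)
    mu_curve = np.clip(window_mean(positions, raw, span), *_MU_CLAMP)
    return Template(
        chrom=chrom, positions=positions, raw=raw, mu_curve=mu_curve, span=span, seed=seed
    )


def _place_regions(rng, n_sites, lengths, occupied, guard):
    """Sample disjoint start indexes for regions of the given site lengths."""
    starts = []
    for L in lengths:
        for _ in range(10_000):
            s = int(rng.integers(0, n_sites - L + 1))
            lo = max(0, s - guard)
            hi = min(n_sites, s + L + guard)
            if not occupied[lo:hi].any():
                occupied[s : s + L] = True
                starts.append(s)
                break
        else:
            raise SimulationError(
                "could not place non-overlapping regions; too few sites"
            )
    return starts


def spike_in_dmrs(
    template: Template,
    n_dmr: int,
    len_range: tuple[int, int] = (5, 50),
    seed: int = 0,
    guard: int = 5,
) -> SimTruth:
    """Spike differential regions into a second group's mean curve.

    ``n_dmr`` disjoint target regions with lengths uniform in
    ``len_range`` CpGs are selected, along with an equal number of source
    regions disjoint from them.  The second group's raw profile equals the
    first's with each target stretch replaced by its source stretch; the
    raw profile is then re-smoothed so the spiked curve remains smooth.
    ``n_dmr = 0`` yields an exact null (identical curves).
    """
    n_sites = len(template.positions)
    lo, hi = len_range
    if n_dmr > 0 and n_sites < n_dmr * hi * 4:
        raise SimulationError(
            f"need >= {n_dmr * hi * 4} sites to place {n_dmr} regions of up to {hi} CpGs"
        )
    rng = np.random.default_rng([seed, 202])
    if n_dmr == 0:
        return SimTruth(
            chrom=template.chrom,
            positions=template.positions,
            mu_true_1=template.mu_curve,
            mu_true_2=template.mu_curve.copy(),
            dmr_intervals=[],
            span=template.span,
            seed=seed,
            raw1=template.raw,
            raw2=template.raw.copy(),
        )
    lengths = rng.integers(lo, hi + 1, size=n_dmr)
    occupied = np.zeros(n_sites, dtype=bool)
    targets = _place_regions(rng, n_sites, lengths, occupied, guard)
    sources = _place_regions(rng, n_sites, lengths, occupied, guard)
    raw2 = template.raw.copy()
    intervals = []
    for t, s, L in zip(targets, sources, lengths):
        raw2[t : t + L] = template.raw[s : s + L]
        intervals.append(
            (
                int(template.positions[t]),
                int(template.positions[t + L - 1]),
                (int(t), int(t + L - 1)),
            )
        )
    intervals.sort()
    mu2 = np.clip(window_mean(template.positions, raw2, template.span), *_MU_CLAMP)
    return SimTruth(
        chrom=template.chrom,
        positions=template.positions,
        mu_true_1=template.mu_curve,
        mu_true_2=mu2,
        dmr_intervals=intervals,
        span=template.span,
        seed=seed,
        raw1=template.raw,
        raw2=raw2,
    )


def simulate_counts(
    truth: SimTruth,
    depth: float = 10.0,
    phi_m0: float = -2.5,
    phi_r0sq: float = 1.0,
    seed: int = 0,
    n_reps: int = 1,
) -> SimData:
    """Draw beta-binomial counts for both groups at the true means.

    Per group, per-site dispersions are drawn once from
    log-normal(``phi_m0``, ``phi_r0sq``) (clamped to [1e-4, 0.99]) and
    shared by that group's replicates; each replicate then draws read
    depths N ~ Poisson(``depth``) and counts X ~ BetaBinomial(N, mu, phi).
    Uncovered sites (N = 0) are retained with X = 0.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng([seed, 303])
    n = truth.n_sites
    out_counts = []
    phis = []
    for mu in (truth.mu_true_1, truth.mu_true_2):
        phi = np.clip(rng.lognormal(phi_m0, np.sqrt(phi_r0sq), size=n), PHI_MIN, PHI_MAX)
        phis.append(phi)
        reps = []
        for _ in range(n_reps):
            N = rng.poisson(depth, size=n)
            X = bb_sample(N, mu, phi, rng)
            reps.append(
                SiteCounts.from_arrays(truth.chrom, truth.positions, N, X)
            )
        out_counts.append(reps)
    return SimData(
        truth=truth,
        counts1=out_counts[0],
        counts2=out_counts[1],
        phi1=phis[0],
        phi2=phis[1],
        depth=depth,
        seed=seed,
    )
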