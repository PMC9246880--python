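"""Monte-Carlo capture engine for a population moving through a trap layout.

Model
-----
A single trap lures and captures a responsive insect at distance d with
probability

    p(d) = exp(-d / (1/λ))

where 1/λ (m) is the trap's attraction length — the distance at which the
single-trap capture probability has fallen to e⁻¹.  Traps act independently,
so an insect at position x survives one day with probability

    p_escape(x) = Π_j (1 − p(d_j(x)))

over all traps j.  Each insect's cumulative escape probability through day t
is the product of its daily escape probabilities over days 1..t (capture is
evaluated once per day at the end-of-day position).  The population-level
p(escape) on a day is the arithmetic mean over insects of their cumulative
escape probabilities, and p(capture) = 1 − p(escape) is the survey
performance metric.  Insects are not removed on capture: the engine tracks
probabilities, so capturing one insect is indistinguishable from capturing
ten, and the expected p(capture) is insensitive to the cohort size.

One Monte-Carlo iteration draws a fresh epicenter, simulates the cohort's
random walk, and produces a per-day cumulative p(escape) series; results are
averaged over iterations with a normal-approximation 95 % confidence
half-width.

All escape products are accumulated in log space, which is exact for the
d = 0 case (log(0) → −inf → escape 0) and immune to underflow near traps.
Trap–insect pairs farther apart than 46 attraction lengths are pruned with a
k-d tree: their per-pair capture probability is below 1e-20 and cannot move
the log-escape sum at double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dispersal import DispersalParams, sample_epicenter, simulate_trajectories
from .grids import TrapLayout

#: pairs beyond this many attraction lengths contribute < 1e-20 and are skipped
_CUTOFF_LENGTHS = 46.0


@dataclass(frozen=True)
class AttractionKernel:
    """Exponential-decay attraction of a single trap, scale 1/λ in metres."""

    lam_inv_m: float

    def __post_init__(self) -> None:
        if self.lam_inv_m <= 0:
            raise ValueError("attraction length 1/λ must be > 0")


def capture_prob_at_distance(d, kernel: AttractionKernel):
    """Single-trap capture probability exp(−d/(1/λ)); 1 at the trap itself."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = np.exp(-d / kernel.lam_inv_m)
    return float(out) if out.ndim == 0 else out


def daily_escape(position, layout: TrapLayout) -> float:
    """One-day escape probability at a fixed position: Π_j (1 − p(d_j)).

    An empty layout gives 1.0; a position exactly at a trap gives 0.0.
    """
    if len(layout) == 0:
        return 1.0
    position = np.asarray(position, dtype=float)
    d = np.hypot(layout.x - position[0], layout.y - position[1])
    with np.errstate(divide="ignore"):
        log_esc = np.log1p(-np.exp(-d / layout.lam_inv)).sum()
    return float(np.exp(log_esc))


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo run settings: replication, survey duration, cohort, seed."""

    iterations: int = 1000
    duration_days: int = 30
    n_insects: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.duration_days < 1:
            raise ValueError("duration_days must be >= 1")
        if self.n_insects < 1:
            raise ValueError("n_insects must be >= 1")


@dataclass
class SimResult:
    """Per-day cumulative mean p(escape)/p(capture) with Monte-Carlo CI."""

    p_escape_by_day: np.ndarray
    ci95_by_day: np.ndarray
    n_iterations: int

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, self.p_escape_by_day.size + 1)

    @property
    def p_capture_by_day(self) -> np.ndarray:
        return 1.0 - self.p_escape_by_day

    @property
    def p_capture_final(self) -> float:
        return float(self.p_capture_by_day[-1])

    @property
    def ci95_halfwidth(self) -> float:
        """95 % half-width of the final-day mean across iterations."""
        return float(self.ci95_by_day[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "day": self.days,
            "p_escape": self.p_escape_by_day,
            "p_capture": self.p_capture_by_day,
            "ci95": self.ci95_by_day,
        })

    def write_csv(self, path, metadata: dict | None = None) -> None:
        """Result CSV with run metadata echoed as ``# key=value`` comments."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}={value}\n")
            self.to_frame().to_csv(fh, index=False)


def _iteration_log_escape(positions: np.ndarray, layout: TrapLayout,
                          tree: cKDTree, cutoff: float) -> np.ndarray:
    """Per-day, per-insect one-day log-escape values, shape (t, n)."""
    t, n, _ = positions.shape
    flat = positions.reshape(-1, 2)
    neighbours = tree.query_ball_point(flat, cutoff)
    counts = np.fromiter((len(nb) for nb in neighbours), dtype=np.intp,
                         count=len(neighbours))
    total = int(counts.sum())
    if total == 0:
        return np.zeros((t, n))
    trap_idx = np.concatenate([np.asarray(nb, dtype=np.intp)
                               for nb in neighbours if nb])
    pos_idx = np.repeat(np.arange(flat.shape[0]), counts)
    d = np.hypot(flat[pos_idx, 0] - layout.x[trap_idx],
                 flat[pos_idx, 1] - layout.y[trap_idx])
    with np.errstate(divide="ignore"):
        contrib = np.log1p(-np.exp(-d / layout.lam_inv[trap_idx]))
    log_esc = np.bincount(pos_idx, weights=contrib, minlength=flat.shape[0])
    return log_esc.reshape(t, n)


def run_simulation(layout: TrapLayout, disp: DispersalParams,
                   cfg: SimConfig) -> SimResult:
    """Monte-Carlo estimate of the per-day cumulative p(escape)/p(capture).

    Per iteration: draw an epicenter uniformly in the core region, walk the
    cohort for the survey duration, form each insect's cumulative escape
    probability, and average over insects.  The returned series is the mean
    over iterations with a 1.96·s/√iterations half-width.  Fully
    deterministic given ``cfg.seed``.
    """
    t, n = cfg.duration_days, cfg.n_insects
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.iterations)
    have_traps = len(layout) > 0
    if have_traps:
        tree = cKDTree(layout.coords)
        cutoff = _CUTOFF_LENGTHS * float(layout.lam_inv.max())
    escape = np.empty((cfg.iterations, t))
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        epicenter = sample_epicenter(rng, disp.epicenter_side_m)
        traj = simulate_trajectories(disp, epicenter, n, t, rng)
        if not have_traps:
            escape[i] = 1.0
            continue
        daily_log = _iteration_log_escape(traj.positions, layout, tree, cutoff)
        cum_log = np.cumsum(daily_log, axis=0)       # per-insect cumulative escape
        escape[i] = np.exp(cum_log).mean(axis=1)     # population mean, per day
    mean = escape.mean(axis=0)
    if cfg.iterations > 1:
        sd = escape.std(axis=0, ddof=1)
        ci = 1.96 * sd / math.sqrt(cfg.iterations)
    else:
        ci = np.full(t, np.nan)
    return SimResult(p_escape_by_day=mean, ci95_by_day=ci,
                     n_iterations=cfg.iterations)
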