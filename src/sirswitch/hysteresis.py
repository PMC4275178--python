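"""In-silico hysteresis protocol and bifurcation-type classification.

Two ensembles of lattices are pre-grown to their history's steady state at
HIGH (I=4) and LOW (I=0) inhibitor levels, then each member is exposed to an
intermediate inhibitor level and its intermediate-time locus occupancy
recorded.  The occupancy gap between the two history-conditioned branches
versus I is the hysteresis diagnostic: a gap that closes gradually marks a
continuous (supercritical-pitchfork-like) merge of the branches, while a
one-step collapse from a still-separated pair marks a discontinuous
(saddle-node-like) jump.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .sim import (LatticeState, SimConfig, simulate, sir_occupancy)

__all__ = [
    "HysteresisScan", "BifurcationReport",
    "pregrow_ensembles", "hysteresis_scan", "classify_bifurcation",
    "DEFAULT_I_GRID", "DEFAULT_T_PREGROW",
]

#: Default inhibitor grid for scans: spans the pre-growth extremes.
DEFAULT_I_GRID = tuple(np.round(np.arange(0.0, 4.01, 0.5), 3))

#: Default pre-growth horizon (mark-loss time units).  Long enough for the
#: shipped rate set to reach its history-conditioned steady state at I=0 and
#: I=4; short enough that a full two-history ensemble stays desk-scale.
DEFAULT_T_PREGROW = 150.0


@dataclass
class HysteresisScan:
    """Per-I, per-history ensembles of locus occupancies.

    ``occ_low[i, r]`` / ``occ_high[i, r]`` hold the post-burn-in occupancy
    of replicate r exposed to ``I_grid[i]``, for the LOW-pregrown and
    HIGH-pregrown histories respectively.
    """

    I_grid: np.ndarray
    occ_low: np.ndarray
    occ_high: np.ndarray
    seeds: dict

    def __post_init__(self) -> None:
        self.I_grid = np.asarray(self.I_grid, float)
        self.occ_low = np.atleast_2d(np.asarray(self.occ_low, float))
        self.occ_high = np.atleast_2d(np.asarray(self.occ_high, float))
        if self.occ_low.shape != self.occ_high.shape:
            raise ValueError("histories must share ensemble shape")
        if self.occ_low.shape[0] != self.I_grid.size:
            raise ValueError("ensemble rows must match I_grid")
        if np.any(np.diff(self.I_grid) <= 0):
            raise ValueError("I_grid must be strictly increasing")

    @property
    def ensemble_size(self) -> int:
        return self.occ_low.shape[1]

    def swapped(self) -> "HysteresisScan":
        """Scan with the two history ensembles exchanged."""
        return HysteresisScan(self.I_grid.copy(), self.occ_high.copy(),
                              self.occ_low.copy(), dict(self.seeds))


@dataclass
class BifurcationReport:
    """Branch means, gap profile and transition classification."""

    I_grid: np.ndarray
    branch_mean_low_history: np.ndarray
    branch_mean_high_history: np.ndarray
    branch_gap: np.ndarray           # mean(LOW) - mean(HIGH) per I
    branch_gap_se: np.ndarray
    threshold_estimate: float | None
    threshold_uncertainty: float | None
    classification: str              # discontinuous_jump | continuous_merge |
                                     # monostable_everywhere |
                                     # bistable_everywhere | ambiguous
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "I_grid": self.I_grid.tolist(),
            "branch_mean_low_history": self.branch_mean_low_history.tolist(),
            "branch_mean_high_history": self.branch_mean_high_history.tolist(),
            "branch_gap": self.branch_gap.tolist(),
            "branch_gap_se": self.branch_gap_se.tolist(),
            "threshold_estimate": self.threshold_estimate,
            "threshold_uncertainty": self.threshold_uncertainty,
            "classification": self.classification,
            "flags": list(self.flags),
        }


def pregrow_ensembles(config: SimConfig, I_high: float = 4.0,
                      I_low: float = 0.0, n_rep: int = 50, *,
                      t_pregrow: float = DEFAULT_T_PREGROW, seed: int = 0,
                      init_low: str = "telomere_block",
                      init_high: str = "all_active"
                      ) -> tuple[list[LatticeState], list[LatticeState]]:
    """Grow (LOW, HIGH) ensembles of steady-state lattices.

    Each member runs independently for ``t_pregrow`` at its history's
    inhibitor level — the in-silico analogue of growing the two cultures
    for many generations with or without drug.  Pre-growth starts in the
    basin of the branch each history occupies: LOW (no drug) from an
    established telomeric S domain, HIGH from the all-active lattice; in a
    robustly bistable system spontaneous branch switching is far slower
    than any simulated horizon, so the initial basin — not the pre-growth
    noise — decides the branch.  Both init modes are overridable (equal
    modes make the two ensembles exchangeable when ``I_high == I_low``).
    Seeds are distinct per member and derived from ``seed``.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(2 * n_rep)]
    low, high = [], []
    for r in range(n_rep):
        traj = simulate(replace(config, I=I_low), init_mode=init_low,
                        seed=seeds[r], duration=t_pregrow,
                        keep_snapshots=False)
        low.append(traj.final_state)
        traj = simulate(replace(config, I=I_high), init_mode=init_high,
                        seed=seeds[n_rep + r], duration=t_pregrow,
                        keep_snapshots=False)
        high.append(traj.final_state)
    return low, high


def hysteresis_scan(config: SimConfig, I_grid: Sequence[float],
                    low_ensemble: Sequence[LatticeState],
                    high_ensemble: Sequence[LatticeState], *,
                    seed: int = 0) -> HysteresisScan:
    """Expose both pre-grown ensembles to each intermediate I.

    Each member is continued at the probe level for ``config.t_record``;
    short-time (burn-in) dynamics is discarded and the intermediate-time
    mean occupancy recorded.
    """
    I_grid = np.asarray(sorted(I_grid), float)
    if I_grid.size == 0:
        raise ValueError("I_grid must be non-empty")
    n_rep = len(low_ensemble)
    if len(high_ensemble) != n_rep:
        raise ValueError("ensembles must have equal size")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31)
             for s in ss.generate_state(2 * n_rep * I_grid.size)]
    occ_low = np.zeros((I_grid.size, n_rep))
    occ_high = np.zeros((I_grid.size, n_rep))
    k = 0
    for gi, I in enumerate(I_grid):
        cfg = replace(config, I=float(I))
        for r in range(n_rep):
            traj = simulate(cfg, initial=low_ensemble[r].copy(),
                            seed=seeds[k], keep_snapshots=False)
            occ_low[gi, r] = sir_occupancy(traj)
            k += 1
            traj = simulate(cfg, initial=high_ensemble[r].copy(),
                            seed=seeds[k], keep_snapshots=False)
            occ_high[gi, r] = sir_occupancy(traj)
            k += 1
    return HysteresisScan(I_grid, occ_low, occ_high,
                          {"scan_seed": seed, "n_rep": n_rep})


def _se(x: np.ndarray) -> float:
    n = x.size
    if n < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(n))


def classify_bifurcation(scan: HysteresisScan, gap_tol: float = 2.0,
                         jump_tol: float = 0.5) -> BifurcationReport:
    """Classify the bistable-to-monostable transition of a scan.

    The threshold estimate I* is the smallest grid point from which the
    absolute branch gap stays within ``gap_tol`` pooled standard errors of
    zero.  The transition is a ``continuous_merge`` when the gap decreases
    to below tolerance with no single-step drop exceeding ``jump_tol`` times
    the maximum gap, and a ``discontinuous_jump`` when the branches are
    still separated by more than ``jump_tol`` x max-gap immediately below
    I*.  A gap below/above tolerance everywhere gives
    ``monostable_everywhere`` / ``bistable_everywhere``; a profile the grid
    cannot disambiguate is flagged ``ambiguous`` rather than guessed.
    """
    if scan.I_grid.size < 4:
        raise ValueError("need at least 4 grid points to classify")
    if scan.ensemble_size < 2:
        raise ValueError("need ensemble size >= 2 for uncertainty estimates")
    mean_low = scan.occ_low.mean(axis=1)
    mean_high = scan.occ_high.mean(axis=1)
    gap = mean_low - mean_high
    se = np.array([math.sqrt(_se(scan.occ_low[i]) ** 2 +
                             _se(scan.occ_high[i]) ** 2)
                   for i in range(scan.I_grid.size)])
    agap = np.abs(gap)
    tol = gap_tol * se
    below = agap <= tol
    flags: list[str] = []
    spacing = float(np.min(np.diff(scan.I_grid)))

    def report(thr, unc, cls):
        return BifurcationReport(scan.I_grid, mean_low, mean_high, gap, se,
                                 thr, unc, cls, flags)

    if below.all():
        return report(float(scan.I_grid[0]), spacing, "monostable_everywhere")
    if not below.any():
        flags.append("threshold_out_of_range")
        return report(None, None, "bistable_everywhere")

    # First index from which the gap stays closed.  A later point only
    # disqualifies a candidate threshold when it *significantly* reopens
    # (beyond twice the tolerance): with many grid points past threshold,
    # demanding every one fall inside the gap_tol band would reject valid
    # thresholds by multiple comparison alone.
    reopen = agap > 2.0 * tol
    idx = None
    for i in range(scan.I_grid.size):
        if below[i] and not reopen[i:].any():
            idx = i
            break
    if idx is None:
        # bimodality reappears above a closed point: coarse/noisy grid
        flags.append("non_monotone_gap_closure")
        idx = int(np.flatnonzero(below)[-1])
        first_below = int(np.flatnonzero(below)[0])
        if idx != first_below:
            return report(float(scan.I_grid[idx]), spacing, "ambiguous")
    if idx == 0:
        return report(float(scan.I_grid[0]), spacing, "monostable_everywhere")

    threshold = float(scan.I_grid[idx])
    unc = float(scan.I_grid[idx] - scan.I_grid[idx - 1])
    max_gap = float(agap.max())
    g_pre = float(agap[idx - 1])  # separation immediately below threshold
    drops = -np.diff(agap[:idx + 1])
    max_drop = float(drops.max()) if drops.size else 0.0

    if g_pre > jump_tol * max_gap:
        return report(threshold, unc, "discontinuous_jump")
    if max_drop <= jump_tol * max_gap:
        return report(threshold, unc, "continuous_merge")
    # the gap fell gently at the end but had a large interior drop: the
    # grid cannot distinguish a jump from a fast merge
    flags.append("interior_step_drop")
    return report(threshold, unc, "ambiguous")
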