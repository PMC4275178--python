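"""Synthetic-data generators emulating both assays' statistical structure.

No raw data were deposited for the experiments this package analyses, so
every pipeline stage is exercised on generated data with stored ground
truth:

* ``generate_plate_counts`` — a bistable two-state (on/off) cell population
  with concentration-dependent per-generation switching, a 12-15 generation
  memory window and a ~1e-6 mutational 5-FOA escape floor, plated with
  Poisson colony counts at auto-adjusted serial dilutions.
* ``generate_colony_colors`` — per-plate 3-channel Gaussian colony-colour
  mixtures whose component means merge continuously at a threshold
  (pitchfork scenario) or stay separated with a vanishing 'off' weight
  (saddle scenario), under per-plate illumination scaling.
* ``generate_hysteresis_scan`` — branch-occupancy ensembles following a
  continuous-merge or discontinuous-jump gap profile, for classifier
  calibration.

All generators are deterministic given their RNG and return ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hysteresis import HysteresisScan
from .survival import HISTORIES

__all__ = [
    "PopulationModel", "ColorModel", "ScanParams",
    "switching_probabilities", "f_off_trajectory", "two_state_closed_form",
    "true_survival", "generate_plate_counts",
    "generate_colony_colors", "generate_hysteresis_scan",
]

#: The 18-concentration design of the survival experiment (µM splitomycin).
DEFAULT_C_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0,
                  12.0, 14.0, 16.0, 20.0, 30.0, 40.0, 50.0, 60.0)


@dataclass(frozen=True)
class PopulationModel:
    """Two-state population model behind the 5-FOA counts.

    Each generation a silenced ('off') cell desilences with probability
    ``p_off_on(c)`` and an expressing ('on') cell establishes silencing with
    probability ``p_on_off(c)``; both are logistic in log concentration
    around the bistable-to-monostable threshold ``c_star`` with sharpness
    ``s``.  Cells surviving 5-FOA are the 'off' fraction plus mutants at
    rate ``mu``.
    """

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    c_star: float = 25.0            # µM threshold
    g: int = 14                     # generations of intermediate exposure
    s: float = 8.0                  # logistic sharpness in log c
    p_desilence_max: float = 0.8    # off->on ceiling above threshold
    p_desilence_base: float = 0.005  # spontaneous desilencing (variegation)
    p_establish_0: float = 1e-5     # on->off establishment at c=0
    f_off_init_low: float = 0.999   # silenced fraction, LOW_pregrown
    f_off_init_high: float = 0.001  # silenced fraction, HIGH_pregrown
    mu: float = 1e-6                # mutational 5-FOA escape rate
    N_cells_plated: float = 5e7
    target_count: float = 200.0     # desired expected colonies per plate

    def __post_init__(self) -> None:
        if np.any(np.diff(self.c_grid) <= 0):
            raise ValueError("c_grid must be strictly increasing")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        for p in (self.p_desilence_max, self.p_desilence_base,
                  self.p_establish_0, self.f_off_init_low,
                  self.f_off_init_high):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    def f_off_init(self, history: str) -> float:
        if history == "LOW_pregrown":
            return self.f_off_init_low
        if history == "HIGH_pregrown":
            return self.f_off_init_high
        raise ValueError(f"unknown history {history!r}")


def switching_probabilities(model: PopulationModel, c: float
                            ) -> tuple[float, float]:
    """(p_on_off, p_off_on): per-generation switch probabilities at c µM."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    x = (c / model.c_star) ** model.s
    p_on_off = model.p_establish_0 / (1.0 + x)
    p_off_on = model.p_desilence_base + \
        model.p_desilence_max * x / (1.0 + x)
    return p_on_off, min(p_off_on, 1.0)


def f_off_trajectory(model: PopulationModel, history: str, c: float
                     ) -> np.ndarray:
    """Silenced fraction per generation (length g+1, starting at g=0)."""
    p_on_off, p_off_on = switching_probabilities(model, c)
    f = model.f_off_init(history)
    out = [f]
    for _ in range(model.g):
        f = f * (1.0 - p_off_on) + (1.0 - f) * p_on_off
        out.append(f)
    return np.asarray(out)


def two_state_closed_form(f0: float, p_on_off: float, p_off_on: float,
                          g: int) -> float:
    """Closed-form silenced fraction after g generations.

    Eigendecomposition of the 2x2 chain: f_g = f_inf + (f0 - f_inf) lam^g
    with lam = 1 - p_on_off - p_off_on and f_inf the stationary silenced
    fraction.  Serves as the independent oracle for
    :func:`f_off_trajectory`.
    """
    tot = p_on_off + p_off_on
    if tot == 0.0:
        return f0
    f_inf = p_on_off / tot
    lam = 1.0 - tot
    return f_inf + (f0 - f_inf) * lam ** g


def true_survival(model: PopulationModel, history: str, c: float) -> float:
    """Expected 5-FOA survival: silenced fraction after exposure, plus the
    mutational floor (off cells survive, on cells die unless mutant)."""
    f_off = float(f_off_trajectory(model, history, c)[-1])
    return f_off * (1.0 - model.mu) + model.mu


def generate_plate_counts(model: PopulationModel,
                          rng: np.random.Generator
                          ) -> tuple[pd.DataFrame, dict]:
    """Simulate the full 18-concentration, two-history plating experiment.

    Dilutions are auto-adjusted per plate so the expected colony count is
    ``model.target_count`` (capped at plating the whole culture), mirroring
    serial dilutions chosen for reliable counts.  Counts are Poisson.
    Returns (counts table, ground truth).
    """
    rows = []
    truth_curves: dict[str, list[float]] = {h: [] for h in HISTORIES}
    for history in HISTORIES:
        for c in model.c_grid:
            s_true = true_survival(model, history, c)
            truth_curves[history].append(s_true)
            d_ypd = min(1.0, model.target_count / model.N_cells_plated)
            exp_foa_full = model.N_cells_plated * s_true
            d_foa = min(1.0, model.target_count / exp_foa_full) \
                if exp_foa_full > 0 else 1.0
            lam_ypd = model.N_cells_plated * d_ypd
            lam_foa = exp_foa_full * d_foa
            if lam_ypd > 1e6 or lam_foa > 1e6:
                raise ValueError(
                    "expected counts exceed 1e6 per plate; use a larger "
                    "dilution")
            rows.append({
                "concentration_uM": c, "history": history,
                "N_YPD": int(rng.poisson(lam_ypd)), "d_YPD": d_ypd,
                "N_FOA": int(rng.poisson(lam_foa)), "d_FOA": d_foa,
            })
    truth = {
        "c_star": model.c_star, "mu": model.mu, "g": model.g,
        "c_grid": list(model.c_grid),
        "true_survival": {h: truth_curves[h] for h in HISTORIES},
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# colony colours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColorModel:
    """Generator of per-colony normalized RGB mixtures along a
    concentration series.

    ``pitchfork``: the 'on' and 'off' component means approach each other as
    ``separation x (1 - c/c_merge)^beta`` (beta = 1/2, the supercritical
    pitchfork exponent) and coincide from ``c_merge`` on, with fixed
    weights.  ``saddle``: the separation stays constant while the 'off'
    weight decays linearly to zero at ``c_merge``.  Every plate is scaled
    by a lognormal illumination factor that per-plate normalization must
    remove.
    """

    scenario: str = "pitchfork"     # pitchfork | saddle
    c_grid: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0)
    c_merge: float = 10.0           # µM
    m_on: tuple[float, float, float] = (0.90, 1.10, 1.08)
    m_off: tuple[float, float, float] = (1.30, 0.85, 0.85)
    beta: float = 0.5
    noise_sd: float = 0.05          # per-channel, post-normalization scale
    illumination_sd: float = 0.1    # lognormal sigma of the plate scalar
    w_off: float = 0.45             # 'off' weight (initial, for saddle)
    colonies_per_plate: int = 200

    def __post_init__(self) -> None:
        if self.scenario not in ("pitchfork", "saddle"):
            raise ValueError("scenario must be 'pitchfork' or 'saddle'")
        if not (self.m_off[0] > self.m_on[0]):
            raise ValueError("'off' must have the larger red channel at c=0")
        if not (0.0 <= self.w_off <= 1.0):
            raise ValueError("w_off must lie in [0, 1]")
        if self.c_merge <= 0:
            raise ValueError("c_merge must be > 0")

    def component_means(self, c: float) -> tuple[np.ndarray, np.ndarray]:
        """(mean_on, mean_off) at concentration c, before illumination."""
        on = np.asarray(self.m_on)
        off = np.asarray(self.m_off)
        center = 0.5 * (on + off)
        half = 0.5 * (off - on)
        if self.scenario == "pitchfork":
            scale = max(0.0, 1.0 - c / self.c_merge) ** self.beta
        else:
            scale = 1.0
        return center - half * scale, center + half * scale

    def off_weight(self, c: float) -> float:
        if self.scenario == "pitchfork":
            return self.w_off
        return self.w_off * max(0.0, 1.0 - c / self.c_merge)


def generate_colony_colors(model: ColorModel, rng: np.random.Generator
                           ) -> tuple[pd.DataFrame, dict]:
    """Draw per-colony RGB tables for every plate of the series.

    Returns (colour table with hidden truth column dropped, ground truth
    dict holding per-colony labels, component means and the scenario).
    """
    rows = []
    truth_means = {}
    for c in model.c_grid:
        mean_on, mean_off = model.component_means(c)
        w_off = model.off_weight(c)
        illum = float(rng.lognormal(0.0, model.illumination_sd))
        labels = rng.random(model.colonies_per_plate) < w_off
        noise = rng.normal(0.0, model.noise_sd,
                           (model.colonies_per_plate, 3))
        means = np.where(labels[:, None], mean_off, mean_on)
        rgb = np.clip(illum * (means + noise), 0.0, None)
        pid = f"plate_c{c:g}"
        for j in range(model.colonies_per_plate):
            rows.append({
                "plate_id": pid, "concentration_uM": c,
                "colony_id": f"{pid}_col{j:03d}",
                "R": rgb[j, 0], "G": rgb[j, 1], "B": rgb[j, 2],
                "true_label": "off" if labels[j] else "on",
            })
        truth_means[float(c)] = {
            "mean_on": mean_on.tolist(), "mean_off": mean_off.tolist(),
            "w_off": w_off, "illumination": illum,
        }
    df = pd.DataFrame(rows)
    truth = {
        "scenario": model.scenario, "c_merge": model.c_merge,
        "beta": model.beta, "per_concentration": truth_means,
        "labels": df[["colony_id", "true_label"]]
                  .set_index("colony_id")["true_label"].to_dict(),
    }
    return df.drop(columns=["true_label"]), truth


# ---------------------------------------------------------------------------
# hysteresis-scan fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    """Branch/gap profile for synthetic hysteresis scans."""

    I_grid: tuple[float, ...] = tuple(np.round(np.arange(0, 4.01, 0.25), 3))
    I_star: float = 2.0
    gap0: float = 0.6               # branch gap deep in the bistable region
    base: float = 0.15              # HIGH-history branch occupancy
    noise_sd: float = 0.05
    n_rep: int = 50

    def gap(self, I: float, truth: str) -> float:
        if truth == "merge":
            return self.gap0 * max(0.0, 1.0 - I / self.I_star)
        if truth == "jump":
            return self.gap0 if I < self.I_star else 0.0
        raise ValueError("truth must be 'merge' or 'jump'")


def generate_hysteresis_scan(truth: str, params: ScanParams,
                             rng: np.random.Generator
                             ) -> tuple[HysteresisScan, dict]:
    """Draw a synthetic scan whose gap profile follows ``truth``.

    'merge': the gap closes linearly at I_star (continuous merge); 'jump':
    the gap stays at ``gap0`` then collapses at I_star (discontinuous
    jump).  Occupancies are Gaussian around the branch means, clipped to
    [0, 1].
    """
    I = np.asarray(params.I_grid, float)
    gaps = np.array([params.gap(i, truth) for i in I])
    n = params.n_rep
    occ_high = np.clip(
        params.base + rng.normal(0, params.noise_sd, (I.size, n)), 0, 1)
    occ_low = np.clip(
        params.base + gaps[:, None]
        + rng.normal(0, params.noise_sd, (I.size, n)), 0, 1)
    scan = HysteresisScan(I, occ_low, occ_high, {"synthetic": truth})
    return scan, {"truth": truth, "I_star": params.I_star,
                  "gap_profile": gaps.tolist()}
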