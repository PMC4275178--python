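"""ADE2 colony-pigmentation analysis.

Colonies silencing the telomeric ADE2 reporter accumulate red pigment, so
per-colony mean RGB intensities report the silencing state integrated over
growth.  Per plate, intensities are normalized by the grand mean over all
channels and colonies (cancelling illumination differences), then fit with
one- and two-component full-covariance 3-D Gaussian mixtures.  A plate is
called bimodal only when the two-component fit wins on BIC *and* its
components are genuinely separated — otherwise the extra component merely
captures non-Gaussian unimodality.  Branch means are projected on the
leading principal component of the 'off'-minus-'on' mean differences, and
the merge concentration is the first unimodal plate of the final unimodal
run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureFit", "BranchTrace", "TraceConfig",
    "normalize_plate", "fit_mixture", "select_model", "classify_colonies",
    "projection_axis", "trace_branches", "em_loglik_trace",
]

_EM_TOL = 1e-8
_EM_MAX_ITER = 500
_RIDGE_SCALE = 1e-6


@dataclass
class MixtureFit:
    """A fitted k-component 3-D Gaussian mixture."""

    k: int
    means: np.ndarray        # (k, 3)
    covariances: np.ndarray  # (k, 3, 3)
    weights: np.ndarray      # (k,)
    log_likelihood: float    # total log-likelihood of the data
    bic: float
    n: int
    converged: bool
    degenerate: bool = False
    model: GaussianMixture | None = field(default=None, repr=False)


def normalize_plate(rgb: np.ndarray) -> np.ndarray:
    """Divide a plate's (n, 3) intensities by their grand mean.

    Compensates per-plate illumination: the normalized grand mean is exactly
    1 and the output is invariant under rescaling the whole plate.
    """
    rgb = np.asarray(rgb, float)
    if rgb.ndim != 2 or rgb.shape[1] != 3 or rgb.shape[0] < 1:
        raise ValueError("expected an (n, 3) array with n >= 1")
    if np.any(rgb < 0) or not np.all(np.isfinite(rgb)):
        raise ValueError("intensities must be finite and non-negative")
    gm = rgb.mean()
    if gm <= 0:
        raise ValueError("plate grand mean must be positive")
    return rgb / gm


def _ridge(X: np.ndarray) -> float:
    v = float(np.mean(np.var(X, axis=0)))
    return max(_RIDGE_SCALE * v, 1e-12)


def fit_mixture(vectors: np.ndarray, k: int, n_restarts: int = 10,
                seed: int = 0) -> MixtureFit:
    """EM fit of a k in {1, 2} component full-covariance Gaussian mixture.

    Runs ``n_restarts`` seeded initializations to convergence
    (log-likelihood change < 1e-8 or 500 iterations) and keeps the best.
    Covariances carry a small diagonal ridge against collapse; a plate of
    identical points is returned flagged degenerate.
    """
    X = np.asarray(vectors, float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) array")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    n = X.shape[0]
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} colonies for k={k}")
    degenerate = bool(np.allclose(X, X[0]))
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         tol=_EM_TOL, max_iter=_EM_MAX_ITER,
                         n_init=n_restarts, reg_covar=_ridge(X),
                         random_state=int(seed))
    gm.fit(X)
    ll = float(gm.score(X) * n)
    return MixtureFit(k=k, means=gm.means_.copy(),
                      covariances=gm.covariances_.copy(),
                      weights=gm.weights_.copy(), log_likelihood=ll,
                      bic=float(gm.bic(X)), n=n,
                      converged=bool(gm.converged_), degenerate=degenerate,
                      model=gm)


def em_loglik_trace(vectors: np.ndarray, k: int, seed: int = 0,
                    max_iter: int = 100) -> np.ndarray:
    """Per-iteration mean log-likelihood of a single warm-started EM run.

    Exposes the EM ascent so the monotonicity invariant (log-likelihood
    never decreases across iterations) can be checked.
    """
    X = np.asarray(vectors, float)
    gm = GaussianMixture(n_components=k, covariance_type="full",
                         tol=0.0, max_iter=1, n_init=1, reg_covar=_ridge(X),
                         random_state=int(seed), warm_start=True)
    trace = []
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(max_iter):
            gm.fit(X)
            trace.append(float(gm.score(X)))
    return np.asarray(trace)


def _mahalanobis_separation(fit2: MixtureFit) -> float:
    """Separation of the two component means under the pooled covariance."""
    if fit2.k != 2:
        raise ValueError("needs a two-component fit")
    w = fit2.weights
    pooled = w[0] * fit2.covariances[0] + w[1] * fit2.covariances[1]
    diff = fit2.means[0] - fit2.means[1]
    return float(math.sqrt(diff @ np.linalg.solve(pooled, diff)))


def select_model(fit1: MixtureFit, fit2: MixtureFit,
                 sep_min: float = 2.0) -> str:
    """'bimodal' or 'unimodal' from the 1- vs 2-component fits.

    Bimodal requires all of: BIC favours two components; the component
    means are at least ``sep_min`` apart in pooled-covariance Mahalanobis
    distance; neither weight is below 0.05.  The separation requirement is
    what rejects two-component fits that only soak up non-Gaussian shape of
    a single mode.
    """
    if fit1.k != 1 or fit2.k != 2:
        raise ValueError("pass the k=1 fit first and the k=2 fit second")
    if fit1.n != fit2.n:
        raise ValueError("fits must be on the same data")
    if (fit2.bic < fit1.bic
            and _mahalanobis_separation(fit2) >= sep_min
            and fit2.weights.min() >= 0.05):
        return "bimodal"
    return "unimodal"


def off_component(fit2: MixtureFit) -> tuple[int, bool]:
    """Index of the 'off' (silenced, red-pigmented) component.

    'off' is the component with the larger red-channel mean.  An exact tie
    is broken by the larger total intensity and flagged.
    """
    red = fit2.means[:, 0]
    if red[0] != red[1]:
        return int(np.argmax(red)), False
    return int(np.argmax(fit2.means.sum(axis=1))), True


def classify_colonies(fit2: MixtureFit, vectors: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-posterior 'on'/'off' labels with posteriors.

    Returns (labels, p_off, tie_flag) where labels is an array of 'on'/'off'
    strings and p_off the posterior probability of the 'off' component.
    """
    if fit2.model is None or fit2.k != 2:
        raise ValueError("needs a fitted two-component mixture")
    X = np.asarray(vectors, float)
    post = fit2.model.predict_proba(X)
    i_off, tie = off_component(fit2)
    p_off = post[:, i_off]
    labels = np.where(p_off >= 0.5, "off", "on")
    return labels, p_off, tie


def projection_axis(branch_diffs: np.ndarray
                    ) -> tuple[np.ndarray, bool]:
    """Leading principal component of 'off'-minus-'on' mean differences.

    The axis is the leading right singular vector of the (uncentred) stack
    of difference vectors, with its sign fixed so the mean projected
    difference is >= 0.  Returns (unit 3-vector, mean_zero_flag).
    """
    D = np.atleast_2d(np.asarray(branch_diffs, float))
    if D.shape[0] < 2 or D.shape[1] != 3:
        raise ValueError("need at least 2 difference 3-vectors")
    _, _, Vt = np.linalg.svd(D, full_matrices=False)
    axis = Vt[0]
    proj_mean = float(D.mean(axis=0) @ axis)
    mean_zero = abs(proj_mean) < 1e-12 * max(1.0, float(np.abs(D).max()))
    if proj_mean < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), mean_zero


@dataclass(frozen=True)
class TraceConfig:
    """Tunables of :func:`trace_branches`."""

    sep_min: float = 2.0
    n_restarts: int = 10
    seed: int = 0
    gap_merge_ratio: float = 0.6   # gap shrinks below this => mean merging
    weight_vanish_ratio: float = 0.5


@dataclass
class BranchTrace:
    """Projected branch means versus concentration with merge detection."""

    concentrations: np.ndarray
    bimodal: np.ndarray                 # bool per concentration
    proj_on: np.ndarray                 # nan when unimodal
    proj_off: np.ndarray                # nan when unimodal
    proj_single: np.ndarray             # nan when bimodal
    within_sd: np.ndarray               # pooled within-component SD (proj.)
    off_weight: np.ndarray              # nan when unimodal
    axis: np.ndarray
    merge_concentration: float
    merge_uncertainty: float
    transition_type: str                # mean_merging | weight_vanishing |
                                        # ambiguous | all_unimodal |
                                        # all_bimodal
    flags: list[str] = field(default_factory=list)
    per_colony: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items() if k != "per_colony"}
        return d


def trace_branches(plates: pd.DataFrame,
                   config: TraceConfig = TraceConfig()) -> BranchTrace:
    """Trace the projected 'on'/'off' pigmentation branches over a
    concentration series.

    ``plates`` needs columns plate_id, concentration_uM, colony_id, R, G, B
    (one plate per concentration; multiple plates at a concentration are
    pooled after per-plate normalization).  Per concentration the 1- and
    2-component mixtures are fit and selected; bimodal means are projected
    on the leading-PC axis of the off-on differences.  The merge
    concentration is the first concentration of the final unimodal run; the
    transition is labelled ``mean_merging`` when the projected gap has
    shrunk below ``gap_merge_ratio`` of its maximum by the last bimodal
    plate, ``weight_vanishing`` when instead the 'off' weight has fallen
    below ``weight_vanish_ratio`` of its initial value while the gap
    persists.
    """
    required = {"plate_id", "concentration_uM", "colony_id", "R", "G", "B"}
    missing = required - set(plates.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    flags: list[str] = []
    conc = np.sort(plates["concentration_uM"].unique())
    if conc.size < 2:
        raise ValueError("need plates spanning at least 2 concentrations")

    norm_rows = []
    for pid, grp in plates.groupby("plate_id", sort=False):
        g = grp.copy()
        g[["R", "G", "B"]] = normalize_plate(g[["R", "G", "B"]].to_numpy())
        norm_rows.append(g)
    norm = pd.concat(norm_rows, ignore_index=True)

    fits: dict[float, tuple[str, MixtureFit, MixtureFit]] = {}
    for ci, c in enumerate(conc):
        X = norm.loc[norm["concentration_uM"] == c, ["R", "G", "B"]].to_numpy()
        f1 = fit_mixture(X, 1, config.n_restarts, seed=config.seed + 7 * ci)
        f2 = fit_mixture(X, 2, config.n_restarts,
                         seed=config.seed + 7 * ci + 3)
        fits[c] = (select_model(f1, f2, config.sep_min), f1, f2)

    bimodal = np.array([fits[c][0] == "bimodal" for c in conc])

    diffs, off_ws = [], []
    for c in conc[bimodal]:
        f2 = fits[c][2]
        i_off, tie = off_component(f2)
        if tie:
            flags.append(f"red_mean_tie_at_{c}")
        diffs.append(f2.means[i_off] - f2.means[1 - i_off])
        off_ws.append(f2.weights[i_off])
    if len(diffs) >= 2:
        axis, mean_zero = projection_axis(np.array(diffs))
        if mean_zero:
            flags.append("mean_zero_differences")
    elif len(diffs) == 1:
        d = diffs[0]
        axis = d / np.linalg.norm(d)
        flags.append("single_bimodal_plate_axis")
    else:
        axis = np.array([1.0, 0.0, 0.0])
        flags.append("no_bimodal_plates")

    n = conc.size
    proj_on = np.full(n, np.nan)
    proj_off = np.full(n, np.nan)
    proj_single = np.full(n, np.nan)
    within_sd = np.full(n, np.nan)
    off_weight = np.full(n, np.nan)
    label_frames = []
    for ci, c in enumerate(conc):
        kind, f1, f2 = fits[c]
        if kind == "bimodal":
            i_off, _ = off_component(f2)
            proj_off[ci] = f2.means[i_off] @ axis
            proj_on[ci] = f2.means[1 - i_off] @ axis
            pooled = (f2.weights[0] * f2.covariances[0]
                      + f2.weights[1] * f2.covariances[1])
            within_sd[ci] = math.sqrt(max(axis @ pooled @ axis, 0.0))
            off_weight[ci] = f2.weights[i_off]
            sub = norm[norm["concentration_uM"] == c]
            labels, p_off, _ = classify_colonies(
                f2, sub[["R", "G", "B"]].to_numpy())
            lf = sub[["plate_id", "concentration_uM", "colony_id"]].copy()
            lf["label"] = labels
            lf["p_off"] = p_off
            label_frames.append(lf)
        else:
            proj_single[ci] = f1.means[0] @ axis
            within_sd[ci] = math.sqrt(
                max(axis @ f1.covariances[0] @ axis, 0.0))

    # merge point: first concentration of the final unimodal run
    if bimodal.all():
        merge_c = float(conc[-1])
        unc = float(conc[-1] - conc[-2])
        ttype = "all_bimodal"
        flags.append("no_merge_within_range")
    elif not bimodal.any():
        merge_c = float(conc[0])
        unc = float(conc[1] - conc[0])
        ttype = "all_unimodal"
    else:
        uni_idx = np.flatnonzero(~bimodal)
        if bimodal[uni_idx[0]:].any():
            flags.append("bimodal_reappears_above_unimodal")
        last_run_start = uni_idx[-1]
        while last_run_start - 1 in uni_idx:
            last_run_start -= 1
        merge_idx = int(last_run_start)
        merge_c = float(conc[merge_idx])
        unc = float(conc[merge_idx] - conc[merge_idx - 1]) if merge_idx else \
            float(conc[1] - conc[0])
        gaps = proj_off - proj_on
        bi_gaps = gaps[bimodal]
        if bi_gaps.size == 0:
            ttype = "ambiguous"
        else:
            gap_ratio = float(bi_gaps[-1] / np.nanmax(bi_gaps))
            w = off_weight[bimodal]
            w_ratio = float(w[-1] / w[0]) if w[0] > 0 else 1.0
            if gap_ratio < config.gap_merge_ratio:
                ttype = "mean_merging"
            elif w_ratio < config.weight_vanish_ratio:
                ttype = "weight_vanishing"
            else:
                ttype = "ambiguous"

    per_colony = (pd.concat(label_frames, ignore_index=True)
                  if label_frames else None)
    return BranchTrace(conc.astype(float), bimodal, proj_on, proj_off,
                       proj_single, within_sd, off_weight, axis,
                       merge_c, unc, ttype, flags, per_colony)
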