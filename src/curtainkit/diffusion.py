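"""1D diffusion analysis: MSD curves, diffusion-coefficient estimation,
displacement Gaussians, the sliding-vs-hopping salt call, and the
rotation-coupled diffusion speed limit.

A protein tracking the DNA helix must rotate once per helical pitch as it
translocates; the resulting rotational drag caps its 1D diffusion
coefficient far below the Stokes-Einstein value. Measured coefficients
above that cap imply translational sliding without helical tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .config import (
    EXTENSION_UM_PER_KBP,
    InsufficientDataError,
    InvalidConfigError,
    Trajectory,
    substream,
)

BOLTZMANN_J_K = 1.380649e-23


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement versus lag time."""

    lags_s: np.ndarray
    msd_kbp2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags_s) <= 0):
            raise InvalidConfigError("lags must be strictly increasing")
        if np.any(self.msd_kbp2 < 0):
            raise InvalidConfigError("MSD must be >= 0")


@dataclass
class DiffusionEstimate:
    D_um2_s: float
    D_kbp2_s: float
    intercept_kbp2: float
    fit_lags: tuple[int, int]
    se_um2_s: float

    def __post_init__(self) -> None:
        if self.D_um2_s < 0 or self.se_um2_s < 0:
            raise InvalidConfigError("D and its se must be >= 0 after clipping")


@dataclass
class HydroParams:
    """Hydrodynamic parameters for the rotation-coupled diffusion limit.

    ``radius_nm`` is the hydrodynamic radius R of the sliding particle,
    ``offset_nm`` the distance R_OC between its center of mass and the DNA
    helical axis, and ``pitch_nm`` the helical pitch (10.5 bp x 0.34 nm).
    """

    temperature_K: float = 296.15  # 23 C reaction buffer
    viscosity_Pa_s: float = 0.000933  # water at 23 C
    radius_nm: float = 20.0
    offset_nm: float = 20.0
    pitch_nm: float = 3.57

    def __post_init__(self) -> None:
        for name in ("temperature_K", "viscosity_Pa_s", "radius_nm",
                     "offset_nm", "pitch_nm"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")


def compute_msd(traj: Trajectory, max_lag: int) -> MSDCurve:
    """Time-averaged MSD over all ordered frame pairs at lags 1..max_lag."""
    n = len(traj)
    if not 1 <= max_lag < n:
        raise InvalidConfigError(f"max_lag must be in [1, {n - 1}]")
    x = traj.positions_kbp
    dt = traj.frame_interval_s
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean((x[k:] - x[:-k]) ** 2) for k in lags])
    n_pairs = n - lags
    return MSDCurve(lags_s=lags * dt, msd_kbp2=msd, n_pairs=n_pairs)


def estimate_D(
    msd: MSDCurve,
    fit_lags: tuple[int, int] = (1, 10),
    extension: float = EXTENSION_UM_PER_KBP,
) -> DiffusionEstimate:
    """Weighted linear fit MSD = 2*D*t + c over a lag range.

    The variance of the overlapping-pair MSD estimator grows roughly as
    k^2 / n_pairs(k) with the lag index k, so the fit weights are
    n_pairs / k^2 (generalized-least-squares approximation). D is clipped
    at zero; the intercept absorbs static localization error (expectation
    2*sigma_loc^2). Restricting to short lags avoids boundary and
    censoring bias.
    """
    lo, hi = fit_lags
    sel = slice(lo - 1, min(hi, msd.lags_s.size))
    t = msd.lags_s[sel]
    y = msd.msd_kbp2[sel]
    k_idx = np.arange(lo, lo + t.size, dtype=float)
    w = msd.n_pairs[sel].astype(float) / k_idx**2
    if t.size < 2:
        raise InvalidConfigError("need >= 2 lags in the fit range")
    if np.ptp(t) == 0:
        raise InvalidConfigError("degenerate lag range")
    (slope, intercept), cov = np.polyfit(t, y, 1, w=np.sqrt(w), cov="unscaled")
    d_kbp2 = max(slope / 2.0, 0.0)
    se_kbp2 = np.sqrt(max(cov[0, 0], 0.0)) / 2.0
    return DiffusionEstimate(
        D_um2_s=d_kbp2 * extension**2,
        D_kbp2_s=d_kbp2,
        intercept_kbp2=float(intercept),
        fit_lags=(lo, min(hi, msd.lags_s.size)),
        se_um2_s=se_kbp2 * extension**2,
    )


class MSDDiffusionEstimator(BaseEstimator):
    """Pooled diffusion-coefficient estimate from a set of trajectories.

    Computes per-track time-averaged MSDs, pools them weighted by pair
    counts, fits the short-lag linear regime, and reports a
    bootstrap-over-tracks standard error (per-track D distributions on
    curtains are broad, so track-level resampling is the honest error).

    Parameters
    ----------
    fit_lags : (int, int)
        Inclusive lag-index range for the linear fit (default 1-10).
    extension_um_per_kbp : float
        Flow-stretch extension factor converting kbp^2/s to um^2/s.
    n_boot : int
        Bootstrap resamples over tracks for the standard error.
    random_state : int
        Seed for the bootstrap.

    Attributes
    ----------
    D_um2_s_, D_kbp2_s_, intercept_kbp2_, se_um2_s_ : float
    per_track_D_um2_s_ : ndarray
    msd_ : MSDCurve  (pooled)
    """

    def __init__(
        self,
        fit_lags: tuple[int, int] = (1, 10),
        extension_um_per_kbp: float = EXTENSION_UM_PER_KBP,
        n_boot: int = 1000,
        random_state: int = 0,
    ):
        self.fit_lags = fit_lags
        self.extension_um_per_kbp = extension_um_per_kbp
        self.n_boot = n_boot
        self.random_state = random_state

    def _pool(self, curves: Sequence[MSDCurve]) -> MSDCurve:
        max_len = max(c.lags_s.size for c in curves)
        dt = curves[0].lags_s[0]
        num = np.zeros(max_len)
        den = np.zeros(max_len)
        for c in curves:
            k = c.lags_s.size
            num[:k] += c.msd_kbp2 * c.n_pairs
            den[:k] += c.n_pairs
        keep = den > 0
        return MSDCurve(
            lags_s=(np.arange(max_len) + 1)[keep] * dt,
            msd_kbp2=(num / np.maximum(den, 1))[keep],
            n_pairs=den[keep].astype(int),
        )

    def fit(self, X: Iterable[Trajectory], y=None):
        trajs = [t for t in X if len(t) > self.fit_lags[0]]
        if not trajs:
            raise InsufficientDataError("no trajectory long enough for the fit")
        max_lag = self.fit_lags[1]
        curves = [
            compute_msd(t, min(max_lag, len(t) - 1)) for t in trajs
        ]
        pooled = self._pool(curves)
        est = estimate_D(pooled, self.fit_lags, self.extension_um_per_kbp)

        per_track = []
        for c in curves:
            try:
                per_track.append(
                    estimate_D(c, self.fit_lags, self.extension_um_per_kbp).D_um2_s
                )
            except InvalidConfigError:
                per_track.append(np.nan)
        self.per_track_D_um2_s_ = np.asarray(per_track)

        rng = substream(self.random_state, "msd-boot")
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            idx = rng.integers(0, len(curves), size=len(curves))
            boots[b] = estimate_D(
                self._pool([curves[i] for i in idx]),
                self.fit_lags,
                self.extension_um_per_kbp,
            ).D_um2_s
        self.D_um2_s_ = est.D_um2_s
        self.D_kbp2_s_ = est.D_kbp2_s
        self.intercept_kbp2_ = est.intercept_kbp2
        self.se_um2_s_ = float(np.std(boots, ddof=1)) if self.n_boot > 1 else 0.0
        self.msd_ = pooled
        self.n_tracks_ = len(curves)
        return self

    @property
    def estimate_(self) -> DiffusionEstimate:
        return DiffusionEstimate(
            D_um2_s=self.D_um2_s_,
            D_kbp2_s=self.D_kbp2_s_,
            intercept_kbp2=self.intercept_kbp2_,
            fit_lags=self.fit_lags,
            se_um2_s=self.se_um2_s_,
        )


def displacement_gaussian(
    trajs: Iterable[Trajectory], lag: int = 1
) -> tuple[float, float, float]:
    """Single-Gaussian fit to the pooled displacement histogram.

    Brownian motion without drift gives displacements symmetric about zero;
    a non-zero fitted center flags flow or directional bias. Returns
    ``(center_kbp, sigma_kbp, r_squared)``.
    """
    disp = np.concatenate([t.displacements(lag) for t in trajs if len(t) > lag])
    if disp.size < 30:
        raise InsufficientDataError(f"need >= 30 displacements, got {disp.size}")
    # symmetric binning about the sample mean keeps the fit unbiased on
    # symmetric data
    half_span = max(np.max(np.abs(disp - disp.mean())), 1e-9)
    edges = disp.mean() + np.linspace(-half_span, half_span, 41)
    counts, edges = np.histogram(disp, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = [counts.max(), float(disp.mean()), float(disp.std() + 1e-9)]
    popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=10_000)
    bin_width = edges[1] - edges[0]
    span = edges[-1] - edges[0]
    if (abs(popt[2]) < bin_width or abs(popt[2]) > span
            or not edges[0] <= popt[1] <= edges[-1]):
        # degenerate LSQ solution (sub-bin spike, flatter than the data
        # range, or center off-histogram — possible for discrete or
        # bimodal data); fall back to the moment estimate, which
        # respects symmetry
        popt = np.array([counts.max(), disp.mean(), max(disp.std(), bin_width)])
    fitted = gauss(centers, *popt)
    ss_res = np.sum((counts - fitted) ** 2)
    ss_tot = np.sum((counts - counts.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(popt[1]), float(abs(popt[2])), float(r2)


def salt_series_call(
    points: Sequence[tuple[float, DiffusionEstimate]],
    rel_change_threshold: float = 0.25,
) -> str:
    """Classify 1D-diffusion mode from the salt dependence of D.

    Hopping involves micro-dissociation, so D rises with ionic strength;
    sliding maintains continuous contact and is salt-insensitive. A
    weighted regression of D on salt is called ``hopping`` when the slope's
    95% CI excludes zero with positive sign and the fitted relative
    increase across the range exceeds ``rel_change_threshold``; ``sliding``
    when the CI contains zero and the relative change is at most the
    threshold; otherwise ``inconclusive``.
    """
    salts = np.array([s for s, _ in points], dtype=float)
    if np.unique(salts).size < 2:
        raise InvalidConfigError("need >= 2 distinct salt concentrations")
    ds = np.array([e.D_um2_s for _, e in points])
    ses = np.array([max(e.se_um2_s, 1e-12) for _, e in points])
    w = 1.0 / ses**2
    # weighted least squares slope/intercept with analytic covariance
    W = np.sum(w)
    xb = np.sum(w * salts) / W
    yb = np.sum(w * ds) / W
    sxx = np.sum(w * (salts - xb) ** 2)
    slope = np.sum(w * (salts - xb) * (ds - yb)) / sxx
    intercept = yb - slope * xb
    slope_se = np.sqrt(1.0 / sxx)
    ci = stats.norm.interval(0.95, loc=slope, scale=slope_se)

    pred_lo = intercept + slope * salts.min()
    pred_hi = intercept + slope * salts.max()
    rel_change = (pred_hi - pred_lo) / pred_lo if pred_lo > 0 else np.inf
    slope_positive = ci[0] > 0
    slope_zero = ci[0] <= 0 <= ci[1]
    if slope_positive and rel_change > rel_change_threshold:
        return "hopping"
    if slope_zero and abs(rel_change) <= rel_change_threshold:
        return "sliding"
    return "inconclusive"


def rotational_limit(h: HydroParams) -> float:
    """Theoretical ceiling on D for rotation-coupled sliding, in um^2/s.

    For a particle of radius R tracking a helix of pitch p with its center
    offset R_OC from the helical axis:

        D_max = kB*T / { 6*pi*eta*R * [1 + (4/3)*(2*pi/p)^2*R^2
                                          + (2*pi/p)^2*R_OC^2] }

    As p -> infinity the bracket tends to 1 and the expression reduces to
    the Stokes-Einstein translational coefficient.
    """
    R = h.radius_nm * 1e-9
    roc = h.offset_nm * 1e-9
    p = h.pitch_nm * 1e-9
    k = (2.0 * np.pi / p) ** 2
    drag_factor = 1.0 + (4.0 / 3.0) * k * R**2 + k * roc**2
    d_m2_s = BOLTZMANN_J_K * h.temperature_K / (
        6.0 * np.pi * h.viscosity_Pa_s * R * drag_factor
    )
    return d_m2_s * 1e12  # m^2/s -> um^2/s
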