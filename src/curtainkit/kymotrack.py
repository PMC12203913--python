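"""Kymograph rendering and single-particle tracking.

A kymograph is the position-versus-time intensity image of one particle on
one DNA molecule. Rendering integrates a Gaussian point-spread function
over pixels with Poisson photon statistics; tracking recovers trajectories
by per-frame spot detection (local maximum above a Poisson threshold,
sub-pixel 1D Gaussian fit) and greedy nearest-neighbor linking with
single-frame gap closing — the single-particle, low-density regime of DNA
curtains needs nothing heavier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .config import InvalidConfigError, Trajectory, substream


@dataclass
class KymographImage:
    intensity: np.ndarray  # (frame, pixel)
    pixel_size_kbp: float = 1.0
    frame_interval_s: float = 0.1
    psf_sigma_px: float = 1.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or min(self.intensity.shape) < 1:
            raise InvalidConfigError("intensity must be a 2D array, >= 1x1")
        if np.any(self.intensity < 0):
            raise InvalidConfigError("intensity must be nonnegative")


class RenderError(RuntimeError):
    pass


def render_kymograph(
    traj: Trajectory,
    psf_sigma_px: float = 1.0,
    photons_per_frame: float = 500.0,
    background: float = 2.0,
    seed: int = 0,
    pixel_size_kbp: float = 1.0,
    n_pixels: int | None = None,
    poisson_noise: bool = True,
) -> KymographImage:
    """Render a trajectory into a kymograph image.

    Each frame carries a Gaussian spot integrated over pixels (sub-pixel
    placement via the error function), a uniform background, and optional
    Poisson photon noise.
    """
    if psf_sigma_px <= 0:
        raise InvalidConfigError("psf_sigma_px must be positive")
    if photons_per_frame <= 0:
        raise InvalidConfigError("photons_per_frame must be positive")
    pos_px = traj.positions_kbp / pixel_size_kbp
    if n_pixels is None:
        n_pixels = int(np.ceil(pos_px.max() + 5 * psf_sigma_px)) + 1
    if np.any(pos_px < 0) or np.any(pos_px > n_pixels - 1):
        raise RenderError("trajectory leaves the rendered field")

    edges = np.arange(n_pixels + 1) - 0.5
    frames = np.empty((len(traj), n_pixels))
    for f, x in enumerate(pos_px):
        cdf = norm.cdf(edges, loc=x, scale=psf_sigma_px)
        frames[f] = photons_per_frame * np.diff(cdf) + background
    if poisson_noise:
        rng = substream(seed, "kymo-render", traj.track_id)
        frames = rng.poisson(frames).astype(float)
    return KymographImage(
        intensity=frames,
        pixel_size_kbp=pixel_size_kbp,
        frame_interval_s=traj.frame_interval_s if len(traj) >= 2 else 0.1,
        psf_sigma_px=psf_sigma_px,
        background_level=background,
    )


def _fit_spot(profile: np.ndarray, peak_idx: int, psf_sigma_px: float) -> float | None:
    """Sub-pixel localization: least-squares 1D Gaussian on a 7-px window."""
    n = profile.size
    lo = max(peak_idx - 3, 0)
    hi = min(peak_idx + 4, n)
    xw = np.arange(lo, hi, dtype=float)
    yw = profile[lo:hi].astype(float)

    def gauss(x, a, mu, sig, b):
        return b + a * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    base = float(yw.min())
    p0 = [max(yw.max() - base, 1e-6), float(peak_idx), psf_sigma_px, base]
    try:
        popt, _ = optimize.curve_fit(
            gauss, xw, yw, p0=p0,
            bounds=([0, lo - 1, 0.2, 0], [np.inf, hi, 10.0, np.inf]),
            maxfev=5_000,
        )
    except RuntimeError:
        return None
    return float(popt[1])


def _detect_spots(
    frame: np.ndarray, threshold: float, psf_sigma_px: float, min_sep_px: int = 3
) -> list[float]:
    """Local maxima above threshold, refined to sub-pixel; ties at equal
    intensity break toward the lower pixel index."""
    above = frame > threshold
    candidates = [
        i
        for i in range(frame.size)
        if above[i]
        and (i == 0 or frame[i] > frame[i - 1])
        and (i == frame.size - 1 or frame[i] >= frame[i + 1])
    ]
    # enforce minimal separation, keeping the brighter candidate
    kept: list[int] = []
    for i in sorted(candidates, key=lambda j: (-frame[j], j)):
        if all(abs(i - j) >= min_sep_px for j in kept):
            kept.append(i)
    out = []
    for i in sorted(kept):
        mu = _fit_spot(frame, i, psf_sigma_px)
        if mu is not None:
            out.append(mu)
    return out


def track_kymograph(
    img: KymographImage,
    max_jump_px: float = 3.0,
    min_track_len: int = 5,
    threshold: float | None = None,
) -> list[Trajectory]:
    """Recover trajectories from a kymograph.

    Detection threshold defaults to ``background + 4*sqrt(background)``
    (a 4-sigma Poisson cut). Linking is greedy nearest-neighbor with a hard
    ``max_jump_px`` and gap closing over at most one missed frame; tracks
    shorter than ``min_track_len`` detections are discarded. Positions are
    returned in kbp.
    """
    if max_jump_px < 1:
        raise InvalidConfigError("max_jump_px must be >= 1")
    bg = img.background_level
    if threshold is None:
        threshold = bg + 4.0 * np.sqrt(max(bg, 1.0))

    n_frames = img.intensity.shape[0]
    detections = [
        _detect_spots(img.intensity[f], threshold, img.psf_sigma_px)
        for f in range(n_frames)
    ]

    # active track: (positions-by-frame dict, last frame, last position)
    active: list[dict] = []
    finished: list[dict] = []
    for f, spots in enumerate(detections):
        unclaimed = list(spots)
        # greedy: closest (track, spot) pairs first
        pairs = sorted(
            (
                (abs(tr["last_pos"] - s), ti, s)
                for ti, tr in enumerate(active)
                for s in unclaimed
            ),
            key=lambda p: p[0],
        )
        claimed_tracks: set[int] = set()
        claimed_spots: set[float] = set()
        for dist, ti, s in pairs:
            if ti in claimed_tracks or s in claimed_spots:
                continue
            gap = f - active[ti]["last_frame"]
            if gap > 2 or dist > max_jump_px * gap:
                continue
            active[ti]["frames"][f] = s
            active[ti]["last_frame"] = f
            active[ti]["last_pos"] = s
            claimed_tracks.add(ti)
            claimed_spots.add(s)
        # retire tracks that missed more than one frame
        still = []
        for tr in active:
            if f - tr["last_frame"] > 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        for s in spots:
            if s not in claimed_spots:
                active.append({"frames": {f: s}, "last_frame": f, "last_pos": s})
    finished.extend(active)

    trajs = []
    for k, tr in enumerate(finished):
        if len(tr["frames"]) < min_track_len:
            continue
        frames = np.array(sorted(tr["frames"]))
        pos_px = np.array([tr["frames"][f] for f in frames])
        # interpolate across single-frame gaps onto a uniform grid
        grid = np.arange(frames[0], frames[-1] + 1)
        pos = np.interp(grid, frames, pos_px)
        trajs.append(
            Trajectory(
                track_id=f"kymo-{k}",
                times_s=grid * img.frame_interval_s,
                positions_kbp=pos * img.pixel_size_kbp,
                sigma_loc_kbp=img.pixel_size_kbp * img.psf_sigma_px
                / np.sqrt(max(img.intensity.max(), 1.0)),
            )
        )
    return trajs
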