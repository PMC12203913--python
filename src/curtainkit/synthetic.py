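"""Synthetic-data generators for every pipeline input.

Replaces the microscope and the gel scanner: Brownian 1D sliding tracks with
localization noise on flow-stretched lambda DNA, lesion-search experiments
with direct-binding vs diffusive-arrival populations and geometric bypass
statistics, curtain binding-position snapshots, equilibrium titration
ladders, and two-component FRAP recovery traces. All generators are
deterministic under a fixed seed via :func:`curtainkit.config.substream`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    DwellEvent,
    EquilibriumParams,
    FrapTrace,
    InvalidConfigError,
    SimConfig,
    TitrationSeries,
    Trajectory,
    substream,
)
from . import equilibria


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] by mirror reflection at both ends."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def simulate_sliding_trajectory(
    cfg: SimConfig, track_id: str = "sim-0", stream: tuple = ()
) -> Trajectory:
    """Simulate one Brownian 1D-sliding track along the DNA.

    Per-frame true displacements are Gaussian with variance ``2*D*dt``
    (converted from um^2/s to kbp^2/s via the extension factor), reflected
    at the DNA ends; independent Gaussian localization noise of sd
    ``localization_sigma_kbp`` is added on top. The start position is
    uniform on the molecule.
    """
    rng = substream(cfg.rng_seed, "sliding", *stream, track_id)
    L = cfg.dna_length_kbp
    dt = cfg.frame_interval_s
    step_sd = np.sqrt(2.0 * cfg.diffusion_kbp2_s * dt)

    start = rng.uniform(0.0, L)
    steps = rng.normal(0.0, step_sd, size=cfg.n_frames - 1) if cfg.n_frames > 1 else []
    true = _reflect(start + np.concatenate([[0.0], np.cumsum(steps)]), 0.0, L)
    observed = true + rng.normal(0.0, cfg.localization_sigma_kbp, size=cfg.n_frames)
    observed = np.clip(observed, 0.0, L)

    times = np.arange(cfg.n_frames) * dt
    return Trajectory(
        track_id=track_id,
        times_s=times,
        positions_kbp=observed,
        sigma_loc_kbp=cfg.localization_sigma_kbp,
        salt_mM=cfg.salt_mM,
        censored_end=times[-1] + dt >= cfg.observation_window_s,
    )


def _render_search_track(
    cfg: SimConfig,
    rng: np.random.Generator,
    track_id: str,
    mode: str,
    arrival_time_s: float,
    dwell_s: float,
) -> Trajectory:
    """Render a stylized track consistent with a drawn search outcome."""
    L = cfg.dna_length_kbp
    lo, hi = cfg.lesion_interval_kbp
    center = 0.5 * (lo + hi)
    dt = cfg.frame_interval_s
    n = cfg.n_frames
    t = np.arange(n) * dt
    step_sd = np.sqrt(2.0 * cfg.diffusion_kbp2_s * dt)

    if mode == "direct":
        true = np.full(n, center)
    else:
        start = rng.uniform(0.0, L)
        steps = rng.normal(0.0, step_sd, size=n - 1)
        path = _reflect(start + np.concatenate([[0.0], np.cumsum(steps)]), 0.0, L)
        true = path.copy()
        if mode == "diffusion":
            arrested = t >= arrival_time_s
            true[arrested] = center
    if dwell_s < cfg.observation_window_s and mode != "none":
        # after release the molecule leaves the field of view; truncate there
        keep = t <= arrival_time_s + dwell_s
        t, true = t[keep], true[keep]
    observed = np.clip(
        true + rng.normal(0.0, cfg.localization_sigma_kbp, size=true.size), 0.0, L
    )
    return Trajectory(
        track_id=track_id,
        times_s=t,
        positions_kbp=observed,
        sigma_loc_kbp=cfg.localization_sigma_kbp,
        salt_mM=cfg.salt_mM,
        censored_end=bool(t[-1] + dt >= cfg.observation_window_s),
    )


def simulate_search_experiment(
    cfg: SimConfig, n_molecules: int, mode: str = "fast"
) -> list[tuple[Trajectory, DwellEvent]]:
    """Simulate a lesion-search experiment on the 3xCPD lambda construct.

    Each molecule either binds the lesion directly on arrival (probability
    ``direct_binding_prob``) or reaches it by 1D diffusion. Diffusive
    arrivals transit the lesion window a geometric number of times before
    capture (per-pass capture probability ``capture_prob_per_pass``);
    arrested molecules dwell exponentially with mean ``mean_dwell_s``,
    right-censored at the observation window.

    ``mode="fast"`` draws bypass counts and dwells from their distributions
    and renders a stylized trajectory (the statistic-testing mode);
    ``mode="explicit"`` integrates an actual Brownian path and applies the
    per-pass capture to real window crossings, so the ground-truth labels
    derive from the path itself (the tracker-testing mode).
    """
    if n_molecules < 1:
        raise InvalidConfigError("n_molecules must be >= 1")
    if mode not in ("fast", "explicit"):
        raise InvalidConfigError(f"unknown search mode {mode!r}")
    if mode == "explicit":
        return _simulate_search_explicit(cfg, n_molecules)

    out: list[tuple[Trajectory, DwellEvent]] = []
    q = cfg.capture_prob_per_pass
    for i in range(n_molecules):
        rng = substream(cfg.rng_seed, "search", "fast", i)
        track_id = f"search-{i}"
        if rng.random() < cfg.direct_binding_prob:
            emode, bypass, arrival = "direct", 0, 0.0
        else:
            emode = "diffusion"
            # geometric number of failed passes before capture; q=0 means
            # the molecule bypasses forever and never arrests
            bypass = int(rng.geometric(q) - 1) if q > 0 else np.inf
            arrival = rng.uniform(0.1, 0.5) * cfg.observation_window_s
            if not np.isfinite(bypass):
                # never captured: record a typical number of window transits
                # accumulated over the observation window
                emode, bypass, arrival = "none", int(rng.poisson(5.0)), 0.0
        if emode == "none":
            dwell, censored = 0.0, False
        else:
            dwell = float(rng.exponential(cfg.mean_dwell_s))
            remaining = cfg.observation_window_s - arrival
            censored = dwell >= remaining
            dwell = min(dwell, remaining)
        event = DwellEvent(
            track_id=track_id,
            mode=emode,
            bypass_count=int(bypass),
            dwell_s=dwell,
            censored=censored,
            arrival_time_s=arrival,
        )
        traj = _render_search_track(cfg, rng, track_id, emode, arrival, dwell)
        out.append((traj, event))
    return out


def _simulate_search_explicit(
    cfg: SimConfig, n_molecules: int
) -> list[tuple[Trajectory, DwellEvent]]:
    L = cfg.dna_length_kbp
    lo, hi = cfg.lesion_interval_kbp
    center = 0.5 * (lo + hi)
    dt = cfg.frame_interval_s
    n = cfg.n_frames
    step_sd = np.sqrt(2.0 * cfg.diffusion_kbp2_s * dt)
    # detection window for a "pass": the lesion interval padded to one pixel
    pad = max(0.5 * (1.0 - (hi - lo)), 0.0)
    wlo, whi = lo - pad, hi + pad

    out: list[tuple[Trajectory, DwellEvent]] = []
    for i in range(n_molecules):
        rng = substream(cfg.rng_seed, "search", "explicit", i)
        track_id = f"search-{i}"
        direct = rng.random() < cfg.direct_binding_prob
        true = np.empty(n)
        bypass = 0
        arrest_frame: int | None = None
        if direct:
            true[:] = center
            arrest_frame = 0
            emode = "direct"
        else:
            x = rng.uniform(0.0, L)
            inside = wlo <= x <= whi
            for f in range(n):
                true[f] = x
                if arrest_frame is not None:
                    true[f] = center
                    continue
                nxt = _reflect(np.array([x + rng.normal(0.0, step_sd)]), 0.0, L)[0]
                entering = (wlo <= nxt <= whi) and not inside
                if entering:
                    if rng.random() < cfg.capture_prob_per_pass:
                        arrest_frame = f + 1
                    else:
                        bypass += 1
                inside = wlo <= nxt <= whi
                x = nxt
            # ground-truth labels follow the observable convention: an
            # arrest is "diffusion" only if the molecule had been more than
            # one pixel away from the lesion window beforehand; sub-pixel
            # wandering before capture is indistinguishable from direct
            # binding at ~1 kbp/pixel resolution
            if arrest_frame is None:
                emode = "none"
            elif arrest_frame < 2 or not np.any(
                (true[:arrest_frame] < wlo - 1.0) | (true[:arrest_frame] > whi + 1.0)
            ):
                emode, bypass = "direct", 0
            else:
                emode = "diffusion"
        if arrest_frame is not None:
            arrival = arrest_frame * dt
            dwell = float(rng.exponential(cfg.mean_dwell_s))
            remaining = min(cfg.observation_window_s, n * dt) - arrival
            censored = dwell >= remaining
            dwell = min(dwell, remaining)
            keep = np.arange(n) * dt <= arrival + dwell
            tvec, truek = np.arange(n)[keep] * dt, true[keep]
        else:
            arrival, dwell, censored = 0.0, 0.0, False
            tvec, truek = np.arange(n) * dt, true
        observed = np.clip(
            truek + rng.normal(0.0, cfg.localization_sigma_kbp, size=truek.size),
            0.0,
            L,
        )
        traj = Trajectory(
            track_id=track_id,
            times_s=tvec,
            positions_kbp=observed,
            sigma_loc_kbp=cfg.localization_sigma_kbp,
            salt_mM=cfg.salt_mM,
            censored_end=bool(tvec[-1] + dt >= min(cfg.observation_window_s, n * dt)),
        )
        out.append(
            (
                traj,
                DwellEvent(
                    track_id=track_id,
                    mode=emode,
                    bypass_count=0 if emode == "direct" else bypass,
                    dwell_s=dwell,
                    censored=censored,
                    arrival_time_s=arrival,
                ),
            )
        )
    return out


@dataclass
class CurtainSnapshot:
    """Binding positions pooled over a curtain field of view, with lesion
    metadata and (hidden) ground-truth specificity labels."""

    positions_kbp: np.ndarray
    lesion_interval_kbp: tuple[float, float]
    dna_length_kbp: float
    is_specific: np.ndarray | None = None


def simulate_curtain_snapshot(
    cfg: SimConfig, n_events: int, specific_fraction: float
) -> CurtainSnapshot:
    """Simulate per-DNA binding positions across a curtain field.

    A fraction ``specific_fraction`` of events is uniform within the lesion
    interval, the rest uniform over the whole molecule; both are convolved
    with Gaussian localization noise and clipped to the DNA.
    """
    if n_events < 1:
        raise InvalidConfigError("n_events must be >= 1")
    if not 0.0 <= specific_fraction <= 1.0:
        raise InvalidConfigError("specific_fraction must be in [0, 1]")
    rng = substream(cfg.rng_seed, "curtain")
    L = cfg.dna_length_kbp
    lo, hi = cfg.lesion_interval_kbp
    specific = rng.random(n_events) < specific_fraction
    pos = np.where(
        specific,
        rng.uniform(lo, hi, size=n_events),
        rng.uniform(0.0, L, size=n_events),
    )
    pos = pos + rng.normal(0.0, cfg.localization_sigma_kbp, size=n_events)
    return CurtainSnapshot(
        positions_kbp=np.clip(pos, 0.0, L),
        lesion_interval_kbp=(lo, hi),
        dna_length_kbp=L,
        is_specific=specific,
    )


def simulate_titration(
    params: EquilibriumParams,
    ladder_nM,
    dna_total_nM: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    protein: str = "U",
    substrate: str = "cpd",
    partner_total_nM: float = 0.0,
) -> TitrationSeries:
    """Simulate an EMSA titration ladder from the mass-balance equilibria.

    For each lane the expected species fractions on DNA (free, singly bound
    titrant, doubly bound, co-bound, partner-bound) come from
    :func:`curtainkit.equilibria.solve_ux`; multiplicative Gaussian noise of
    sd ``noise_sd`` is then applied per band and lanes renormalized to sum
    to 1, mimicking densitometry error.
    """
    ladder = np.asarray(ladder_nM, dtype=float)
    if np.any(ladder < 0):
        raise InvalidConfigError("ladder concentrations must be >= 0")
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    if protein not in ("U", "X"):
        raise InvalidConfigError("protein must be 'U' or 'X'")

    labels = ("free", "1x", "2x", "cobind", "partner")
    fractions = {k: np.zeros_like(ladder) for k in labels}
    for j, conc in enumerate(ladder):
        totals = {"U": 0.0, "X": 0.0, "D": dna_total_nM}
        totals[protein] = conc
        totals["X" if protein == "U" else "U"] = partner_total_nM
        p = EquilibriumParams(
            kd_U_cpd_nM=params.kd_U_cpd_nM,
            kd_U_und_nM=params.kd_U_und_nM,
            kd_X_cpd_nM=params.kd_X_cpd_nM,
            kd_X_und_nM=params.kd_X_und_nM,
            kd_UX_protein_nM=params.kd_UX_protein_nM,
            kd_UXdna_policy=params.kd_UXdna_policy,
            kd_U2_nM=params.kd_U2_nM,
            totals=totals,
        )
        state = equilibria.solve_ux(p, substrate)
        D = dna_total_nM
        own = state.UD if protein == "U" else state.XD
        other = state.XD if protein == "U" else state.UD
        fractions["free"][j] = state.D / D
        fractions["1x"][j] = own / D
        fractions["2x"][j] = state.U2D / D
        fractions["cobind"][j] = state.UXD / D
        fractions["partner"][j] = other / D

    if noise_sd > 0:
        rng = substream(seed, "titration")
        for k in labels:
            fractions[k] = fractions[k] * np.clip(
                1.0 + rng.normal(0.0, noise_sd, size=ladder.size), 0.0, None
            )
        total = sum(fractions.values())
        for k in labels:
            fractions[k] = np.divide(
                fractions[k], total, out=np.zeros_like(total), where=total > 0
            )
    return TitrationSeries(
        protein_concs_nM=ladder,
        dna_total_nM=dna_total_nM,
        band_fractions=fractions,
        noise_sd=noise_sd,
    )


def simulate_frap(
    mobile_fraction: float,
    recovery_tau_s: float,
    times_s,
    bleach_depth: float = 0.6,
    noise_sd: float = 0.0,
    n_prebleach: int = 5,
    seed: int = 0,
    condition: str = "",
) -> FrapTrace:
    """Simulate a normalized FRAP trace with single-exponential recovery.

    Pre-bleach intensity is 1; the bleach removes ``bleach_depth`` of the
    signal, after which a fraction ``mobile_fraction`` of the bleached pool
    recovers with time constant ``recovery_tau_s``:
    ``f(t) = (1 - bleach_depth) + bleach_depth * mobile_fraction * (1 - exp(-t/tau))``.
    ``times_s`` are post-bleach sampling times (default acquisition in the
    assay this emulates: one frame per second).
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise InvalidConfigError("mobile_fraction must be in [0, 1]")
    if recovery_tau_s <= 0:
        raise InvalidConfigError("recovery_tau_s must be positive")
    times = np.asarray(times_s, dtype=float)
    if times.size == 0:
        raise InvalidConfigError("empty time grid")
    if not 0.0 < bleach_depth <= 1.0:
        raise InvalidConfigError("bleach_depth must be in (0, 1]")

    dt = times[1] - times[0] if times.size > 1 else 1.0
    pre_t = times[0] - dt * np.arange(n_prebleach, 0, -1)
    baseline = 1.0 - bleach_depth
    post = baseline + bleach_depth * mobile_fraction * (1.0 - np.exp(-times / recovery_tau_s))
    full_t = np.concatenate([pre_t, times])
    full_i = np.concatenate([np.ones(n_prebleach), post])
    if noise_sd > 0:
        rng = substream(seed, "frap", condition)
        full_i = np.clip(full_i + rng.normal(0.0, noise_sd, size=full_i.size), 0.0, None)
    return FrapTrace(
        times_s=full_t, intensity_norm=full_i, bleach_time_s=0.0, condition=condition
    )
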