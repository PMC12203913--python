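"""File formats, run configuration, and the end-to-end pipeline driver.

Conventions: TSV for tables, JSON for results, YAML for configuration,
single-plane TIFF for kymographs. Positions are stored in kbp (0-based
from the barrier-tethered end), times in seconds. Every artifact carries a
schema version; readers reject newer majors.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import diffusion, equilibria, lesion_search, position_stats, synthetic
from .config import (
    DwellEvent,
    EquilibriumParams,
    InvalidConfigError,
    SimConfig,
    TitrationSeries,
    Trajectory,
)

SCHEMA_VERSION = "1.0"
logger = logging.getLogger("curtainkit")

TRACK_COLUMNS = [
    "track_id", "frame", "time_s", "position_kbp", "sigma_kbp", "salt_mM",
    "censored_end",
]


class SchemaError(ValueError):
    pass


def _check_schema(version: str) -> None:
    major = int(str(version).split(".")[0])
    if major > int(SCHEMA_VERSION.split(".")[0]):
        raise SchemaError(
            f"artifact schema {version} newer than supported {SCHEMA_VERSION}"
        )


def _write_sidecar(path: Path, payload: dict) -> None:
    meta = {"schema_version": SCHEMA_VERSION, **payload}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def write_tracks(trajs: Iterable[Trajectory], path, config: dict | None = None) -> None:
    path = Path(path)
    rows = []
    for tr in trajs:
        for f, (t, x) in enumerate(zip(tr.times_s, tr.positions_kbp)):
            rows.append(
                (tr.track_id, f, t, x, tr.sigma_loc_kbp, tr.salt_mM, tr.censored_end)
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {"kind": "tracks", "config": config or {}})


def load_tracks(path) -> list[Trajectory]:
    """Read the TSV track table; malformed tracks are reported by line."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        _check_schema(json.loads(sidecar.read_text()).get("schema_version", "1.0"))
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty track file", RuntimeWarning, stacklevel=2)
        return []
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: no tracks", RuntimeWarning, stacklevel=2)
        return []
    out = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            first_line = int(grp.index[0]) + 2  # header + 1-based
            raise InvalidConfigError(
                f"{path}: track {tid!r} (starting line {first_line}) has "
                "non-monotonic time"
            )
        out.append(
            Trajectory(
                track_id=str(tid),
                times_s=times,
                positions_kbp=grp["position_kbp"].to_numpy(dtype=float),
                sigma_loc_kbp=float(grp["sigma_kbp"].iloc[0]),
                salt_mM=float(grp["salt_mM"].iloc[0]),
                censored_end=bool(grp["censored_end"].iloc[0]),
            )
        )
    return out


def write_snapshot(snapshot, path, config: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "dna_id": np.arange(snapshot.positions_kbp.size),
            "position_kbp": snapshot.positions_kbp,
        }
    ).to_csv(path, sep="\t", index=False)
    _write_sidecar(
        path,
        {
            "kind": "snapshot",
            "lesion_interval_kbp": list(snapshot.lesion_interval_kbp),
            "dna_length_kbp": snapshot.dna_length_kbp,
            "config": config or {},
        },
    )


def load_snapshot_positions(path) -> np.ndarray:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    if "position_kbp" not in df.columns:
        raise SchemaError(f"{path}: missing position_kbp column")
    return df["position_kbp"].to_numpy(dtype=float)


def write_titration(series: TitrationSeries, path, config: dict | None = None) -> None:
    path = Path(path)
    rows = []
    for species, fracs in series.band_fractions.items():
        for conc, frac in zip(series.protein_concs_nM, fracs):
            rows.append((conc, species, frac))
    pd.DataFrame(rows, columns=["conc_nM", "species", "fraction"]).to_csv(
        path, sep="\t", index=False
    )
    _write_sidecar(
        path,
        {"kind": "titration", "dna_total_nM": series.dna_total_nM,
         "noise_sd": series.noise_sd, "config": config or {}},
    )


def load_titration(path, dna_total_nM: float | None = None) -> TitrationSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("conc_nM", "species", "fraction"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    if dna_total_nM is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        _check_schema(meta.get("schema_version", "1.0"))
        dna_total_nM = float(meta["dna_total_nM"])
    wide = df.pivot_table(index="conc_nM", columns="species", values="fraction").sort_index()
    return TitrationSeries(
        protein_concs_nM=wide.index.to_numpy(dtype=float),
        dna_total_nM=dna_total_nM,
        band_fractions={c: wide[c].to_numpy(dtype=float) for c in wide.columns},
    )


def write_events(events: Iterable[DwellEvent], path) -> None:
    path = Path(path)
    pd.DataFrame(
        [
            (e.track_id, e.mode, e.bypass_count, e.dwell_s, e.censored)
            for e in events
        ],
        columns=["track_id", "mode", "bypass_count", "dwell_s", "censored"],
    ).to_csv(path, sep="\t", index=False)
    _write_sidecar(path, {"kind": "events"})


def load_events(path) -> list[DwellEvent]:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    return [
        DwellEvent(
            track_id=str(r.track_id),
            mode=str(r.mode),
            bypass_count=int(r.bypass_count),
            dwell_s=float(r.dwell_s),
            censored=bool(r.censored),
        )
        for r in df.itertuples()
    ]


def write_kymograph(img, path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, img.intensity.astype(np.float32))
    _write_sidecar(
        path,
        {
            "kind": "kymograph",
            "pixel_size_kbp": img.pixel_size_kbp,
            "frame_interval_s": img.frame_interval_s,
            "psf_sigma_px": img.psf_sigma_px,
            "background_level": img.background_level,
        },
    )


def load_kymograph(path):
    import tifffile

    from .kymotrack import KymographImage

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    _check_schema(meta.get("schema_version", "1.0"))
    return KymographImage(
        intensity=tifffile.imread(path).astype(float),
        pixel_size_kbp=meta["pixel_size_kbp"],
        frame_interval_s=meta["frame_interval_s"],
        psf_sigma_px=meta["psf_sigma_px"],
        background_level=meta["background_level"],
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline driver

_KNOWN_SECTIONS = {"seed", "out_dir", "verbosity", "sim", "sliding", "search",
                   "curtain", "titration"}
_KNOWN_KEYS = {
    "sliding": {"n_tracks"},
    "search": {"n_molecules", "mode"},
    "curtain": {"n_events", "specific_fraction"},
    "titration": {"ladder_nM", "dna_total_nM", "noise_sd", "protein", "substrate"},
}


def validate_config(config: dict) -> dict:
    """Validate a run configuration, rejecting unknown keys."""
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise InvalidConfigError(f"unknown config sections: {sorted(unknown)}")
    sim_fields = set(SimConfig.__dataclass_fields__)
    bad = set(config.get("sim", {})) - sim_fields
    if bad:
        raise InvalidConfigError(f"unknown sim keys: {sorted(bad)}")
    for section, allowed in _KNOWN_KEYS.items():
        bad = set(config.get(section, {})) - allowed
        if bad:
            raise InvalidConfigError(f"unknown {section} keys: {sorted(bad)}")
    return config


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute simulate -> analyze stages per config; returns the report.

    Stages: sliding-track simulation and MSD diffusion estimation with a
    pooled displacement-Gaussian check; a lesion-search experiment with
    mode fractions (binomial sd), bypass-based recognition efficiency and
    naive + censored-MLE residence times; a curtain snapshot with histogram
    peak fit and lesion enrichment; and a titration with a depletion-model
    Kd fit. A resolved-config snapshot and the JSON report are written to
    ``out_dir`` when given.
    """
    config = validate_config(dict(config))
    seed = int(config.get("seed", 0))
    sim_over = dict(config.get("sim", {}))
    report: dict = {"schema_version": SCHEMA_VERSION, "seed": seed}

    stage = "sliding"
    try:
        n_tracks = int(config.get("sliding", {}).get("n_tracks", 50))
        cfg = SimConfig(rng_seed=seed, **sim_over)
        tracks = [
            synthetic.simulate_sliding_trajectory(cfg, track_id=f"slide-{i}")
            for i in range(n_tracks)
        ]
        est = diffusion.MSDDiffusionEstimator(random_state=seed).fit(tracks)
        center, sigma, r2 = diffusion.displacement_gaussian(tracks)
        report["diffusion"] = {
            "D_um2_s": est.D_um2_s_,
            "se_um2_s": est.se_um2_s_,
            "intercept_kbp2": est.intercept_kbp2_,
            "n_tracks": est.n_tracks_,
            "displacement_center_kbp": center,
            "displacement_sigma_kbp": sigma,
            "displacement_fit_r2": r2,
        }

        stage = "search"
        n_mol = int(config.get("search", {}).get("n_molecules", 100))
        search_mode = config.get("search", {}).get("mode", "fast")
        search_cfg = cfg.with_(
            rng_seed=seed + 1,
            n_frames=int(cfg.observation_window_s / cfg.frame_interval_s),
        )
        pairs = synthetic.simulate_search_experiment(search_cfg, n_mol, mode=search_mode)
        events = [e for _, e in pairs]
        engaged = [e for e in events if e.mode != "none"]
        n_direct = sum(e.mode == "direct" for e in engaged)
        frac = lesion_search.fraction_with_sd(n_direct, max(len(engaged), 1))
        eff = lesion_search.recognition_efficiency(events)
        tau_naive = lesion_search.fit_residence_time(
            events, search_cfg.observation_window_s, "naive"
        )
        tau_mle = lesion_search.fit_residence_time(
            events, search_cfg.observation_window_s, "mle"
        )
        report["search"] = {
            "n_molecules": n_mol,
            "fraction_direct": frac.p_hat,
            "fraction_direct_sd": frac.sd_binomial,
            "efficiency_percent": eff.efficiency_percent,
            "bypass_histogram": {str(k): v for k, v in eff.bypass_histogram.items()},
            "tau_naive_s": tau_naive[0],
            "tau_naive_se_s": tau_naive[1],
            "tau_mle_s": tau_mle[0],
            "tau_mle_se_s": tau_mle[1],
        }

        stage = "curtain"
        n_events = int(config.get("curtain", {}).get("n_events", 300))
        spec_frac = float(config.get("curtain", {}).get("specific_fraction", 0.6))
        snap = synthetic.simulate_curtain_snapshot(
            cfg.with_(rng_seed=seed + 2), n_events, spec_frac
        )
        hist = position_stats.build_histogram(
            snap.positions_kbp, L=snap.dna_length_kbp, seed=seed
        )
        peak = position_stats.fit_peak(hist)
        report["positions"] = {
            "n_events": n_events,
            "peak_center_kbp": peak.center_kbp,
            "peak_sigma_kbp": peak.sigma_kbp,
            "peak_center_se": peak.center_se,
            "enrichment_fold": position_stats.lesion_enrichment(
                snap.positions_kbp, L=snap.dna_length_kbp
            ),
        }

        stage = "titration"
        tit = config.get("titration", {})
        ladder = tit.get("ladder_nM", [0, 3, 5, 10, 15, 20, 30, 50])
        dna_total = float(tit.get("dna_total_nM", 4.0))
        noise_sd = float(tit.get("noise_sd", 0.05))
        params = EquilibriumParams()
        series = synthetic.simulate_titration(
            params,
            ladder,
            dna_total,
            noise_sd=noise_sd,
            seed=seed + 3,
            protein=tit.get("protein", "U"),
            substrate=tit.get("substrate", "cpd"),
        )
        kd, kd_se = equilibria.fit_kd(series)
        report["titration"] = {"kd_nM": kd, "kd_se_nM": kd_se,
                               "dna_total_nM": dna_total}
    except Exception as exc:
        exc.add_note(f"pipeline stage: {stage}")
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.partial.json").write_text(json.dumps(report, indent=2))
        raise

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "config.resolved.json").write_text(json.dumps(config, indent=2))
    return report
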