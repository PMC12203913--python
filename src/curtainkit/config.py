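"""Core domain types and the seed-splitting scheme.

Canonical units throughout the package: positions in kbp measured from the
barrier-tethered DNA end (0-based), times in seconds, concentrations in nM,
diffusion coefficients in um^2/s with conversion to kbp^2/s through the
flow-stretch extension factor (um of stretched DNA per kbp of contour).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: Lambda-phage genome length in bp (standard lambda cI857ind1 Sam7 genome).
LAMBDA_BP = 48_502

#: Triple-CPD lesion cassette coordinates on the lambda construct, bp.
LESION_INTERVAL_BP = (33_513, 33_630)

#: Flow-stretched extension, um of apparent length per kbp of contour
#: (~80% of the 0.34 nm/bp B-form contour).
EXTENSION_UM_PER_KBP = 0.272


class InvalidConfigError(ValueError):
    """Raised when a simulation or run configuration violates an invariant."""


class InsufficientDataError(ValueError):
    """Raised when an analysis is handed fewer observations than it needs."""


def substream(seed: int, *labels) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from one master seed.

    Every source of randomness in the package draws from a stream obtained
    here. Streams are keyed by string/int labels, so adding a stage never
    perturbs the draws of another. Implemented by hashing the labels into a
    ``spawn_key`` for :class:`numpy.random.SeedSequence`.
    """
    digest = hashlib.sha256("/".join(map(str, labels)).encode()).digest()
    key = tuple(int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass
class SimConfig:
    """Physical and acquisition parameters of a simulated curtain experiment.

    Defaults reproduce the experimental regime of the lambda-DNA curtain
    assays: 48,502 bp DNA carrying a 3xCPD cassette at 33,513-33,630 bp,
    ~1 kbp/pixel imaging resolution (localization sigma defaults to half a
    pixel), a 600 s observation window, and a sliding diffusion coefficient
    of 0.025 um^2/s.
    """

    dna_length_bp: int = LAMBDA_BP
    lesion_interval_bp: tuple[int, int] = LESION_INTERVAL_BP
    extension_um_per_kbp: float = EXTENSION_UM_PER_KBP
    frame_interval_s: float = 0.1
    n_frames: int = 300
    localization_sigma_kbp: float = 0.5
    diffusion_um2_s: float = 0.025
    capture_prob_per_pass: float = 0.885
    direct_binding_prob: float = 0.19
    mean_dwell_s: float = 900.0
    observation_window_s: float = 600.0
    salt_mM: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_interval_bp
        if not (0 <= lo < hi <= self.dna_length_bp):
            raise InvalidConfigError(
                f"lesion interval {self.lesion_interval_bp} outside "
                f"[0, {self.dna_length_bp}]"
            )
        if self.frame_interval_s <= 0:
            raise InvalidConfigError("frame_interval_s must be positive")
        if self.n_frames < 1:
            raise InvalidConfigError("n_frames must be >= 1")
        if self.diffusion_um2_s < 0:
            raise InvalidConfigError("diffusion coefficient must be >= 0")
        if not 0.0 <= self.capture_prob_per_pass <= 1.0:
            raise InvalidConfigError("capture_prob_per_pass must be in [0, 1]")
        if not 0.0 <= self.direct_binding_prob <= 1.0:
            raise InvalidConfigError("direct_binding_prob must be in [0, 1]")
        for name in ("localization_sigma_kbp", "mean_dwell_s",
                     "observation_window_s", "extension_um_per_kbp"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")

    @property
    def dna_length_kbp(self) -> float:
        return self.dna_length_bp / 1000.0

    @property
    def lesion_interval_kbp(self) -> tuple[float, float]:
        lo, hi = self.lesion_interval_bp
        return lo / 1000.0, hi / 1000.0

    @property
    def diffusion_kbp2_s(self) -> float:
        """D converted to sequence units: D_kbp2 = D_um2 / extension^2."""
        return self.diffusion_um2_s / self.extension_um_per_kbp**2

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """One particle's time-ordered positions along a single DNA molecule."""

    track_id: str
    times_s: np.ndarray
    positions_kbp: np.ndarray
    sigma_loc_kbp: float = 0.5
    salt_mM: float = 0.0
    censored_end: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_kbp = np.asarray(self.positions_kbp, dtype=float)
        if self.times_s.shape != self.positions_kbp.shape:
            raise InvalidConfigError("times and positions must align")
        if self.times_s.size >= 2:
            dt = np.diff(self.times_s)
            if np.any(dt <= 0):
                raise InvalidConfigError(
                    f"track {self.track_id}: times must be strictly increasing"
                )
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InvalidConfigError(
                    f"track {self.track_id}: frame spacing must be uniform"
                )

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def frame_interval_s(self) -> float:
        if len(self) < 2:
            raise InvalidConfigError("frame interval undefined for <2 frames")
        return float(self.times_s[1] - self.times_s[0])

    def displacements(self, lag: int = 1) -> np.ndarray:
        return self.positions_kbp[lag:] - self.positions_kbp[:-lag]


@dataclass
class DwellEvent:
    """A lesion-engagement record for one molecule.

    ``mode`` is how the molecule engaged the lesion: ``direct`` (3D collision,
    already arrested on appearance), ``diffusion`` (arrived by 1D sliding),
    or ``none`` (never arrested within the window). ``bypass_count`` is the
    number of enter-exit transits of the lesion window before arrest.
    """

    track_id: str
    mode: str
    bypass_count: int
    dwell_s: float
    censored: bool
    arrival_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "diffusion", "none"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.bypass_count < 0:
            raise InvalidConfigError("bypass_count must be >= 0")
        if self.mode == "direct" and self.bypass_count != 0:
            raise InvalidConfigError("direct events cannot have bypasses")


@dataclass
class TitrationSeries:
    """An EMSA-style titration: a protein ladder with per-lane band fractions.

    ``band_fractions`` maps a species label (``free``, ``1x``, ``2x``,
    ``cobind``, ``partner``) to a fraction-per-lane array; fractions in each
    lane sum to 1.
    """

    protein_concs_nM: np.ndarray
    dna_total_nM: float
    band_fractions: dict[str, np.ndarray]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.protein_concs_nM = np.asarray(self.protein_concs_nM, dtype=float)
        if np.any(self.protein_concs_nM < 0):
            raise InvalidConfigError("protein concentrations must be >= 0")
        if self.dna_total_nM <= 0:
            raise InvalidConfigError("dna_total_nM must be positive")
        self.band_fractions = {
            k: np.asarray(v, dtype=float) for k, v in self.band_fractions.items()
        }
        totals = sum(self.band_fractions.values())
        if not np.allclose(totals, 1.0, atol=1e-6):
            raise InvalidConfigError("per-lane band fractions must sum to 1")

    @property
    def bound_fraction(self) -> np.ndarray:
        """Total bound fraction per lane (everything except free DNA)."""
        return 1.0 - self.band_fractions["free"]


@dataclass
class EquilibriumParams:
    """Dissociation constants of the UV-DDB (U) / XPC-RAD23B (X) system, nM.

    Single-protein DNA affinities default to the EMSA-derived hierarchy:
    U binds CPD DNA ~5x tighter than undamaged (5 vs 26 nM) while X barely
    discriminates (7 vs 9 nM). ``kd_UX_protein_nM`` is the protein-protein
    complex Kd (experimentally only bounded as tight; default 1 nM).
    ``kd_UXdna_policy`` sets the DNA affinity of the UX complex: the string
    ``"tighter"`` (use the tighter subunit's Kd for that substrate) or a
    numeric Kd in nM. ``kd_U2_nM`` optionally enables a second UV-DDB binding
    to protein-bound DNA (the 2x band); None disables it.
    """

    kd_U_cpd_nM: float = 5.0
    kd_U_und_nM: float = 26.0
    kd_X_cpd_nM: float = 7.0
    kd_X_und_nM: float = 9.0
    kd_UX_protein_nM: float = 1.0
    kd_UXdna_policy: object = "tighter"
    kd_U2_nM: float | None = None
    totals: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("kd_U_cpd_nM", "kd_U_und_nM", "kd_X_cpd_nM",
                     "kd_X_und_nM", "kd_UX_protein_nM"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.kd_U2_nM is not None and self.kd_U2_nM <= 0:
            raise InvalidConfigError("kd_U2_nM must be positive")
        if any(v < 0 for v in self.totals.values()):
            raise InvalidConfigError("totals must be >= 0")

    def kd_U(self, substrate: str) -> float:
        return {"cpd": self.kd_U_cpd_nM, "undamaged": self.kd_U_und_nM}[substrate]

    def kd_X(self, substrate: str) -> float:
        return {"cpd": self.kd_X_cpd_nM, "undamaged": self.kd_X_und_nM}[substrate]

    def kd_UXdna(self, substrate: str) -> float:
        if self.kd_UXdna_policy == "tighter":
            return min(self.kd_U(substrate), self.kd_X(substrate))
        return float(self.kd_UXdna_policy)


@dataclass
class FrapTrace:
    """A normalized FRAP time course; intensity 1 before the bleach."""

    times_s: np.ndarray
    intensity_norm: np.ndarray
    bleach_time_s: float = 0.0
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensity_norm = np.asarray(self.intensity_norm, dtype=float)
        if self.times_s.shape != self.intensity_norm.shape:
            raise InvalidConfigError("times and intensities must align")
        if np.any(self.intensity_norm < 0):
            raise InvalidConfigError("normalized intensities must be >= 0")
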