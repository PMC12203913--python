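"""Protein-DNA binding equilibria: depletion isotherms, EMSA/SPR fitting,
and the coupled UV-DDB (U) / XPC-RAD23B (X) mass-balance model.

DNA concentrations in these assays (4-10 nM) are comparable to the
dissociation constants, so free ligand cannot be approximated by total
ligand: all fitting uses the exact single-site solution with ligand
depletion (a quadratic in the complex concentration), never a
Hill/Langmuir approximation. The coupled model formalizes the hypothesis
that the solution complex of the two proteins (UX) loads UV-DDB onto DNA
through the tighter DNA affinity of its XPC-RAD23B subunit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .config import EquilibriumParams, InsufficientDataError, InvalidConfigError


class SolverError(RuntimeError):
    """Mass-balance solver failed to converge; carries the residual."""


class NonIdentifiableError(ValueError):
    """Titration data cannot constrain the dissociation constant."""


def bound_fraction(p_tot_nM, d_tot_nM: float, kd_nM: float):
    """Exact bound DNA fraction for single-site binding with ligand depletion.

    Solves P + D <-> PD exactly: the complex concentration is
    ``C = (S - sqrt(S^2 - 4*P*D)) / 2`` with ``S = P + D + Kd``; returns
    ``C / D``. Vectorized over the protein concentration.
    """
    p = np.asarray(p_tot_nM, dtype=float)
    if np.any(p < 0):
        raise InvalidConfigError("protein concentration must be >= 0")
    if kd_nM <= 0:
        raise InvalidConfigError("Kd must be positive")
    if d_tot_nM <= 0:
        raise InvalidConfigError("undefined bound fraction at zero DNA")
    s = p + d_tot_nM + kd_nM
    c = 0.5 * (s - np.sqrt(s * s - 4.0 * p * d_tot_nM))
    out = c / d_tot_nM
    return float(out) if np.isscalar(p_tot_nM) else out


@dataclass
class SpeciesState:
    """Converged free and bound concentrations (nM) of the coupled system."""

    U: float
    X: float
    D: float
    UX: float
    UD: float
    XD: float
    UXD: float
    U2D: float
    residual: float

    @property
    def dna_bound_U(self) -> float:
        """Total DNA-associated UV-DDB (counts both copies in U2D)."""
        return self.UD + self.UXD + 2.0 * self.U2D

    @property
    def dna_bound_X(self) -> float:
        return self.XD + self.UXD


def solve_ux(params: EquilibriumParams, substrate: str = "cpd") -> SpeciesState:
    """Solve the coupled mass-action system for free/bound concentrations.

    Reactions (all Kd in nM): U + X <-> UX; U + D <-> UD; X + D <-> XD;
    UX + D <-> UXD; and optionally UD + U <-> U2D when ``kd_U2_nM`` is set.
    Totals are taken from ``params.totals`` (keys ``U``, ``X``, ``D``).
    Solved by trust-region least squares on log free concentrations;
    converged mass-balance residual < 1e-9 relative.
    """
    if substrate not in ("cpd", "undamaged"):
        raise InvalidConfigError(f"unknown substrate {substrate!r}")
    u_tot = float(params.totals.get("U", 0.0))
    x_tot = float(params.totals.get("X", 0.0))
    d_tot = float(params.totals.get("D", 0.0))
    k_ud = params.kd_U(substrate)
    k_xd = params.kd_X(substrate)
    k_ux = params.kd_UX_protein_nM
    k_uxd = params.kd_UXdna(substrate)
    k_u2 = params.kd_U2_nM

    names = [n for n, t in (("U", u_tot), ("X", x_tot), ("D", d_tot)) if t > 0]
    totals = {"U": u_tot, "X": x_tot, "D": d_tot}

    def species(free: dict[str, float]):
        u, x, d = free.get("U", 0.0), free.get("X", 0.0), free.get("D", 0.0)
        ux = u * x / k_ux
        ud = u * d / k_ud
        xd = x * d / k_xd
        uxd = ux * d / k_uxd
        u2d = (ud * u / k_u2) if k_u2 else 0.0
        return ux, ud, xd, uxd, u2d

    def balances(free: dict[str, float]):
        u, x, d = free.get("U", 0.0), free.get("X", 0.0), free.get("D", 0.0)
        ux, ud, xd, uxd, u2d = species(free)
        return {
            "U": u + ux + ud + uxd + 2.0 * u2d,
            "X": x + ux + xd + uxd,
            "D": d + ud + xd + uxd + u2d,
        }

    if not names:
        return SpeciesState(0, 0, 0, 0, 0, 0, 0, 0, 0.0)

    def residuals(logfree: np.ndarray) -> np.ndarray:
        free = {n: np.exp(v) for n, v in zip(names, logfree)}
        bal = balances(free)
        return np.array([(bal[n] - totals[n]) / totals[n] for n in names])

    x0 = np.log([0.5 * totals[n] for n in names])
    sol = optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=20_000,
    )
    resid = float(np.max(np.abs(residuals(sol.x))))
    if resid > 1e-9:
        # retry from a more depleted start before giving up
        sol = optimize.least_squares(
            residuals, x0 - 5.0, method="lm", xtol=1e-15, ftol=1e-15,
            gtol=1e-15, max_nfev=50_000,
        )
        resid = float(np.max(np.abs(residuals(sol.x))))
        if resid > 1e-9:
            raise SolverError(f"mass balance did not converge (residual {resid:.3e})")
    free = {n: float(np.exp(v)) for n, v in zip(names, sol.x)}
    ux, ud, xd, uxd, u2d = species(free)
    return SpeciesState(
        U=free.get("U", 0.0),
        X=free.get("X", 0.0),
        D=free.get("D", 0.0),
        UX=ux,
        UD=ud,
        XD=xd,
        UXD=uxd,
        U2D=u2d,
        residual=resid,
    )


def enhancement_fold(
    params: EquilibriumParams, substrate: str = "cpd"
) -> tuple[float, float]:
    """Fold change in DNA-associated protein caused by its partner.

    Returns ``(fold_U, fold_X)``: DNA-bound U with X present divided by
    DNA-bound U with X absent (all else equal), and the symmetric quantity
    for X. In the verbal model the asymmetry — fold_U > 1 while
    fold_X ~ 1 — encodes that X loads U onto DNA but U does not load X.
    """
    with_both = solve_ux(params, substrate)
    totals = dict(params.totals)

    def _without(key: str) -> SpeciesState:
        t = dict(totals)
        t[key] = 0.0
        p = EquilibriumParams(
            kd_U_cpd_nM=params.kd_U_cpd_nM,
            kd_U_und_nM=params.kd_U_und_nM,
            kd_X_cpd_nM=params.kd_X_cpd_nM,
            kd_X_und_nM=params.kd_X_und_nM,
            kd_UX_protein_nM=params.kd_UX_protein_nM,
            kd_UXdna_policy=params.kd_UXdna_policy,
            kd_U2_nM=params.kd_U2_nM,
            totals=t,
        )
        return solve_ux(p, substrate)

    no_x = _without("X")
    no_u = _without("U")
    fold_u = with_both.dna_bound_U / no_x.dna_bound_U if no_x.dna_bound_U > 0 else np.inf
    fold_x = with_both.dna_bound_X / no_u.dna_bound_X if no_u.dna_bound_X > 0 else np.inf
    return float(fold_u), float(fold_x)


class KdFitter(BaseEstimator):
    """Depletion-corrected single-site Kd fit to a bound-fraction titration.

    Least-squares fit of :func:`bound_fraction` over a protein ladder at
    known total DNA concentration. scikit-learn estimator interface:
    ``fit(concs_nM, bound_fracs)`` sets ``kd_nM_`` and ``kd_se_nM_``.

    Parameters
    ----------
    dna_total_nM : float
        Total DNA concentration in the binding reactions.
    """

    def __init__(self, dna_total_nM: float = 4.0):
        self.dna_total_nM = dna_total_nM

    def fit(self, X, y=None):
        concs = np.asarray(X, dtype=float).ravel()
        frac = np.asarray(y, dtype=float).ravel()
        if concs.size != frac.size:
            raise InvalidConfigError("ladder and fractions must align")
        if concs.size < 4:
            raise InsufficientDataError("need >= 4 titration points")
        span = frac.max() - frac.min()
        if span < 0.1:
            raise NonIdentifiableError(
                "titration is flat (span %.3f); Kd not identifiable" % span
            )

        def model(c, kd):
            return bound_fraction(c, self.dna_total_nM, kd)

        # half-saturation heuristic start
        half = 0.5 * (frac.max() + frac.min())
        k0 = float(np.interp(half, frac, concs, left=concs[concs > 0].min(), right=concs.max()))
        popt, pcov = optimize.curve_fit(
            model, concs, frac, p0=[max(k0, 1e-3)], bounds=(1e-9, np.inf), maxfev=10_000
        )
        self.kd_nM_ = float(popt[0])
        self.kd_se_nM_ = float(np.sqrt(pcov[0, 0]))
        self.n_points_ = int(concs.size)
        return self

    def predict(self, X):
        return bound_fraction(np.asarray(X, dtype=float), self.dna_total_nM, self.kd_nM_)


def fit_kd(series) -> tuple[float, float]:
    """Fit the dissociation constant from a :class:`TitrationSeries`.

    Returns ``(kd_nM, se_nM)``; the bound fraction per lane is everything
    that is not free DNA.
    """
    est = KdFitter(dna_total_nM=series.dna_total_nM).fit(
        series.protein_concs_nM, series.bound_fraction
    )
    return est.kd_nM_, est.kd_se_nM_


class SprSteadyStateFitter(BaseEstimator):
    """Steady-state affinity fit to SPR response-vs-concentration data.

    Fits ``RU(C) = RU_max * C / (Kd + C)`` (free analyte is in excess in the
    flow cell, so no depletion correction applies). Sets ``kd_nM_``,
    ``ru_max_`` and their standard errors; warns if the ladder does not
    approach saturation.
    """

    def fit(self, X, y=None):
        concs = np.asarray(X, dtype=float).ravel()
        ru = np.asarray(y, dtype=float).ravel()
        if concs.size < 4:
            raise InsufficientDataError("need >= 4 concentrations")

        def model(c, kd, rmax):
            return rmax * c / (kd + c)

        popt, pcov = optimize.curve_fit(
            model, concs, ru, p0=[np.median(concs[concs > 0]), ru.max() * 1.5],
            bounds=(1e-9, np.inf), maxfev=10_000,
        )
        self.kd_nM_, self.ru_max_ = map(float, popt)
        se = np.sqrt(np.diag(pcov))
        self.kd_se_nM_, self.ru_max_se_ = map(float, se)
        if concs.max() < 2.0 * self.kd_nM_:
            warnings.warn(
                "SPR ladder does not reach 2x Kd; affinity poorly constrained",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def predict(self, X):
        c = np.asarray(X, dtype=float)
        return self.ru_max_ * c / (self.kd_nM_ + c)


def spr_steady_state(conc_nM, ru) -> tuple[float, float]:
    """Fit the SPR steady-state isotherm; returns ``(kd_nM, ru_max)``."""
    est = SprSteadyStateFitter().fit(conc_nM, ru)
    return est.kd_nM_, est.ru_max_
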