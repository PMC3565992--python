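"""Protein signaling functions: steady-state input -> output transfer curves.

A psf maps the *total* concentration of a source (input) species to the
settled concentration of a target species.  In isolation every binding or
(reversible) enzymatic reaction yields a saturating hyperbola in the source
total; embedded in a full system the curve is reshaped by competing reactions
("systemic psf") and is fitted with either the four-parameter hyperbola

    y(x) = y0 + Y * x^n / (C^n + x^n)

or, where the sampled range only covers a short section of the full mapping,
a straight line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import RateConstants, ReactionSystem, SchemeKind
from . import fixtures
from .steady import SteadyStateCriterion, settle

__all__ = [
    "PsfCurve",
    "PsfMatrix",
    "HyperbolicFit",
    "LinearFit",
    "AdjustResult",
    "make_grid",
    "elementary_binding_psf",
    "elementary_enzymatic_psf",
    "systemic_psf",
    "psf_matrix",
    "fit_psf",
    "transmission_strength",
    "adjust_elementary_to_match",
]


def make_grid(lo: float, hi: float, n: int = 20, spacing: str = "log") -> np.ndarray:
    """Input-total grid; logarithmic by default so the low end of a
    hyperbola is resolved."""
    if lo <= 0 and spacing == "log":
        raise ValueError("log spacing requires lo > 0")
    if hi <= lo:
        raise ValueError("grid needs hi > lo")
    if n < 2:
        raise ValueError("grid needs n >= 2")
    if spacing == "log":
        return np.geomspace(lo, hi, n)
    if spacing == "linear":
        return np.linspace(lo, hi, n)
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass
class PsfCurve:
    """Sampled psf: target steady-state value (nM) per source total (nM)."""

    source: str
    target: str
    grid: np.ndarray
    values: np.ndarray
    delays: np.ndarray | None = None        # per-point settle times, s
    converged: np.ndarray | None = None     # per-point convergence flags

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1-D and equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values.min()), float(self.values.max())

    @property
    def span(self) -> float:
        return float(self.values.max() - self.values.min())

    def interp(self, x, log_x: bool | None = None) -> np.ndarray:
        """Value at arbitrary source totals; linear in log-x when the grid is
        (geometrically) log-spaced, linear otherwise."""
        if log_x is None:
            ratios = np.diff(np.log(self.grid)) if np.all(self.grid > 0) else None
            log_x = ratios is not None and np.allclose(ratios, ratios[0], rtol=1e-6)
        x = np.asarray(x, dtype=float)
        if log_x:
            return np.interp(np.log(np.maximum(x, self.grid[0] * 1e-12)),
                             np.log(self.grid), self.values)
        return np.interp(x, self.grid, self.values)

    def to_frame(self) -> pd.DataFrame:
        d = {"input": self.source, "input_total_nM": self.grid,
             "target": self.target, "value_nM": self.values}
        if self.delays is not None:
            d["settle_time_s"] = self.delays
        return pd.DataFrame(d)


@dataclass
class PsfMatrix:
    """Two-input psf: target steady state on grid1 x grid2."""

    inputs: tuple[str, str]
    grids: tuple[np.ndarray, np.ndarray]
    target: str
    values: np.ndarray        # shape (len(grid1), len(grid2))

    def __post_init__(self) -> None:
        g1, g2 = (np.asarray(g, dtype=float) for g in self.grids)
        self.grids = (g1, g2)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(g1), len(g2)):
            raise ValueError("values shape must match the two grids")

    def dependence_shares(self) -> dict[str, float]:
        """Fraction of grid variance explained by each input alone.

        Main-effect decomposition: the share of input i is the variance of
        the target averaged over the other axis, normalized by the total
        variance over the grid.  A flat matrix has both shares 0.
        """
        total = float(np.var(self.values))
        if total <= 0:
            return {self.inputs[0]: 0.0, self.inputs[1]: 0.0}
        v1 = float(np.var(self.values.mean(axis=1)))
        v2 = float(np.var(self.values.mean(axis=0)))
        return {self.inputs[0]: v1 / total, self.inputs[1]: v2 / total}

    def interp(self, x1: float, x2: float) -> float:
        """Bilinear interpolation (in log-input where grids are log-spaced)."""
        def axis(g, x):
            lg = np.all(g > 0) and np.allclose(
                np.diff(np.log(g)), np.diff(np.log(g))[0], rtol=1e-6)
            gx, xx = (np.log(g), np.log(max(x, g[0] * 1e-12))) if lg else (g, x)
            j = int(np.clip(np.searchsorted(gx, xx) - 1, 0, len(g) - 2))
            w = (xx - gx[j]) / (gx[j + 1] - gx[j])
            return j, float(np.clip(w, 0.0, 1.0))

        i, wi = axis(self.grids[0], x1)
        j, wj = axis(self.grids[1], x2)
        v = self.values
        return float((1 - wi) * (1 - wj) * v[i, j] + wi * (1 - wj) * v[i + 1, j]
                     + (1 - wi) * wj * v[i, j + 1] + wi * wj * v[i + 1, j + 1])

    def to_frame(self) -> pd.DataFrame:
        g1, g2 = self.grids
        ii, jj = np.meshgrid(np.arange(len(g1)), np.arange(len(g2)), indexing="ij")
        return pd.DataFrame({
            f"{self.inputs[0]}_total_nM": g1[ii.ravel()],
            f"{self.inputs[1]}_total_nM": g2[jj.ravel()],
            "target": self.target,
            "value_nM": self.values.ravel(),
        })


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperbolicFit:
    """Saturating hyperbola y0 + Y x^n / (C^n + x^n); Y < 0 for falling psfs."""

    Y: float
    C: float
    n: float
    y0: float
    sse: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xn = np.where(x > 0, x, 0.0) ** self.n
        return self.y0 + self.Y * xn / (self.C ** self.n + xn)

    def slope(self, x) -> np.ndarray:
        """Analytic derivative dy/dx."""
        x = np.asarray(x, dtype=float)
        cn = self.C ** self.n
        xn = np.where(x > 0, x, 0.0) ** self.n
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.Y * self.n * cn * xn / x / (cn + xn) ** 2
        if self.n == 1:
            out = np.where(x == 0, self.Y / self.C, out)
        return out

    @property
    def model(self) -> str:
        return "hyperbolic"

    def params(self) -> dict[str, float]:
        return {"Y": self.Y, "C": self.C, "n": self.n, "y0": self.y0}


@dataclass(frozen=True)
class LinearFit:
    slope_: float
    intercept: float
    sse: float

    def predict(self, x) -> np.ndarray:
        return self.slope_ * np.asarray(x, dtype=float) + self.intercept

    def slope(self, x) -> np.ndarray:
        return np.full_like(np.asarray(x, dtype=float), self.slope_)

    @property
    def model(self) -> str:
        return "linear"

    def params(self) -> dict[str, float]:
        return {"slope": self.slope_, "intercept": self.intercept}


def _hyperbolic_sse(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    Y, logC, logn, y0 = theta
    C, n = np.exp(logC), np.exp(logn)
    if n > 50:  # runaway steepness: treat as invalid
        return 1e300
    with np.errstate(over="ignore"):
        xn = x ** n
        pred = y0 + Y * xn / (C ** n + xn)
    r = pred - y
    return float(r @ r)


def fit_psf(
    curve: PsfCurve,
    init: Mapping[str, float] | None = None,
    linear_C_factor: float = 10.0,
) -> HyperbolicFit | LinearFit:
    """Fit a psf with the saturating hyperbola, falling back to a line.

    Derivative-free (Nelder–Mead) minimization of the summed squared error
    over (Y, log C, log n, y0).  The linear fit is selected when it matches
    at least as well, or when the fitted C lies more than ``linear_C_factor``
    beyond the sampled grid — the curve is then only a short section of the
    full mapping and the hyperbolic parameters are not identified.
    """
    x, y = curve.grid, curve.values
    if len(x) < 4:
        raise ValueError("fit needs at least 4 grid points")

    # linear candidate (exact least squares)
    slope, intercept = np.polyfit(x, y, 1)
    lin_res = y - (slope * x + intercept)
    lin = LinearFit(float(slope), float(intercept), float(lin_res @ lin_res))

    if np.allclose(y, y[0]):
        return LinearFit(0.0, float(y[0]), float(np.sum((y - y[0]) ** 2)))

    rising = y[-1] >= y[0]
    if init is not None:
        th0 = np.array([
            init.get("Y", y.max() - y.min()),
            np.log(init.get("C", np.median(x))),
            np.log(init.get("n", 1.0)),
            init.get("y0", y.min()),
        ])
    else:
        if rising:
            y0_0, Y0 = float(y.min()), float(y.max() - y.min())
        else:
            y0_0, Y0 = float(y.max()), -float(y.max() - y.min())
        half = y0_0 + Y0 / 2.0
        C0 = float(x[np.argmin(np.abs(y - half))])
        C0 = max(C0, x[0] * 1e-3)
        th0 = np.array([Y0, np.log(C0), 0.0, y0_0])

    best = None
    for start in (th0, None):
        if start is None:
            if best is None:
                break
            start = best.x  # polish from the first solution
        res = minimize(
            _hyperbolic_sse, start, args=(x, y), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    Y, logC, logn, y0 = best.x
    hyp = HyperbolicFit(float(Y), float(np.exp(logC)), float(np.exp(logn)),
                        float(y0), float(best.fun))

    if lin.sse <= hyp.sse or hyp.C > linear_C_factor * x[-1]:
        return lin
    return hyp


def transmission_strength(
    fit_or_curve: HyperbolicFit | LinearFit | PsfCurve,
    x: float,
    factor: float = 2.0,
) -> dict[str, float | None]:
    """Local signal transmission: slope at x, and the fractional output change
    produced by multiplying the input by ``factor``.

    The relative gain is undefined (``None``) where the output is zero.
    """
    if isinstance(fit_or_curve, PsfCurve):
        c = fit_or_curve
        h = x * 1e-4 if x > 0 else (c.grid[1] - c.grid[0]) * 1e-4
        slope = float((c.interp(x + h) - c.interp(max(x - h, 0.0))) /
                      (x + h - max(x - h, 0.0)))
        y_x = float(c.interp(x))
        y_fx = float(c.interp(factor * x))
    else:
        slope = float(fit_or_curve.slope(x))
        y_x = float(fit_or_curve.predict(x))
        y_fx = float(fit_or_curve.predict(factor * x))
    gain = None if y_x == 0 else (y_fx - y_x) / y_x
    return {"slope": slope, "relative_gain": gain}


# ---------------------------------------------------------------------------
# elementary psfs
# ---------------------------------------------------------------------------

def elementary_binding_psf(
    a_total_grid: Sequence[float],
    b_total: float,
    kon: float,
    koff: float,
    criterion: SteadyStateCriterion | None = None,
) -> PsfCurve:
    """Steady-state [AB] of an isolated A + B <-> AB as a function of total A.

    Computed by integrating the elementary system to steady state at every
    grid point (the quadratic closed form is used as an independent check in
    the test suite, not here).
    """
    if koff <= 0:
        raise ValueError("koff must be > 0 for a finite binding equilibrium")
    grid = np.asarray(a_total_grid, dtype=float)
    crit = criterion or SteadyStateCriterion()
    values = np.empty_like(grid)
    delays = np.empty_like(grid)
    for i, at in enumerate(grid):
        sys_i = fixtures.toy_binding(a_total=float(at), b_total=b_total,
                                     kon=kon, koff=koff)
        res = settle(sys_i, criterion=crit)
        values[i] = res.concentrations["AB"]
        delays[i] = res.settle_time
    return PsfCurve("A", "AB", grid, values, delays=delays)


def elementary_enzymatic_psf(
    e_total_grid: Sequence[float],
    substrate_total: float,
    forward_rates: RateConstants,
    reverse_rates: RateConstants,
    phosphatase_total: float = 100.0,
    criterion: SteadyStateCriterion | None = None,
) -> PsfCurve:
    """Steady-state product level of a covalent cycle vs forward-enzyme total.

    The forward (kinase) arm converts S to Sp; a reverse (phosphatase) arm
    regenerating the substrate is required — without it the reaction runs to
    completion and the transfer function degenerates.
    """
    for label, r in (("forward", forward_rates), ("reverse", reverse_rates)):
        if r.kon is None or r.koff is None or r.kcat is None:
            raise ValueError(f"{label} rates need kon, koff and kcat")
    if reverse_rates.kcat == 0 or phosphatase_total == 0:
        raise ValueError("a working reverse reaction is required "
                         "(reverse kcat and enzyme total must be > 0)")
    grid = np.asarray(e_total_grid, dtype=float)
    crit = criterion or SteadyStateCriterion()
    values = np.empty_like(grid)
    delays = np.empty_like(grid)
    for i, et in enumerate(grid):
        sys_i = fixtures.toy_covalent_cycle(
            substrate_total=substrate_total, kinase_total=float(et),
            phosphatase_total=phosphatase_total,
            kon_k=forward_rates.kon, koff_k=forward_rates.koff,
            kcat_k=forward_rates.kcat,
            kon_p=reverse_rates.kon, koff_p=reverse_rates.koff,
            kcat_p=reverse_rates.kcat,
        )
        res = settle(sys_i, criterion=crit)
        values[i] = res.concentrations["Sp"]
        delays[i] = res.settle_time
    return PsfCurve("E1", "Sp", grid, values, delays=delays)


# ---------------------------------------------------------------------------
# systemic psfs
# ---------------------------------------------------------------------------

def systemic_psf(
    system: ReactionSystem,
    input_species: str,
    input_range: tuple[float, float],
    n: int = 20,
    targets: Sequence[str] | None = None,
    criterion: SteadyStateCriterion | None = None,
    spacing: str = "log",
    overrides: Mapping[str, float] | None = None,
    record_delays: bool = True,
) -> dict[str, PsfCurve]:
    """Sweep one input's total and settle the whole system at each grid point.

    Each point integrates from the declared initial totals with the input's
    total replaced by the grid value (and any ``overrides`` applied, e.g. a
    fixed level for the other input); curves are returned for every target
    species.  Grid points that fail the steady-state criterion are flagged in
    ``converged`` rather than raising.
    """
    if input_species not in system.inputs:
        raise ValueError(f"{input_species!r} is not declared as an input")
    grid = make_grid(*input_range, n=n, spacing=spacing)
    crit = criterion or SteadyStateCriterion()
    names = list(targets) if targets is not None else list(system.species_names)
    vals = np.empty((len(grid), len(names)))
    delays = np.empty(len(grid))
    conv = np.empty(len(grid), dtype=bool)
    for i, x in enumerate(grid):
        ov = dict(overrides or {})
        ov[input_species] = float(x)
        res = settle(system.with_initial(ov), criterion=crit)
        conv[i] = res.converged
        delays[i] = res.settle_time
        vals[i] = [res.concentrations[t] for t in names]
    return {
        t: PsfCurve(input_species, t, grid, vals[:, j],
                    delays=delays.copy(), converged=conv.copy())
        for j, t in enumerate(names)
    }


def psf_matrix(
    system: ReactionSystem,
    input_pair: tuple[str, str],
    grids: tuple[Sequence[float], Sequence[float]],
    target: str,
    criterion: SteadyStateCriterion | None = None,
    overrides: Mapping[str, float] | None = None,
) -> PsfMatrix:
    """Settle the system over a grid of two input totals."""
    a, b = input_pair
    if a == b:
        raise ValueError("the two inputs must be distinct")
    for name in (a, b):
        if name not in system.inputs:
            raise ValueError(f"{name!r} is not declared as an input")
    g1, g2 = (np.asarray(g, dtype=float) for g in grids)
    crit = criterion or SteadyStateCriterion()
    vals = np.empty((len(g1), len(g2)))
    for i, x1 in enumerate(g1):
        for j, x2 in enumerate(g2):
            ov = dict(overrides or {})
            ov[a], ov[b] = float(x1), float(x2)
            res = settle(system.with_initial(ov), criterion=crit)
            vals[i, j] = res.concentrations[target]
    return PsfMatrix((a, b), (g1, g2), target, vals)


def psf_matrices(
    system: ReactionSystem,
    input_pair: tuple[str, str],
    grids: tuple[Sequence[float], Sequence[float]],
    targets: Sequence[str],
    criterion: SteadyStateCriterion | None = None,
    overrides: Mapping[str, float] | None = None,
) -> dict[str, PsfMatrix]:
    """Like :func:`psf_matrix` for several targets, settling each cell once."""
    a, b = input_pair
    g1, g2 = (np.asarray(g, dtype=float) for g in grids)
    crit = criterion or SteadyStateCriterion()
    vals = {t: np.empty((len(g1), len(g2))) for t in targets}
    for i, x1 in enumerate(g1):
        for j, x2 in enumerate(g2):
            ov = dict(overrides or {})
            ov[a], ov[b] = float(x1), float(x2)
            res = settle(system.with_initial(ov), criterion=crit)
            for t in targets:
                vals[t][i, j] = res.concentrations[t]
    return {t: PsfMatrix((a, b), (g1, g2), t, vals[t]) for t in targets}


# ---------------------------------------------------------------------------
# local parameter adjustment
# ---------------------------------------------------------------------------

@dataclass
class AdjustResult:
    rates: RateConstants
    residual: float
    converged: bool
    n_evaluations: int = 0


def adjust_elementary_to_match(
    system: ReactionSystem,
    scheme_id: int,
    target_fit: HyperbolicFit | LinearFit | PsfCurve,
    free_parameters: Sequence[str],
    input_species: str,
    target: str,
    grid: Sequence[float],
    tolerance: float = 1e-3,
    criterion: SteadyStateCriterion | None = None,
    overrides: Mapping[str, float] | None = None,
    maxiter: int = 60,
) -> AdjustResult:
    """Search elementary rate constants so the *systemic* psf matches a target.

    Derivative-free (Nelder–Mead) search over the logs of the chosen rate
    constants of one scheme, minimizing the mean squared distance between the
    recomputed systemic psf (input -> target on ``grid``) and the target
    fit's predictions.  The relative residual (RMS distance over the target's
    RMS level) is compared against ``tolerance``.
    """
    free = list(free_parameters)
    allowed = {"kon", "koff", "kcat"}
    if not free or not set(free) <= allowed:
        raise ValueError(f"free_parameters must be a nonempty subset of {allowed}")
    scheme = system.scheme(scheme_id)
    for p in free:
        if getattr(scheme.rates, p) in (None, 0):
            raise ValueError(f"scheme {scheme_id} has no adjustable {p}")
    grid = np.asarray(grid, dtype=float)
    if isinstance(target_fit, PsfCurve):
        y_target = target_fit.interp(grid)
    else:
        y_target = target_fit.predict(grid)
    crit = criterion or SteadyStateCriterion()
    scale = float(np.sqrt(np.mean(y_target ** 2))) or 1.0
    n_eval = 0

    def sweep(rates: RateConstants) -> np.ndarray:
        sys_i = system.with_scheme_rates(scheme_id, rates)
        vals = np.empty(len(grid))
        for i, x in enumerate(grid):
            ov = dict(overrides or {})
            ov[input_species] = float(x)
            vals[i] = settle(sys_i.with_initial(ov),
                             criterion=crit).concentrations[target]
        return vals

    def unpack(theta: np.ndarray) -> RateConstants:
        kw = {p: getattr(scheme.rates, p) for p in ("kon", "koff", "kcat")}
        for p, v in zip(free, np.exp(theta)):
            kw[p] = float(v)
        return RateConstants(**kw)

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        r = sweep(unpack(theta)) - y_target
        return float(np.mean(r ** 2))

    theta0 = np.log([getattr(scheme.rates, p) for p in free])
    res = minimize(objective, theta0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-12})
    rates = unpack(res.x)
    rel = float(np.sqrt(res.fun)) / scale
    return AdjustResult(rates=rates, residual=rel,
                        converged=rel <= tolerance, n_evaluations=n_eval)
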