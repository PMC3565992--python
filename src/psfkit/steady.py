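"""Integration to steady state, input steps, and transition delays.

Steady state is defined pragmatically: the system counts as settled once every
species (above a numerical floor) has changed by less than ``rel_change``
relative over a trailing ``window`` seconds.  Rate constants in signaling
models span many orders of magnitude, so all integration goes through a
stiff-capable solver (BDF) with the analytic Jacobian of the mass-action rate
law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import ReactionSystem, RateEvaluator

__all__ = [
    "Trajectory",
    "SteadyStateCriterion",
    "SteadyStateResult",
    "StepTransition",
    "IntegrationError",
    "UndefinedDelay",
    "integrate",
    "settle",
    "apply_input_step",
    "transition_delay",
    "transition_delays",
    "moiety_drift",
]

UNDEFINED_DELAY = None


class IntegrationError(RuntimeError):
    def __init__(self, message: str, time_reached: float):
        super().__init__(f"{message} (time reached: {time_reached:g} s)")
        self.time_reached = time_reached


class UndefinedDelay(ValueError):
    """The species does not change across the transition; no delay is defined."""


@dataclass
class Trajectory:
    """Sampled solution: times (s) and concentrations (nM) per species."""

    times: np.ndarray
    values: np.ndarray          # shape (n_times, n_species)
    species: list[str]

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def state_at(self, index: int) -> dict[str, float]:
        return dict(zip(self.species, self.values[index].tolist()))

    def final_state(self) -> dict[str, float]:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: time_s, species, nM."""
        frames = [
            pd.DataFrame({"time_s": self.times, "species": name,
                          "nM": self.values[:, i]})
            for i, name in enumerate(self.species)
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class SteadyStateCriterion:
    """Settled iff every species above ``floor`` changed < ``rel_change``
    relative over the trailing ``window`` seconds, checked every ``check_dt``."""

    rel_change: float = 0.02
    window: float = 100.0
    floor: float = 1e-6
    max_time: float = 2e5
    check_dt: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.rel_change < 1):
            raise ValueError("rel_change must be in (0, 1)")
        if self.window <= 0 or self.check_dt <= 0:
            raise ValueError("window and check_dt must be > 0")

    def holds(self, now: np.ndarray, past: np.ndarray) -> bool:
        mask = np.abs(now) > self.floor
        if not mask.any():
            return True
        return bool(np.all(
            np.abs(now[mask] - past[mask]) < self.rel_change * np.abs(now[mask])
        ))


@dataclass
class SteadyStateResult:
    concentrations: dict[str, float]
    settle_time: float
    converged: bool
    trajectory: Trajectory | None = None


@dataclass(frozen=True)
class StepTransition:
    """An instantaneous change of one input's total concentration."""

    input_species: str
    total_before: float
    total_after: float

    def __post_init__(self) -> None:
        if self.total_before < 0 or self.total_after < 0:
            raise ValueError("transition totals must be >= 0")


# ---------------------------------------------------------------------------


def _state_vector(system: ReactionSystem, conc: Mapping[str, float]) -> np.ndarray:
    c0 = np.zeros(len(system.species))
    idx = system.species_index()
    for name, v in conc.items():
        if name not in idx:
            raise KeyError(f"unknown species {name!r}")
        if v < 0:
            raise ValueError(f"initial concentration of {name!r} is negative")
        c0[idx[name]] = v
    return c0


def integrate(
    system: ReactionSystem,
    initial_concentrations: Mapping[str, float],
    duration: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: np.ndarray | None = None,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the mass-action ODEs for ``duration`` seconds."""
    ev = RateEvaluator(system.steps, system.species_names)
    c0 = _state_vector(system, initial_concentrations)
    sol = solve_ivp(
        ev, (0.0, duration), c0, method=method, jac=ev.jacobian,
        rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    values = np.maximum(sol.y.T, 0.0)
    return Trajectory(times=sol.t, values=values, species=list(system.species_names))


def settle(
    system: ReactionSystem,
    initial_concentrations: Mapping[str, float] | None = None,
    criterion: SteadyStateCriterion | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    keep_trajectory: bool = False,
) -> SteadyStateResult:
    """Integrate until the steady-state criterion first holds.

    Returns the settled concentrations and the first sample time at which the
    trailing-window check passed; ``converged=False`` with the last state if
    ``criterion.max_time`` is exceeded.
    """
    crit = criterion or SteadyStateCriterion()
    conc = initial_concentrations or system.initial_concentrations()
    ev = RateEvaluator(system.steps, system.species_names)
    c0 = _state_vector(system, conc)

    lag = max(1, int(round(crit.window / crit.check_dt)))
    chunk = max(10.0 * crit.window, 50.0 * crit.check_dt)
    all_t: list[np.ndarray] = [np.array([0.0])]
    all_y: list[np.ndarray] = [c0[None, :]]
    samples: list[np.ndarray] = [c0]
    sample_times: list[float] = [0.0]
    t0 = 0.0
    y0 = c0
    while t0 < crit.max_time:
        t1 = min(t0 + chunk, crit.max_time)
        n = int(round((t1 - t0) / crit.check_dt))
        t_eval = t0 + crit.check_dt * np.arange(1, n + 1)
        t_eval = t_eval[t_eval <= t1 + 1e-9]
        sol = solve_ivp(
            ev, (t0, t1), y0, method="BDF", jac=ev.jacobian,
            rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else t0)
        ys = np.maximum(sol.y.T, 0.0)
        for ti, yi in zip(sol.t, ys):
            samples.append(yi)
            sample_times.append(float(ti))
            if len(samples) > lag and crit.holds(yi, samples[-1 - lag]):
                if keep_trajectory:
                    all_t.append(sol.t[sol.t <= ti + 1e-9])
                    all_y.append(ys[: len(all_t[-1])])
                traj = _assemble(all_t, all_y, system) if keep_trajectory else None
                return SteadyStateResult(
                    concentrations=dict(zip(system.species_names, yi.tolist())),
                    settle_time=float(ti), converged=True, trajectory=traj,
                )
        if keep_trajectory and len(sol.t):
            all_t.append(sol.t)
            all_y.append(ys)
        if len(sol.t):
            t0 = float(sol.t[-1])
            y0 = ys[-1]
        else:
            t0 = t1
    traj = _assemble(all_t, all_y, system) if keep_trajectory else None
    return SteadyStateResult(
        concentrations=dict(zip(system.species_names, y0.tolist())),
        settle_time=t0, converged=False, trajectory=traj,
    )


def _assemble(ts: list[np.ndarray], ys: list[np.ndarray], system: ReactionSystem) -> Trajectory:
    return Trajectory(
        times=np.concatenate(ts), values=np.vstack(ys),
        species=list(system.species_names),
    )


def apply_input_step(
    system: ReactionSystem,
    state: Mapping[str, float],
    transition: StepTransition,
) -> dict[str, float]:
    """Apply an instantaneous change of an input's *total* concentration.

    An increase raises the free input pool by the difference.  A decrease
    drains the free pool first; any remainder is removed proportionally from
    the input-containing complexes (the other members of the input's declared
    moiety), modeling removal of ligand regardless of binding state.
    """
    name = transition.input_species
    new = dict(state)
    delta = transition.total_after - transition.total_before
    if delta >= 0:
        new[name] = new.get(name, 0.0) + delta
        return new
    removal = -delta
    free = new.get(name, 0.0)
    taken = min(free, removal)
    new[name] = free - taken
    removal -= taken
    if removal <= 1e-12:
        return new
    moiety = system.moiety_containing(name)
    if moiety is None:
        raise ValueError(
            f"cannot remove {removal:g} nM of {name!r}: free pool exhausted and "
            "no moiety is declared for it"
        )
    members = [(n, m) for n, m in moiety.members if n != name]
    bound = sum(new.get(n, 0.0) * m for n, m in members)
    if removal > bound + 1e-9:
        raise ValueError(
            f"requested removal of {name!r} exceeds its moiety total "
            f"(need {removal:g} nM more, bound pool holds {bound:g} nM)"
        )
    frac = removal / bound
    for n, _m in members:
        new[n] = new.get(n, 0.0) * (1.0 - frac)
    return new


def _sweep_grid_times(t_end: float, n: int = 1200) -> np.ndarray:
    """Dense scan grid biased to early times (log-spaced) plus a linear tail."""
    t_end = max(t_end, 1.0)
    logs = np.geomspace(1e-3, t_end, n)
    lins = np.linspace(0.0, t_end, n // 2)
    return np.unique(np.concatenate([[0.0], logs, lins]))


def transition_delays(
    system: ReactionSystem,
    transition: StepTransition,
    species: Sequence[str] | None = None,
    fraction: float = 0.95,
    baseline_state: Mapping[str, float] | None = None,
    criterion: SteadyStateCriterion | None = None,
    band: str = "value",
    floor: float = 1e-6,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict[str, float | None]:
    """Times for species to complete ``fraction`` of their transition.

    Equilibrates at the pre-step input total (unless ``baseline_state`` is
    given), applies the step at t=0, integrates well past settling, and for
    each species returns the *last* time its trajectory sits outside a band
    around the new steady state — robust to transients that cross the band
    early.  With ``band="value"`` (default) the half-width is
    (1-fraction)·c_new, i.e. the trajectory has reached EC95 of the new
    steady-state level; with ``band="change"`` it is (1-fraction)·|c_new -
    c_old|.  The two coincide when the species starts from zero.  Species
    whose change is below ``floor`` map to ``None`` (no delay defined).
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if band not in ("value", "change"):
        raise ValueError("band must be 'value' or 'change'")
    crit = criterion or SteadyStateCriterion()
    targets = list(species) if species is not None else list(system.species_names)

    if baseline_state is None:
        base_system = system.with_initial(
            {transition.input_species: transition.total_before})
        base = settle(base_system, criterion=crit, rtol=rtol, atol=atol)
        if not base.converged:
            raise IntegrationError("baseline failed to settle", base.settle_time)
        baseline_state = base.concentrations

    stepped = apply_input_step(system, baseline_state, transition)
    post = settle(system, stepped, criterion=crit, rtol=rtol, atol=atol)
    if not post.converged:
        raise IntegrationError("post-step state failed to settle", post.settle_time)
    # integrate once more with dense output, past the settle time so the
    # asymptote used for the band is accurate
    t_end = max(3.0 * post.settle_time, post.settle_time + 10.0 * crit.window)
    ev = RateEvaluator(system.steps, system.species_names)
    c0 = _state_vector(system, stepped)
    sol = solve_ivp(
        ev, (0.0, t_end), c0, method="BDF", jac=ev.jacobian,
        rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    idx = system.species_index()
    scan_t = _sweep_grid_times(t_end)
    scan_y = np.maximum(sol.sol(scan_t).T, 0.0)
    c_new_vec = np.maximum(sol.y[:, -1], 0.0)

    out: dict[str, float | None] = {}
    for name in targets:
        i = idx[name]
        c_old = baseline_state.get(name, 0.0)
        c_new = float(c_new_vec[i])
        change = c_new - c_old
        if abs(change) < floor:
            out[name] = None
            continue
        if band == "value":
            half_width = (1.0 - fraction) * abs(c_new)
            if half_width < floor:  # species settles at ~0: fall back
                half_width = (1.0 - fraction) * abs(change)
        else:
            half_width = (1.0 - fraction) * abs(change)
        dev = np.abs(scan_y[:, i] - c_new)
        outside = dev > half_width
        if not outside.any():
            out[name] = 0.0
            continue
        j = int(np.flatnonzero(outside)[-1])
        if j + 1 >= len(scan_t):
            # still outside the band at the end of the run: report the horizon
            out[name] = float(scan_t[-1])
            continue
        f = lambda t: abs(float(sol.sol(t)[i]) - c_new) - half_width
        lo, hi = float(scan_t[j]), float(scan_t[j + 1])
        try:
            out[name] = float(brentq(f, lo, hi, xtol=1e-6, rtol=1e-10))
        except ValueError:
            out[name] = hi
    return out


def transition_delay(
    system: ReactionSystem,
    transition: StepTransition,
    species: str,
    fraction: float = 0.95,
    baseline_state: Mapping[str, float] | None = None,
    criterion: SteadyStateCriterion | None = None,
    **kwargs,
) -> float:
    """Single-species version of :func:`transition_delays`; raises
    :class:`UndefinedDelay` when the species does not respond to the step."""
    res = transition_delays(
        system, transition, [species], fraction=fraction,
        baseline_state=baseline_state, criterion=criterion, **kwargs,
    )[species]
    if res is None:
        raise UndefinedDelay(
            f"{species!r} does not change across the transition")
    return res


def delay_table(
    system: ReactionSystem,
    transitions: Sequence[StepTransition],
    species: Sequence[str],
    fraction: float = 0.95,
    criterion: SteadyStateCriterion | None = None,
    band: str = "value",
    **kwargs,
) -> pd.DataFrame:
    """Species x transition table of step-response delays (s).

    Baselines are settled once per distinct pre-step total and reused across
    transitions.  Columns are labeled ``before->after`` in nM.
    """
    baselines: dict[tuple[str, float], Mapping[str, float]] = {}
    cols: dict[str, list[float | None]] = {}
    crit = criterion or SteadyStateCriterion()
    for tr in transitions:
        key = (tr.input_species, tr.total_before)
        if key not in baselines:
            base_system = system.with_initial({tr.input_species: tr.total_before})
            res = settle(base_system, criterion=crit)
            if not res.converged:
                raise IntegrationError("baseline failed to settle", res.settle_time)
            baselines[key] = res.concentrations
        d = transition_delays(
            system, tr, species, fraction=fraction,
            baseline_state=baselines[key], criterion=crit, band=band, **kwargs,
        )
        cols[f"{tr.total_before:g}->{tr.total_after:g}"] = [d[s] for s in species]
    return pd.DataFrame(cols, index=list(species)).rename_axis("species")


def moiety_drift(system: ReactionSystem, trajectory: Trajectory) -> dict[str, float]:
    """Max relative drift of each declared moiety total along a trajectory."""
    out: dict[str, float] = {}
    idx = {n: i for i, n in enumerate(trajectory.species)}
    for m in system.moieties:
        weights = np.zeros(len(trajectory.species))
        for n, mult in m.members:
            if n in idx:
                weights[idx[n]] = mult
        totals = trajectory.values @ weights
        ref = totals[0]
        if ref <= 0:
            out[m.name] = float(np.max(np.abs(totals)))
        else:
            out[m.name] = float(np.max(np.abs(totals - ref)) / ref)
    return out
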