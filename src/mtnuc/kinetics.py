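"""Nucleation kinetics of surface-templated microtubule formation.

A field of surface-attached nucleation templates (γTuRCs) fires at a rate
that decays as templates are consumed.  With ``k`` the initial nucleation
rate (MTs/s) and ``N_max`` the number of activatable templates, the
cumulative number of microtubules follows the saturating exponential

    N(t) = N_max * (1 - exp(-k * t / N_max))

whose discrete-time counterpart is the recursion

    N_t = N_{t-dt} + dt * k * (1 - N_{t-dt} / N_max),   N_0 = 0.

The recursion is the form used for forward simulation; the closed form is
the one fitted to measured count trajectories.  A two-phase variant models
an activator mutant whose effect switches on late: at the switch time the
rate is replaced by the wildtype rate and the remaining capacity by the
wildtype capacity minus the microtubules already present.

The module also carries the assay's small stoichiometric arithmetic:
tubulin sequestration by stathmin (2 tubulin dimers removed per stathmin),
fold changes against a buffer control, and activator-dimer occupancy of
purified template complexes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "NucleationKinetics",
    "CountTrajectory",
    "SequestrationState",
    "DimerOccupancy",
    "eq1_counts",
    "eq2_trajectory",
    "two_phase_trajectory",
    "free_tubulin",
    "final_stathmin",
    "fold_change",
    "dimer_occupancy",
]

logger = logging.getLogger(__name__)

#: significant digits used when serializing model trajectories
_CSV_SIGFIGS = 12


@dataclass(frozen=True)
class NucleationKinetics:
    """Parameters of the saturating nucleation rate law.

    Parameters
    ----------
    k : float
        Initial nucleation rate, MTs/s.  Non-negative.
    n_max : float
        Maximum number of activatable nucleation templates (trajectory
        saturation level).  Strictly positive.
    switch_time : float, optional
        Time (s) at which two-phase rules take over.  Must be paired with
        ``k_post``.
    k_post : float, optional
        Post-switch nucleation rate, MTs/s.
    """

    k: float
    n_max: float
    switch_time: float | None = None
    k_post: float | None = None

    def __post_init__(self) -> None:
        if not self.k >= 0:
            raise ValueError(f"nucleation rate k must be >= 0, got {self.k}")
        if not self.n_max > 0:
            raise ValueError(f"N_max must be > 0, got {self.n_max}")
        if (self.switch_time is None) != (self.k_post is None):
            raise ValueError("switch_time and k_post must be given together")
        if self.switch_time is not None and not self.switch_time > 0:
            raise ValueError(f"switch_time must be > 0, got {self.switch_time}")


@dataclass
class CountTrajectory:
    """Cumulative microtubule count vs time.

    ``times`` start at 0 and are strictly increasing; ``counts`` are
    non-negative and, for model output, non-decreasing real numbers
    (fractional microtubules are allowed — integerization is the
    simulator's job).
    """

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at t >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    def window(self, t_min: float, t_max: float) -> "CountTrajectory":
        """Restrict to times in the closed interval [t_min, t_max]."""
        sel = (self.times >= t_min) & (self.times <= t_max)
        return CountTrajectory(self.times[sel], self.counts[sel])

    # -- CSV round-trip (two columns, 12 significant digits) ---------------
    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        df = pd.DataFrame({"time_s": self.times, "count": self.counts})
        df.to_csv(path, index=False, float_format=f"%.{_CSV_SIGFIGS}g")

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "CountTrajectory":
        df = pd.read_csv(path)
        missing = {"time_s", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
        return cls(df["time_s"].to_numpy(), df["count"].to_numpy())


def eq1_counts(t, kin: NucleationKinetics):
    """Closed-form cumulative count N(t) = N_max * (1 - exp(-k t / N_max)).

    Vectorizes over ``t``; scalar in, scalar out.  Negative times are a
    domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = kin.n_max * (-np.expm1(-kin.k * t_arr / kin.n_max))
    return out if isinstance(t, np.ndarray) else float(out) if t_arr.ndim == 0 else out


def eq2_trajectory(
    kin: NucleationKinetics, duration: float, dt: float = 1.0
) -> CountTrajectory:
    """Discrete-time nucleation recursion.

    ``N_t = N_{t-dt} + dt * k * (1 - N_{t-dt} / N_max)`` starting from
    ``N_0 = 0``; increments are clamped so N never exceeds ``N_max``.  At
    ``dt = 1`` this is the unit-step recursion verbatim.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if not dt > 0:
        raise ValueError("dt must be > 0")
    n_steps = int(round(duration / dt))
    counts = np.empty(n_steps + 1)
    counts[0] = 0.0
    n = 0.0
    for i in range(1, n_steps + 1):
        n = min(n + dt * kin.k * (1.0 - n / kin.n_max), kin.n_max)
        counts[i] = n
    return CountTrajectory(np.arange(n_steps + 1) * dt, counts)


def two_phase_trajectory(
    kin_phase1: NucleationKinetics,
    kin_wt: NucleationKinetics,
    switch_time: float,
    duration: float,
    dt: float = 1.0,
) -> CountTrajectory:
    """Two-phase recursion for a late-activating mutant.

    Phase 1 runs the recursion with ``kin_phase1`` up to ``switch_time``.
    From then on the rate becomes ``kin_wt.k`` and the remaining capacity
    becomes ``max(0, kin_wt.n_max - N(switch_time))``, layered on top of
    the microtubules already present, so the trajectory is continuous at
    the switch.  Already-nucleated microtubules are never removed: if the
    wildtype capacity is below the count at the switch the residual
    capacity is floored at 0 (and logged).
    """
    if not 0 < switch_time < duration:
        raise ValueError("switch_time must satisfy 0 < switch_time < duration")
    phase1 = eq2_trajectory(kin_phase1, duration=switch_time, dt=dt)
    n_switch = float(phase1.counts[-1])
    capacity = kin_wt.n_max - n_switch
    if capacity < 0:
        logger.warning(
            "two-phase capacity %.3f below count at switch %.3f; flooring at 0",
            kin_wt.n_max,
            n_switch,
        )
        capacity = 0.0
    n_steps = int(round((duration - switch_time) / dt))
    times2 = phase1.times[-1] + np.arange(1, n_steps + 1) * dt
    counts2 = np.empty(n_steps)
    m = 0.0
    for i in range(n_steps):
        if capacity > 0:
            m = min(m + dt * kin_wt.k * (1.0 - m / capacity), capacity)
        counts2[i] = n_switch + m
    return CountTrajectory(
        np.concatenate([phase1.times, times2]),
        np.concatenate([phase1.counts, counts2]),
    )


# ---------------------------------------------------------------------------
# Stoichiometric arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequestrationState:
    """Tubulin pool under sequestration by stathmin.

    Each stathmin molecule removes ``stoichiometry`` (default 2) tubulin
    dimers from the polymerizable pool; the free pool is floored at 0.
    Concentrations in µM.
    """

    tubulin_total: float
    stathmin: float
    stoichiometry: float = 2.0

    def __post_init__(self) -> None:
        if self.tubulin_total < 0 or self.stathmin < 0 or self.stoichiometry < 0:
            raise ValueError("concentrations and stoichiometry must be >= 0")

    @property
    def tubulin_free(self) -> float:
        return max(0.0, self.tubulin_total - self.stoichiometry * self.stathmin)


def free_tubulin(state: SequestrationState) -> float:
    """Free (unsequestered) tubulin concentration, µM."""
    return state.tubulin_free


def final_stathmin(endogenous_um: float, added_um: float) -> float:
    """Total stathmin after spiking extract: endogenous + added, µM."""
    if endogenous_um < 0 or added_um < 0:
        raise ValueError("concentrations must be >= 0")
    return endogenous_um + added_um


def fold_change(value: float, reference: float) -> float:
    """Ratio of a measured quantity to its buffer-control reference."""
    if not reference > 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return value / reference


class DimerOccupancy(NamedTuple):
    retained: float
    lost: float


def dimer_occupancy(dimer_conc: float, turc_conc: float) -> DimerOccupancy:
    """Fraction of template complexes retaining their activator dimer.

    ``retained = dimer_conc / turc_conc`` (capped at 1), ``lost`` is the
    complement.  Concentrations in nM (any common unit cancels).
    """
    if not turc_conc > 0:
        raise ValueError(f"template concentration must be > 0, got {turc_conc}")
    if dimer_conc < 0:
        raise ValueError(f"dimer concentration must be >= 0, got {dimer_conc}")
    retained = min(1.0, dimer_conc / turc_conc)
    return DimerOccupancy(retained=retained, lost=1.0 - retained)
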