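"""Species populations from sedimentation-coefficient distributions.

Sedimentation-velocity AUC yields a continuous distribution c(s) whose
peaks correspond to the oligomeric species of a self-associating protein.
Populations are quantified by integrating c(s) over per-species s-windows
anchored on hydrodynamic reference s-values for the H-NS monomer, dimer,
tetramer and octamer (1.1, 1.6, 2.4 and 3.5 S, fixed constants from
bead-model predictions).  Because the absorbance signal is proportional
to protomer mass, the normalized window areas are protomer-mass
fractions, directly comparable with the thermodynamic model's species
fractions.

Caveat: under reaction-boundary conditions peak positions shift with
loading concentration; windows whose peak maximum falls close to a
window edge are flagged rather than re-apportioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REFERENCE_S_VALUES",
    "CsDistribution",
    "SpeciesWindows",
    "WindowFractions",
    "default_windows",
    "integrate_windows",
    "signal_to_protomer_fractions",
    "EmptyDistributionError",
]

#: Bead-model reference sedimentation coefficients (svedberg).
REFERENCE_S_VALUES = {
    "monomer": 1.1,
    "dimer": 1.6,
    "tetramer": 2.4,
    "octamer": 3.5,
}

_STOICHIOMETRY = {"monomer": 1, "dimer": 2, "tetramer": 4, "octamer": 8}


class EmptyDistributionError(ValueError):
    """The c(s) distribution carries no signal."""


@dataclass
class CsDistribution:
    """A c(s) distribution: amplitudes on a strictly increasing s grid."""

    s_grid: np.ndarray
    c_values: np.ndarray
    total_C: float = float("nan")
    label: str = ""

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.c_values = np.asarray(self.c_values, dtype=float)
        if self.s_grid.shape != self.c_values.shape:
            raise ValueError("s_grid and c_values must have equal lengths")
        if not np.all(np.diff(self.s_grid) > 0):
            raise ValueError("s_grid must be strictly increasing")
        if np.any(self.c_values < 0):
            raise ValueError("c_values must be non-negative")


@dataclass(frozen=True)
class SpeciesWindows:
    """Ordered, disjoint closed s-intervals per species."""

    windows: dict[str, tuple[float, float]]

    def __post_init__(self):
        items = list(self.windows.items())
        prev_hi = -math.inf
        for name, (lo, hi) in items:
            if not lo < hi:
                raise ValueError(f"window {name!r} is empty or inverted")
            if lo < prev_hi:
                raise ValueError("windows must be disjoint and ascending")
            prev_hi = hi

    def __iter__(self):
        return iter(self.windows.items())


def default_windows(s_min: float = 0.0, s_max: float = 15.0) -> SpeciesWindows:
    """Windows centered on the reference s-values.

    Boundaries sit at the geometric midpoints between adjacent reference
    values (1.33, 1.96, 2.90 S); the monomer window opens at ``s_min``
    and the octamer window extends to ``s_max`` (integration limits are
    an operational choice — they are not reported with the data).
    """
    refs = list(REFERENCE_S_VALUES.values())
    cuts = [math.sqrt(a * b) for a, b in zip(refs, refs[1:])]
    edges = [s_min, *cuts, s_max]
    names = list(REFERENCE_S_VALUES)
    return SpeciesWindows(
        {name: (edges[i], edges[i + 1]) for i, name in enumerate(names)}
    )


@dataclass(frozen=True)
class WindowFractions:
    """Normalized window areas plus bookkeeping of unassigned signal."""

    fractions: dict[str, float]
    unassigned_fraction: float
    boundary_flags: dict[str, bool]

    def as_dict(self) -> dict[str, float]:
        return dict(self.fractions)


def _window_area(dist: CsDistribution, lo: float, hi: float) -> float:
    """Trapezoidal area of c(s) over [lo, hi] with interpolated edges."""
    s, c = dist.s_grid, dist.c_values
    lo = max(lo, s[0])
    hi = min(hi, s[-1])
    if hi <= lo:
        return 0.0
    inner = (s > lo) & (s < hi)
    xs = np.concatenate([[lo], s[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, s, c)], c[inner], [np.interp(hi, s, c)]])
    return float(np.trapezoid(ys, xs))


def integrate_windows(
    dist: CsDistribution, windows: SpeciesWindows | None = None
) -> WindowFractions:
    """Per-species signal fractions from window areas.

    Areas are trapezoidal integrals per window, normalized by the summed
    area over all windows so the fractions add to one.  Signal outside
    every window is reported separately as ``unassigned_fraction`` (of the
    total distribution area).  A window is flagged when the position of
    its maximum lies within 10% of the window width of either boundary —
    the reaction-boundary caveat.
    """
    if windows is None:
        windows = default_windows(s_min=dist.s_grid[0], s_max=dist.s_grid[-1])
    total = float(np.trapezoid(dist.c_values, dist.s_grid))
    if total <= 0:
        raise EmptyDistributionError("c(s) distribution has zero total area")

    areas: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for name, (lo, hi) in windows:
        areas[name] = _window_area(dist, lo, hi)
        mask = (dist.s_grid >= lo) & (dist.s_grid <= hi)
        if mask.any() and areas[name] > 0:
            s_peak = dist.s_grid[mask][np.argmax(dist.c_values[mask])]
            margin = 0.10 * (hi - lo)
            flags[name] = bool(s_peak < lo + margin or s_peak > hi - margin)
        else:
            flags[name] = False

    in_windows = sum(areas.values())
    if in_windows <= 0:
        raise EmptyDistributionError("no signal inside the species windows")
    fractions = {k: v / in_windows for k, v in areas.items()}
    return WindowFractions(
        fractions=fractions,
        unassigned_fraction=(total - in_windows) / total,
        boundary_flags=flags,
    )


def signal_to_protomer_fractions(
    signal_fractions: dict[str, float], mode: str = "identity"
) -> dict[str, float]:
    """Convert signal fractions to species fractions.

    ``identity``: absorbance is proportional to protomer mass, so signal
    fractions already are protomer-mass fractions (the convention used to
    compare with the thermodynamic model).  ``molar``: divide by the
    stoichiometry (8, 4, 2, 1) and renormalize to get mole fractions of
    the assemblies themselves.
    """
    tot = sum(signal_fractions.values())
    if not math.isclose(tot, 1.0, rel_tol=1e-6, abs_tol=1e-9):
        raise ValueError("signal fractions must sum to 1")
    if mode == "identity":
        return dict(signal_fractions)
    if mode == "molar":
        molar = {
            k: v / _STOICHIOMETRY.get(k, 1) for k, v in signal_fractions.items()
        }
        norm = sum(molar.values())
        return {k: v / norm for k, v in molar.items()}
    raise ValueError(f"unknown mode {mode!r}; use 'identity' or 'molar'")
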