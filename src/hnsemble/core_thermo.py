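"""Equilibrium thermodynamics of H-NS self-assembly and unfolding.

The model couples three linked equilibria for a self-associating protein:

    N8 <-> 2 N4 <-> 4 N2 <-> 8 N <-> 8 U

i.e. octamers dissociate into tetramers, tetramers into dimers, dimers
into folded monomers, and the folded monomer unfolds.  Both association
steps above the dimer share a single oligomerization constant ``K_o``
(association, per molar); dimerization has its own constant ``K_d``;
unfolding is governed by the dimensionless ``K_U`` which equals one at
the melting temperature ``T_m``.  Every constant follows a van't Hoff
temperature dependence parameterized by an enthalpy and a reference
temperature, so the model carries eight free parameters in total.

The partition function per protomer, Z(T) = C / [N], yields the excess
molar heat capacity

    Cp(T) = 2 R T (d ln Z / dT) + R T^2 (d^2 ln Z / dT^2)

and the protomer-mass fraction of each species, alpha_Y = Z_Y / Z.

All internal units are kelvin, molar and joules; R = 8.314 J mol-1 K-1.
Dissociation constants (K_O = 1/K_o, K_D = 1/K_d) are exposed for
reporting because experimental work quotes dissociation values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

R = 8.314
"""Gas constant, J mol-1 K-1."""

__all__ = [
    "R",
    "ThermoParams",
    "SpeciesConcentrations",
    "PartitionTerms",
    "SpeciesFractions",
    "CpCurve",
    "vant_hoff_K",
    "enthalpy_from_two_points",
    "solve_mass_balance",
    "partition_terms",
    "species_fractions",
    "heat_capacity_curve",
    "local_maxima",
    "preset",
    "PRESET_NAMES",
    "InvalidParameterError",
    "DegenerateStateError",
    "MassBalanceError",
]


class InvalidParameterError(ValueError):
    """A thermodynamic parameter violates its physical domain."""


class DegenerateStateError(ValueError):
    """The system is in a degenerate state (e.g. no folded monomer)."""


class MassBalanceError(RuntimeError):
    """The mass-balance root finder failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def vant_hoff_K(K_ref: float, dH: float, T_ref: float, T: float):
    """Equilibrium constant at ``T`` from a reference point and enthalpy.

    The entropy is fixed by the reference point, dS = dH/T_ref + R ln(K_ref),
    and K(T) = exp(-dH/(R T) + dS/R).  Returns ``K_ref`` exactly at
    ``T = T_ref``; with ``dH = 0`` the equilibrium is athermal.

    Accepts scalars or numpy arrays for ``T``.
    """
    if np.any(np.asarray(T_ref) <= 0) or np.any(np.asarray(T) <= 0):
        raise InvalidParameterError("temperatures must be positive (kelvin)")
    if K_ref <= 0:
        raise InvalidParameterError("K_ref must be positive")
    dS = dH / T_ref + R * math.log(K_ref)
    return np.exp(-dH / (R * np.asarray(T, dtype=float)) + dS / R)


def enthalpy_from_two_points(K1: float, T1: float, K2: float, T2: float) -> float:
    """van't Hoff enthalpy from two (K, T) anchors.

    Inverse of :func:`vant_hoff_K`: dH = R ln(K2/K1) / (1/T1 - 1/T2).
    """
    if K1 <= 0 or K2 <= 0 or T1 <= 0 or T2 <= 0:
        raise InvalidParameterError("anchors must have positive K and T")
    if T1 == T2:
        raise InvalidParameterError("anchors must be at distinct temperatures")
    return R * math.log(K2 / K1) / (1.0 / T1 - 1.0 / T2)


@dataclass(frozen=True)
class ThermoParams:
    """Eight-parameter description of the linked assembly/unfolding model.

    Parameters
    ----------
    T_O, T_D, T_m : float
        Reference temperatures (K) for oligomerization, dimerization and
        unfolding.  ``T_m`` is the monomer melting temperature; the
        unfolding constant equals one there by construction.
    dH_O, dH_D, dH_U : float
        van't Hoff enthalpies (J per mol of reaction as written).
    K_o_ref, K_d_ref : float
        Association constants (per molar) at ``T_O`` and ``T_D``.
    label : str
        Free-text condition tag (e.g. ionic strength).
    """

    T_O: float
    T_D: float
    T_m: float
    dH_O: float
    dH_D: float
    dH_U: float
    K_o_ref: float
    K_d_ref: float
    label: str = ""

    def __post_init__(self):
        for name in ("T_O", "T_D", "T_m"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0 K")
        if self.K_o_ref <= 0 or self.K_d_ref <= 0:
            raise InvalidParameterError("association constants must be > 0")

    # -- temperature-dependent constants ------------------------------
    def K_o(self, T):
        """Oligomerization association constant at T (per molar)."""
        return vant_hoff_K(self.K_o_ref, self.dH_O, self.T_O, T)

    def K_d(self, T):
        """Dimerization association constant at T (per molar)."""
        return vant_hoff_K(self.K_d_ref, self.dH_D, self.T_D, T)

    def K_U(self, T):
        """Unfolding constant at T (dimensionless, 1 at T_m)."""
        return vant_hoff_K(1.0, self.dH_U, self.T_m, T)

    # -- dissociation constants for reporting -------------------------
    def K_O_diss(self, T):
        """Oligomerization dissociation constant at T (molar)."""
        return 1.0 / self.K_o(T)

    def K_D_diss(self, T):
        """Dimerization dissociation constant at T (molar)."""
        return 1.0 / self.K_d(T)


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Molar concentrations of every species plus the protomer total."""

    n8: float
    n4: float
    n2: float
    n: float
    u: float
    total_C: float

    def residual(self) -> float:
        """Absolute mass-balance residual, 8 n8 + 4 n4 + 2 n2 + n + u - C."""
        return 8 * self.n8 + 4 * self.n4 + 2 * self.n2 + self.n + self.u - self.total_C


@dataclass(frozen=True)
class PartitionTerms:
    """Species partition-function terms; zN is 1 by normalization."""

    z8: float
    z4: float
    z2: float
    zN: float
    zU: float

    @property
    def Z(self) -> float:
        return self.z8 + self.z4 + self.z2 + self.zN + self.zU


@dataclass(frozen=True)
class SpeciesFractions:
    """Protomer-mass fractions per species at one (C, T) point."""

    a8: float
    a4: float
    a2: float
    aN: float
    aU: float
    T: float
    total_C: float

    def as_dict(self) -> dict[str, float]:
        return {
            "octamer": self.a8,
            "tetramer": self.a4,
            "dimer": self.a2,
            "monomer_folded": self.aN,
            "monomer_unfolded": self.aU,
        }


@dataclass
class CpCurve:
    """Molar heat capacity (J mol-1 K-1) on a strictly increasing T grid."""

    T_grid: np.ndarray
    cp: np.ndarray
    total_C: float
    params_label: str = ""

    def __post_init__(self):
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.T_grid.shape != self.cp.shape:
            raise ValueError("T_grid and cp must have equal lengths")
        if self.T_grid.size > 1 and not np.all(np.diff(self.T_grid) > 0):
            raise ValueError("T_grid must be strictly increasing")


# ---------------------------------------------------------------------
# mass balance
# ---------------------------------------------------------------------

def _mass_balance_poly_N(N, C, K_o, K_d, K_U):
    """Protomer balance written in the folded monomer concentration N.

    C = 8 Ko^3 Kd^4 N^8 + 4 Ko Kd^2 N^4 + 2 Kd N^2 + N + K_U N.
    Monotone increasing in N on [0, C], hence a single positive root.
    """
    return (
        8.0 * K_o**3 * K_d**4 * N**8
        + 4.0 * K_o * K_d**2 * N**4
        + 2.0 * K_d * N**2
        + (1.0 + K_U) * N
        - C
    )


def _solve_N_vector(C, K_o, K_d, K_U, n_bisect: int = 100):
    """Vectorized bracketed bisection for the folded-monomer root.

    All arguments broadcast; the bracket [0, C] always contains the unique
    root because the balance polynomial is monotone with a single sign
    change.  100 halvings take the bracket to ~C * 8e-31, far below the
    1e-14 relative target, and the method is unconditionally robust.
    """
    C, K_o, K_d, K_U = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (C, K_o, K_d, K_U))
    )
    # fixed polynomial coefficients, hoisted out of the iteration
    c8 = 8.0 * K_o**3 * K_d**4
    c4 = 4.0 * K_o * K_d**2
    c2 = 2.0 * K_d
    c1 = 1.0 + K_U
    lo = np.zeros_like(C)
    hi = C.copy()
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        n2 = mid * mid
        n4 = n2 * n2
        f = (c8 * n4 + c4) * n4 + c2 * n2 + c1 * mid - C
        take_hi = f > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    return 0.5 * (lo + hi)


def solve_mass_balance(
    C: float, K_o: float, K_d: float, K_U: float
) -> SpeciesConcentrations:
    """Solve the protomer mass balance for all species concentrations.

    Finds the unique non-negative root of the degree-8 balance polynomial
    and back-computes every species through the equilibrium constants.
    The returned concentrations satisfy the balance to 1e-9 relative
    (1e-15 absolute when C = 0).
    """
    if C < 0:
        raise InvalidParameterError("total concentration must be >= 0")
    if K_o < 0 or K_d < 0:
        raise InvalidParameterError("association constants must be >= 0")
    if K_U <= 0:
        raise InvalidParameterError("K_U must be > 0")
    if C == 0:
        return SpeciesConcentrations(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    n = float(_solve_N_vector(C, K_o, K_d, K_U))
    u = K_U * n
    n2 = K_d * n * n
    n4 = K_o * n2 * n2
    n8 = K_o * n4 * n4
    out = SpeciesConcentrations(n8, n4, n2, n, u, C)
    resid = abs(out.residual())
    if resid > 1e-9 * C:
        raise MassBalanceError(
            f"mass-balance residual {resid:.3e} exceeds 1e-9*C", residual=resid
        )
    return out


# ---------------------------------------------------------------------
# partition function
# ---------------------------------------------------------------------

def partition_terms(
    concs: SpeciesConcentrations, K_o: float, K_d: float, K_U: float
) -> PartitionTerms:
    """Species partition-function terms from the equilibrium constants.

    Written in powers of the unfolded concentration as the constants
    prescribe (z8 = 8 Ko^3 Kd^4 (u/K_U)^7, ...); the consistency check
    Z == (8 n8 + 4 n4 + 2 n2 + n + u) / n is available through
    :meth:`SpeciesConcentrations.residual` and exercised in tests.
    """
    if concs.n <= 0:
        raise DegenerateStateError(
            "no folded monomer present; partition terms are undefined"
        )
    x = concs.u / K_U  # equals [N] when the balance holds
    z2 = 2.0 * K_d * x
    z4 = 4.0 * K_o * K_d**2 * x**3
    z8 = 8.0 * K_o**3 * K_d**4 * x**7
    return PartitionTerms(z8=z8, z4=z4, z2=z2, zN=1.0, zU=K_U)


def species_fractions(params: ThermoParams, C: float, T: float) -> SpeciesFractions:
    """Protomer-mass fraction of every species at one (C, T) point.

    alpha_Y = Z_Y / Z; the folded monomer (zN = 1) completes the
    normalization so the five fractions sum to one.
    """
    K_o = float(params.K_o(T))
    K_d = float(params.K_d(T))
    K_U = float(params.K_U(T))
    concs = solve_mass_balance(C, K_o, K_d, K_U)
    if C == 0:
        # infinite-dilution limit: pure monomer, split by K_U
        aU = K_U / (1.0 + K_U)
        return SpeciesFractions(0.0, 0.0, 0.0, 1.0 - aU, aU, T, C)
    terms = partition_terms(concs, K_o, K_d, K_U)
    Z = terms.Z
    return SpeciesFractions(
        a8=terms.z8 / Z,
        a4=terms.z4 / Z,
        a2=terms.z2 / Z,
        aN=terms.zN / Z,
        aU=terms.zU / Z,
        T=T,
        total_C=C,
    )


# ---------------------------------------------------------------------
# heat capacity
# ---------------------------------------------------------------------

def _ln_Z(params: ThermoParams, C: float, T: np.ndarray) -> np.ndarray:
    """ln Z(T) = ln(C / [N]) on an arbitrary temperature array."""
    T = np.asarray(T, dtype=float)
    K_o = params.K_o(T)
    K_d = params.K_d(T)
    K_U = params.K_U(T)
    n = _solve_N_vector(np.full_like(T, C), K_o, K_d, K_U)
    return np.log(C) - np.log(n)


def heat_capacity_curve(
    params: ThermoParams,
    C: float,
    T_grid,
    *,
    internal_step: float | None = 0.1,
    fd_step: float = 0.01,
) -> CpCurve:
    """Excess molar heat capacity on ``T_grid`` at protomer concentration C.

    ln Z is evaluated on an internal grid (default 0.1 K) and
    differentiated by central finite differences with a 0.01 K step; the
    curve is then interpolated onto the requested grid.  With
    ``internal_step=None`` the stencil is evaluated directly at the
    requested temperatures (cheaper; used inside fitting loops).  The
    result is the excess heat capacity of the model only — no instrument
    baseline.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size < 1 or (T_grid.size > 1 and not np.all(np.diff(T_grid) > 0)):
        raise InvalidParameterError("T_grid must be non-empty, strictly increasing")
    if T_grid[0] <= 250.0 or T_grid[-1] >= 400.0:
        raise InvalidParameterError("T_grid must lie within (250, 400) K")
    if C <= 0:
        raise InvalidParameterError("Cp requires a positive protomer concentration")

    if internal_step is None:
        T_int = T_grid
    else:
        T_int = np.arange(T_grid[0], T_grid[-1] + internal_step / 2, internal_step)
    h = fd_step
    stacked = np.concatenate([T_int - h, T_int, T_int + h])
    lnZ = _ln_Z(params, C, stacked)
    m = T_int.size
    lnZ_lo, lnZ_0, lnZ_hi = lnZ[:m], lnZ[m : 2 * m], lnZ[2 * m :]
    d1 = (lnZ_hi - lnZ_lo) / (2 * h)
    d2 = (lnZ_hi - 2 * lnZ_0 + lnZ_lo) / (h * h)
    cp_int = 2 * R * T_int * d1 + R * T_int**2 * d2
    cp = cp_int if internal_step is None else np.interp(T_grid, T_int, cp_int)
    return CpCurve(T_grid=T_grid.copy(), cp=cp, total_C=C, params_label=params.label)


def local_maxima(curve: CpCurve, min_prominence_frac: float = 0.02) -> np.ndarray:
    """Temperatures of interior local maxima of a heat-capacity curve.

    A peak must rise above its surroundings by ``min_prominence_frac`` of
    the curve's full amplitude, which suppresses finite-difference ripple.
    """
    from scipy.signal import find_peaks

    amp = float(np.ptp(curve.cp))
    if amp == 0:
        return np.array([])
    idx, _ = find_peaks(curve.cp, prominence=min_prominence_frac * amp)
    return curve.T_grid[idx]


# ---------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------

_T25 = 298.15
_T37 = 310.15


def _anchored(KD_25, KD_37, KO_25, KO_37, dH_U, T_m, label):
    """ThermoParams from dissociation-constant anchors at 25/37 C."""
    kd25, kd37 = 1.0 / KD_25, 1.0 / KD_37
    ko25, ko37 = 1.0 / KO_25, 1.0 / KO_37
    return ThermoParams(
        T_O=_T25,
        T_D=_T25,
        T_m=T_m,
        dH_O=enthalpy_from_two_points(ko25, _T25, ko37, _T37),
        dH_D=enthalpy_from_two_points(kd25, _T25, kd37, _T37),
        dH_U=dH_U,
        K_o_ref=ko25,
        K_d_ref=kd25,
        label=label,
    )


def preset(name: str) -> ThermoParams:
    """Packaged parameter sets for H-NS.

    ``wt_150mM`` is anchored to the 25/37 C dissociation constants of the
    physiological ionic-strength condition (K_D 0.5 -> 8 uM, K_O 30 ->
    45 uM: strong temperature dependence of dimerization, weak of
    oligomerization), with the unfolding parameters chosen so the 15 uM
    excess-Cp curve shows two resolved transitions that merge into one at
    high concentration.  ``wt_300mM`` encodes the high-osmolarity regime:
    weaker dimerization, slightly stronger oligomerization, hence
    comparable constants and a single cooperative transition.
    """
    if name == "wt_150mM":
        return _anchored(
            KD_25=0.5e-6, KD_37=8e-6, KO_25=30e-6, KO_37=45e-6,
            dH_U=1.3e5, T_m=342.15, label="wt_150mM",
        )
    if name == "wt_300mM":
        return _anchored(
            KD_25=5e-6, KD_37=25e-6, KO_25=20e-6, KO_37=30e-6,
            dH_U=1.3e5, T_m=342.15, label="wt_300mM",
        )
    raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


PRESET_NAMES = ("wt_150mM", "wt_300mM")
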