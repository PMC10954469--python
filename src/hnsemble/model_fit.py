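"""Joint calibration of the assembly model against DSC shapes and AUC
populations.

A steep pre-transition region makes absolute DSC baselines unreliable
for this system, so calibration is semi-quantitative by design: the
objective compares peak-normalized heat-capacity shapes (per
concentration) together with species-population tables derived from
sedimentation-velocity experiments, and parameter recovery on synthetic
data — not reproduction of any particular published parameter vector —
is the accuracy contract.

Parameterization note: the van't Hoff form makes (T_ref, K_ref) pairs a
gauge freedom (every pair on the same K(T) line is the same model), so
the fit pins T_O = T_D = 298.15 K and searches the six identifiable
parameters dH_O, dH_D, dH_U, T_m, log10 K_o_ref, log10 K_d_ref.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize

from .core_thermo import (
    CpCurve,
    InvalidParameterError,
    ThermoParams,
    heat_capacity_curve,
    species_fractions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationTable",
    "CalibrationDataset",
    "FitResult",
    "FitBounds",
    "baseline_subtract",
    "objective",
    "fit",
]

_REF_T = 298.15
_PENALTY = 1e6

_SPECIES_KEYS = ("octamer", "tetramer", "dimer", "monomer")


@dataclass(frozen=True)
class PopulationTable:
    """Species protomer fractions at one (C, T), e.g. from AUC windows.

    ``fractions`` keys are a subset of octamer/tetramer/dimer/monomer;
    the model's folded and unfolded monomer fractions are summed for the
    comparison (a c(s) monomer peak does not resolve folding status).
    """

    total_C: float
    temperature: float
    fractions: dict[str, float]

    def __post_init__(self):
        if self.total_C <= 0:
            raise InvalidParameterError("population table needs C > 0")
        unknown = set(self.fractions) - set(_SPECIES_KEYS)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")


@dataclass
class CalibrationDataset:
    """Thermograms (baseline-subtracted) and/or AUC population tables."""

    thermograms: list[CpCurve] = field(default_factory=list)
    populations: list[PopulationTable] = field(default_factory=list)
    weight_dsc: float = 1.0
    weight_pop: float = 1.0

    def __post_init__(self):
        if not self.thermograms and not self.populations:
            raise ValueError("dataset needs at least one thermogram or table")
        for tg in self.thermograms:
            if not (tg.total_C > 0):
                raise InvalidParameterError("thermogram concentrations must be > 0")


@dataclass(frozen=True)
class FitBounds:
    """Search box for the six identifiable parameters."""

    dH_O: tuple[float, float] = (-1e6, 0.0)
    dH_D: tuple[float, float] = (-1e6, 0.0)
    dH_U: tuple[float, float] = (1e4, 1e6)
    T_m: tuple[float, float] = (300.0, 380.0)
    log10_K_o: tuple[float, float] = (2.0, 8.0)
    log10_K_d: tuple[float, float] = (2.0, 9.0)

    def as_list(self):
        return [self.dH_O, self.dH_D, self.dH_U, self.T_m,
                self.log10_K_o, self.log10_K_d]


@dataclass
class FitResult:
    """Best parameters, objective value and per-term residuals."""

    params: ThermoParams
    objective_value: float
    residuals: dict[str, float]
    n_iterations: int
    seed: int
    converged: bool


# ---------------------------------------------------------------------
# baseline handling
# ---------------------------------------------------------------------

def baseline_subtract(
    raw: CpCurve,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    kind: str = "linear",
) -> CpCurve:
    """Subtract an instrument baseline anchored in two transition-free
    windows.

    ``linear``: one straight line through both windows.  ``sigmoidal``:
    separate pre/post lines blended by the integrated transition progress
    (the standard chemical baseline for calorimetry).  Output may dip
    slightly negative near the anchors; that is expected of excess heat
    capacity estimates.
    """
    T, cp = raw.T_grid, raw.cp
    masks = []
    for lo, hi in (pre_window, post_window):
        if lo >= hi or lo < T[0] - 1e-9 or hi > T[-1] + 1e-9:
            raise ValueError("baseline windows must be ordered and inside T_grid")
        masks.append((T >= lo) & (T <= hi))
    pre_m, post_m = masks
    if pre_m.sum() < 5 or post_m.sum() < 5:
        raise ValueError("baseline windows must contain at least 5 points")
    if (pre_window[1] > post_window[0]):
        raise ValueError("baseline windows must not overlap")

    if kind == "linear":
        both = pre_m | post_m
        coef = np.polyfit(T[both], cp[both], 1)
        base = np.polyval(coef, T)
    elif kind == "sigmoidal":
        pre = np.polyval(np.polyfit(T[pre_m], cp[pre_m], 1), T)
        post = np.polyval(np.polyfit(T[post_m], cp[post_m], 1), T)
        # iterate: progress = normalized cumulative excess area
        base = pre.copy()
        for _ in range(3):
            excess = np.clip(cp - base, 0.0, None)
            area = np.concatenate([[0.0], np.cumsum(
                0.5 * (excess[1:] + excess[:-1]) * np.diff(T))])
            alpha = area / area[-1] if area[-1] > 0 else np.zeros_like(T)
            base = (1 - alpha) * pre + alpha * post
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    return CpCurve(T_grid=T.copy(), cp=cp - base, total_C=raw.total_C,
                   params_label=raw.params_label)


# ---------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------

def _model_populations(params: ThermoParams, table: PopulationTable):
    sf = species_fractions(params, table.total_C, table.temperature)
    model = {
        "octamer": sf.a8,
        "tetramer": sf.a4,
        "dimer": sf.a2,
        "monomer": sf.aN + sf.aU,
    }
    return {k: model[k] for k in table.fractions}


def objective(params: ThermoParams, data: CalibrationDataset) -> float:
    """Weighted shape + population mismatch; large finite penalty on model
    failure (never an exception, so optimizers can traverse bad regions).

    DSC term: mean squared difference between peak-normalized model and
    experimental excess Cp per thermogram (normalization makes the term
    invariant to uniform rescaling of the measured curve).  Population
    term: squared species-fraction differences.
    """
    try:
        total = 0.0
        for tg in data.thermograms:
            model = heat_capacity_curve(params, tg.total_C, tg.T_grid,
                                        internal_step=None)
            peak_m = np.max(np.abs(model.cp))
            peak_e = np.max(np.abs(tg.cp))
            if peak_m <= 0 or peak_e <= 0:
                return _PENALTY
            diff = model.cp / peak_m - tg.cp / peak_e
            total += data.weight_dsc * float(np.mean(diff * diff))
        for table in data.populations:
            model = _model_populations(params, table)
            for k, v in table.fractions.items():
                total += data.weight_pop * (model[k] - v) ** 2
        if not math.isfinite(total):
            return _PENALTY
        return total
    except Exception as err:  # noqa: BLE001 - any model failure is a penalty
        logger.warning("model evaluation failed (%s); penalizing", err)
        return _PENALTY


def _params_from_vector(x, label="fit") -> ThermoParams:
    dH_O, dH_D, dH_U, T_m, lko, lkd = x
    return ThermoParams(
        T_O=_REF_T, T_D=_REF_T, T_m=T_m, dH_O=dH_O, dH_D=dH_D, dH_U=dH_U,
        K_o_ref=10.0**lko, K_d_ref=10.0**lkd, label=label,
    )


def fit(
    data: CalibrationDataset,
    bounds: FitBounds | None = None,
    seed: int = 0,
    maxiter: int = 120,
    popsize: int = 16,
) -> FitResult:
    """Global (seeded differential evolution) + local (Nelder-Mead) fit.

    Deterministic given ``seed``.  ``maxiter``/``popsize`` trade run time
    against search depth; the defaults recover synthetic six-parameter
    ground truths from four-concentration datasets.
    """
    bounds = bounds or FitBounds()
    blist = bounds.as_list()

    def func(x):
        return objective(_params_from_vector(x), data)

    result = differential_evolution(
        func, blist, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=1e-10, polish=False, init="sobol", updating="deferred",
    )
    # derivative-free polish, clipped to bounds
    lo = np.array([b[0] for b in blist])
    hi = np.array([b[1] for b in blist])

    def clipped(x):
        return func(np.clip(x, lo, hi))

    local = minimize(clipped, result.x, method="Nelder-Mead",
                     options={"maxiter": 800, "maxfev": 1500,
                              "xatol": 1e-6, "fatol": 1e-10})
    best_x = np.clip(local.x, lo, hi) if local.fun <= result.fun else result.x
    best_f = min(float(local.fun), float(result.fun))
    if not math.isfinite(best_f) or best_f >= _PENALTY:
        raise RuntimeError("all fit starts failed; objective never evaluated")

    params = _params_from_vector(best_x)
    residuals = {}
    for i, tg in enumerate(data.thermograms):
        single = CalibrationDataset(thermograms=[tg],
                                    weight_dsc=data.weight_dsc,
                                    weight_pop=data.weight_pop)
        residuals[f"thermogram_{i}"] = objective(params, single)
    for i, table in enumerate(data.populations):
        single = CalibrationDataset(populations=[table],
                                    weight_dsc=data.weight_dsc,
                                    weight_pop=data.weight_pop)
        residuals[f"populations_{i}"] = objective(params, single)
    return FitResult(
        params=params,
        objective_value=best_f,
        residuals=residuals,
        n_iterations=int(result.nit) + int(local.nit),
        seed=seed,
        converged=bool(result.success or local.success),
    )
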