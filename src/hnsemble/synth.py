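"""Synthetic data generators for every input format the pipeline consumes.

The generators emulate the statistical structure of the corresponding
experiments — model-derived excess heat capacity on top of a linear
instrument baseline with additive Gaussian noise, multi-Gaussian c(s)
distributions with prescribed peak areas, Hill / 1:1 / two-mode binding
isotherms, Gaussian emission spectra, and ideal-geometry toy protein
structures in PDB format.  Every stochastic generator is pure given
(parameters, seed).
"""

from __future__ import annotations

import math

import numpy as np

from .binding import BindingIsotherm, EmissionSpectrum, one_to_one_isotherm
from .core_thermo import CpCurve, ThermoParams, heat_capacity_curve
from .hydro import CsDistribution

__all__ = [
    "gen_thermogram",
    "gen_cs_distribution",
    "gen_isotherm",
    "gen_spectrum",
    "gen_toy_structure",
]


def gen_thermogram(
    params: ThermoParams,
    C: float,
    T_grid,
    baseline: tuple[float, float] = (0.0, 0.0),
    sigma: float = 0.0,
    seed: int = 0,
) -> CpCurve:
    """Model heat capacity plus a linear baseline a + b*T and Gaussian noise.

    With ``sigma=0`` and a zero baseline the output equals
    :func:`~hnsemble.core_thermo.heat_capacity_curve` exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    curve = heat_capacity_curve(params, C, T_grid)
    a, b = baseline
    cp = curve.cp + a + b * curve.T_grid
    if sigma > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, sigma, size=cp.shape)
    return CpCurve(T_grid=curve.T_grid, cp=cp, total_C=C,
                   params_label=f"synthetic:{params.label}")


def gen_cs_distribution(
    peaks: list[tuple[float, float, float]],
    s_grid=None,
    sigma: float = 0.0,
    seed: int = 0,
    total_C: float = float("nan"),
    label: str = "synthetic",
) -> CsDistribution:
    """Sum of Gaussian peaks (center S, width S, area) on an s grid.

    Optional additive Gaussian noise (clipped at zero, keeping c(s)
    non-negative).  An empty peak list yields an all-zero distribution,
    which downstream window integration rejects.
    """
    if s_grid is None:
        s_grid = np.linspace(0.0, 15.0, 1501)
    s = np.asarray(s_grid, dtype=float)
    c = np.zeros_like(s)
    for center, width, area in peaks:
        if width <= 0:
            raise ValueError("peak width must be positive")
        c += area / (width * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((s - center) / width) ** 2
        )
    if sigma > 0:
        rng = np.random.default_rng(seed)
        c = c + rng.normal(0.0, sigma, size=c.shape)
    c = np.clip(c, 0.0, None)
    return CsDistribution(s_grid=s, c_values=c, total_C=total_C, label=label)


def gen_isotherm(
    model: str,
    params: dict,
    conc_grid,
    sigma: float = 0.0,
    seed: int = 0,
    **iso_kwargs,
) -> BindingIsotherm:
    """Noiseless or noisy binding isotherms.

    Models
    ------
    ``hill``
        params: K_half, n_H, signal_min, signal_max.
    ``one_to_one``
        params: K_D, fixed_conc, signal_min, signal_max (exact
        ligand-depletion isotherm).
    ``two_mode``
        sum of two Hill components emulating a specific and a
        non-specific binding regime; params: K1, n1, amp1, K2, n2, amp2,
        signal_min.

    ``sigma`` is the standard deviation of additive Gaussian noise in
    signal units.
    """
    c = np.asarray(conc_grid, dtype=float)
    if model == "hill":
        K, n = params["K_half"], params.get("n_H", 1.0)
        smin = params.get("signal_min", 0.0)
        smax = params.get("signal_max", 1.0)
        f = c**n / (K**n + c**n)
        y = smin + (smax - smin) * f
    elif model == "one_to_one":
        smin = params.get("signal_min", 0.0)
        smax = params.get("signal_max", 1.0)
        f = one_to_one_isotherm(params["K_D"], c, params["fixed_conc"])
        y = smin + (smax - smin) * f
        iso_kwargs.setdefault("fixed_conc", params["fixed_conc"])
    elif model == "two_mode":
        f1 = c ** params.get("n1", 1.0) / (
            params["K1"] ** params.get("n1", 1.0) + c ** params.get("n1", 1.0)
        )
        f2 = c ** params.get("n2", 1.0) / (
            params["K2"] ** params.get("n2", 1.0) + c ** params.get("n2", 1.0)
        )
        y = (
            params.get("signal_min", 0.0)
            + params.get("amp1", 1.0) * f1
            + params.get("amp2", 1.0) * f2
        )
    else:
        raise ValueError(f"unknown isotherm model {model!r}")
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=y.shape)
    return BindingIsotherm(titrant_conc=c, signal=y, **iso_kwargs)


def gen_spectrum(
    center_nm: float = 350.0,
    width_nm: float = 25.0,
    amplitude: float = 1.0,
    wavelength_grid=None,
    sigma: float = 0.0,
    seed: int = 0,
) -> EmissionSpectrum:
    """Gaussian-shaped emission spectrum, optionally noisy (clipped at 0)."""
    if wavelength_grid is None:
        wavelength_grid = np.arange(310.0, 451.0, 1.0)
    lam = np.asarray(wavelength_grid, dtype=float)
    inten = amplitude * np.exp(-0.5 * ((lam - center_nm) / width_nm) ** 2)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0.0, sigma, size=inten.shape)
    return EmissionSpectrum(wavelength=lam, intensity=np.clip(inten, 0.0, None))


# ---------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Position a fourth atom from three reference atoms (NeRF).

    Returns the point at distance ``bond`` from ``c``, forming the given
    b-c-x angle and a-b-c-x dihedral.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(ang), bond * math.sin(ang) * math.cos(dih),
         bond * math.sin(ang) * math.sin(dih)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_res: int, phi: float = -57.0, psi: float = -47.0):
    """Ideal polypeptide backbone (N, CA, C, O, CB per residue).

    Standard bond geometry with uniform (phi, psi) and trans peptide
    bonds; the alpha-helical default gives the canonical i/i+3, i/i+4
    contact pattern.
    """
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    C = CA + 1.525 * np.array([math.cos(math.radians(180 - 111.0)),
                               math.sin(math.radians(180 - 111.0)), 0.0])
    residues = []
    for i in range(n_res):
        if i > 0:
            N = _place_atom(prev_N, prev_CA, prev_C, 1.329, 116.2, psi)
            CA = _place_atom(prev_CA, prev_C, N, 1.458, 121.7, 180.0)
            C = _place_atom(prev_C, N, CA, 1.525, 111.0, phi)
        O = _place_atom(N, CA, C, 1.231, 120.5, psi + 180.0)
        CB = _place_atom(C, N, CA, 1.526, 110.4, -122.6)
        residues.append({"N": N, "CA": CA, "C": C, "O": O, "CB": CB})
        prev_N, prev_CA, prev_C = N, CA, C
    return residues


def _principal_axis(residues):
    cas = np.array([r["CA"] for r in residues])
    centered = cas - cas.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    return cas.mean(axis=0), axis


def _pdb_atom(serial, name, resname, resseq, xyz, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s}{resname:>3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def gen_toy_structure(n_res: int, geometry: str = "helix", seed: int = 0) -> str:
    """PDB text for an ideal toy structure (single chain of ALA residues).

    ``helix``: one ideal alpha-helix built from standard backbone
    geometry — native 5 A heavy-atom contacts concentrate at sequence
    separations 3-4.  ``helix-hairpin``: two antiparallel ideal helices
    packed side by side (axis separation ~10 A) with a connector residue,
    adding inter-segment contacts.  Deterministic given the arguments
    (``seed`` is accepted for interface uniformity; the geometry is
    noise-free).
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if geometry == "helix":
        residues = _build_backbone(n_res)
    elif geometry == "helix-hairpin":
        h = max((n_res - 1) // 2, 1)
        first = _build_backbone(h)
        second = _build_backbone(max(n_res - h - 1, 1))
        center1, axis1 = _principal_axis(first)
        # orient both helices along z, run the second one antiparallel
        def orient(res_list, axis, center):
            z = np.array([0.0, 0.0, 1.0])
            v = np.cross(axis, z)
            s, c = np.linalg.norm(v), float(axis @ z)
            if s < 1e-12:
                Rm = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
            else:
                vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
                Rm = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
            return [
                {k: Rm @ (p - center) for k, p in r.items()} for r in res_list
            ]

        first = orient(first, axis1, center1)
        center2, axis2 = _principal_axis(second)
        second = orient(second, axis2, center2)
        # flip the second helix and shift it next to the first
        flip = np.diag([1.0, -1.0, -1.0])
        offset = np.array([9.0, 0.0, 0.0])
        second = [{k: flip @ p + offset for k, p in r.items()} for r in second]
        top1 = max(p[2] for r in first for p in r.values())
        connector_z = top1 + 2.0
        conn = {
            "N": np.array([4.0, 0.0, connector_z]),
            "CA": np.array([5.0, 0.5, connector_z + 0.8]),
            "C": np.array([6.0, 0.0, connector_z]),
            "O": np.array([6.3, -1.0, connector_z + 0.3]),
            "CB": np.array([5.0, 1.8, connector_z + 1.5]),
        }
        residues = first + [conn] + second
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    lines = []
    serial = 1
    for i, res in enumerate(residues, start=1):
        for name in ("N", "CA", "C", "O", "CB"):
            element = name[0]
            lines.append(_pdb_atom(serial, name, "ALA", i, res[name], element))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
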