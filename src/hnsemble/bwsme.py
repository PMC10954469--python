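"""Block Wako-Saito-Munoz-Eaton (bWSME) ensemble model.

An Ising-like model of protein folding: each block of consecutive
residues is either folded (1) or unfolded (0), and the allowed
microstates are the fully unfolded state, all single contiguous folded
stretches, and all pairs of disjoint, non-adjacent folded stretches —
for nu blocks that is

    1 + nu (nu + 1) / 2 + C(nu + 1, 4)

states.  The free energy of a microstate (relative to the fully unfolded
reference) collects, over native contacts falling entirely inside folded
stretches, a van der Waals stabilization energy per contact, an implicit
solvation term per contact (a heat-capacity change referenced to
``T_ref_cp``), and Debye-Hueckel screened electrostatics between charged
residues in contact — against an entropic penalty per folded residue.
Boltzmann weighting the ensemble yields residue-resolved folding
probabilities, thermal unfolding curves of structural segments, and
pairwise thermodynamic coupling free energies.

The coupling free energy used here is a log-odds association measure on
the joint folded/unfolded probabilities of a residue pair,

    dG_c(i, j) = R T ln[ P(f_i, f_j) P(u_i, u_j) /
                         (P(f_i, u_j) P(u_i, f_j)) ],

an operational definition: it is zero for thermodynamically independent
residues, positive (maximal on the diagonal) for residues whose folding
status is linked — including linkage through population redistribution
rather than direct contact — and registers as a strongly negative
sentinel for residues that never fold together.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .core_thermo import R

__all__ = [
    "ContactMap",
    "BlockPartition",
    "WSMEParams",
    "Microstate",
    "CouplingMatrix",
    "build_contact_map",
    "charges_from_sequence",
    "enumerate_microstates",
    "microstate_count",
    "microstate_free_energy",
    "partition_and_probabilities",
    "WSMEModel",
    "unfolding_curves",
    "segment_midpoint",
    "calibrate_vdw",
    "coupling_matrix",
    "diff_map",
    "CalibrationError",
]

_AVOGADRO = 6.02214076e23
_E_CHARGE = 1.602176634e-19
_EPS0 = 8.8541878128e-12
_KB = 1.380649e-23
#: e^2 N_A / (4 pi eps0), in J * Angstrom / mol
_COULOMB_J_A_MOL = _E_CHARGE**2 * _AVOGADRO / (4 * math.pi * _EPS0) * 1e10


class CalibrationError(RuntimeError):
    """The vdW calibration target is unreachable within the search bounds."""


# ---------------------------------------------------------------------
# contact map and charges
# ---------------------------------------------------------------------

@dataclass
class ContactMap:
    """Native contacts: per residue pair (i < j, |i-j| >= 2) a heavy-atom
    contact count and the minimal heavy-atom distance (Angstrom)."""

    n_residues: int
    i_idx: np.ndarray  # 1-based
    j_idx: np.ndarray
    counts: np.ndarray
    min_dist: np.ndarray
    cutoff: float = 5.0

    def __post_init__(self):
        self.i_idx = np.asarray(self.i_idx, dtype=int)
        self.j_idx = np.asarray(self.j_idx, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        self.min_dist = np.asarray(self.min_dist, dtype=float)
        if not (self.i_idx.shape == self.j_idx.shape == self.counts.shape
                == self.min_dist.shape):
            raise ValueError("contact arrays must have equal lengths")
        if np.any(self.i_idx >= self.j_idx):
            raise ValueError("contacts must be stored with i < j")
        if np.any(self.j_idx - self.i_idx < 2):
            raise ValueError("contacts require sequence separation >= 2")
        if np.any(self.i_idx < 1) or np.any(self.j_idx > self.n_residues):
            raise ValueError("contact indices out of range")
        pairs = set(zip(self.i_idx.tolist(), self.j_idx.tolist()))
        if len(pairs) != self.i_idx.size:
            raise ValueError("duplicate contact pairs")

    @property
    def n_contacts(self) -> float:
        return float(self.counts.sum())


def build_contact_map(structure, cutoff: float = 5.0) -> ContactMap:
    """Native contact map from PDB coordinates (5 A heavy-atom cutoff).

    ``structure`` is PDB text or a path to a PDB file; the first chain of
    the first model is used.  The contact count of a residue pair is the
    number of heavy-atom pairs within ``cutoff``; pairs with sequence
    separation < 2 are excluded.  Hydrogens are ignored.
    """
    from Bio.PDB import PDBParser
    from scipy.spatial import cKDTree

    parser = PDBParser(QUIET=True)
    if isinstance(structure, str) and "\n" in structure:
        handle = io.StringIO(structure)
    else:
        handle = structure
    model = next(parser.get_structure("s", handle).get_models())
    chain = next(model.get_chains())
    residues = [r for r in chain.get_residues() if r.id[0] == " "]
    if not residues:
        raise ValueError("no standard residues found in the first chain")

    coords, res_of_atom = [], []
    for ri, res in enumerate(residues):
        heavy = [a for a in res.get_atoms() if a.element != "H"]
        if not heavy:
            raise ValueError(f"residue {res.id[1]} has no heavy atoms")
        for a in heavy:
            coords.append(a.coord)
            res_of_atom.append(ri)
    coords = np.asarray(coords, dtype=float)
    res_of_atom = np.asarray(res_of_atom)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        ri = res_of_atom[pairs[:, 0]]
        rj = res_of_atom[pairs[:, 1]]
        lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
        keep = hi - lo >= 2
        lo, hi, pr = lo[keep], hi[keep], pairs[keep]
    else:
        lo = hi = np.array([], dtype=int)
        pr = np.empty((0, 2), dtype=int)

    n = len(residues)
    counts: dict[tuple[int, int], int] = {}
    dmin: dict[tuple[int, int], float] = {}
    if lo.size:
        d = np.linalg.norm(coords[pr[:, 0]] - coords[pr[:, 1]], axis=1)
        for a, b, dist in zip(lo.tolist(), hi.tolist(), d.tolist()):
            key = (a + 1, b + 1)
            counts[key] = counts.get(key, 0) + 1
            dmin[key] = min(dmin.get(key, math.inf), dist)
    else:
        warnings.warn("structure yields zero native contacts", stacklevel=2)
    keys = sorted(counts)
    return ContactMap(
        n_residues=n,
        i_idx=np.array([k[0] for k in keys], dtype=int),
        j_idx=np.array([k[1] for k in keys], dtype=int),
        counts=np.array([counts[k] for k in keys], dtype=float),
        min_dist=np.array([dmin[k] for k in keys], dtype=float),
        cutoff=cutoff,
    )


_CHARGE_BY_AA = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.0}


def charges_from_sequence(seq: str, pH: float = 7.0) -> np.ndarray:
    """Residue charges at pH 7: Asp/Glu -1, Lys/Arg +1, His 0, termini +-1."""
    q = np.array([_CHARGE_BY_AA.get(a, 0.0) for a in seq], dtype=float)
    if q.size:
        q[0] += 1.0   # N-terminal amine
        q[-1] -= 1.0  # C-terminal carboxylate
    return q


# ---------------------------------------------------------------------
# partition into blocks, microstates
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class BlockPartition:
    """Contiguous residue blocks covering 1..n_residues without overlap."""

    blocks: tuple[tuple[int, int], ...]  # 1-based inclusive ranges

    def __post_init__(self):
        prev_end = 0
        for a, b in self.blocks:
            if a != prev_end + 1 or b < a:
                raise ValueError("blocks must be contiguous, ordered, non-empty")
            prev_end = b

    @classmethod
    def uniform(cls, n_residues: int, block_size: int = 2) -> "BlockPartition":
        if n_residues < 1 or block_size < 1:
            raise ValueError("n_residues and block_size must be >= 1")
        blocks = []
        a = 1
        while a <= n_residues:
            b = min(a + block_size - 1, n_residues)
            blocks.append((a, b))
            a = b + 1
        return cls(tuple(blocks))

    @property
    def nu(self) -> int:
        return len(self.blocks)

    @property
    def n_residues(self) -> int:
        return self.blocks[-1][1]

    def block_of_residue(self) -> np.ndarray:
        """0-based block index for each residue (array of length n_residues)."""
        out = np.empty(self.n_residues, dtype=int)
        for k, (a, b) in enumerate(self.blocks):
            out[a - 1 : b] = k
        return out

    def block_sizes(self) -> np.ndarray:
        return np.array([b - a + 1 for a, b in self.blocks], dtype=float)


@dataclass(frozen=True)
class Microstate:
    """Up to two disjoint, non-adjacent folded stretches of block indices.

    Stretches are (first_block, last_block) 0-based inclusive; an empty
    tuple is the fully unfolded reference state.
    """

    stretches: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.stretches) > 2:
            raise ValueError("at most two folded stretches are allowed")
        prev_end = -2
        for a, b in self.stretches:
            if b < a or a < 0:
                raise ValueError("invalid stretch")
            if a <= prev_end + 1:
                raise ValueError("stretches must be disjoint and non-adjacent")
            prev_end = b

    def folded_blocks(self, nu: int) -> np.ndarray:
        mask = np.zeros(nu, dtype=bool)
        for a, b in self.stretches:
            mask[a : b + 1] = True
        return mask


def microstate_count(nu: int, max_stretches: int = 2) -> int:
    """Closed-form ensemble size: 1 + nu(nu+1)/2 [+ C(nu+1, 4)]."""
    n = 1 + nu * (nu + 1) // 2
    if max_stretches == 2:
        n += math.comb(nu + 1, 4)
    return n


def enumerate_microstates(partition: BlockPartition, max_stretches: int = 2):
    """Yield every allowed microstate (unfolded, single-, double-stretch).

    Double stretches require at least one unfolded block between them.
    """
    if max_stretches not in (1, 2):
        raise ValueError("max_stretches must be 1 or 2")
    nu = partition.nu
    yield Microstate(())
    for a in range(nu):
        for b in range(a, nu):
            yield Microstate(((a, b),))
    if max_stretches == 2:
        for a1 in range(nu):
            for b1 in range(a1, nu - 2):
                for a2 in range(b1 + 2, nu):
                    for b2 in range(a2, nu):
                        yield Microstate(((a1, b1), (a2, b2)))


# ---------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class WSMEParams:
    """Energetic parameters of the block-WSME model.

    Defaults: van der Waals energy -102 J/mol per native contact, entropic
    penalty -16.5 J/mol/K per residue, heat-capacity change -0.36
    J/mol/K per contact (implicit solvation, referenced to ``T_ref_cp``),
    Debye-Hueckel electrostatics at 150 mM ionic strength, pH 7,
    dielectric constant 78.5.
    """

    xi_vdw: float = -102.0
    dS_res: float = -16.5
    dCp_cont: float = -0.36
    T_ref_cp: float = 385.0
    ionic_strength: float = 0.150
    pH: float = 7.0
    elec_scale: float = 1.0
    dielectric: float = 78.5

    def __post_init__(self):
        if self.ionic_strength <= 0:
            raise ValueError("ionic strength must be positive (molar)")


def _debye_kappa_inv_A(ionic_strength: float, T: float, dielectric: float) -> float:
    """Inverse Debye length, 1/Angstrom."""
    kappa_sq = (
        2 * _AVOGADRO * _E_CHARGE**2 * ionic_strength * 1000.0
        / (_EPS0 * dielectric * _KB * T)
    )
    return math.sqrt(kappa_sq) * 1e-10


def _solvation_per_contact(params: WSMEParams, T: float) -> float:
    """Implicit-solvation free energy per contact at T (J/mol)."""
    Tr = params.T_ref_cp
    return params.dCp_cont * ((T - Tr) - T * math.log(T / Tr))


def _electrostatic_pair_energy(
    qq: np.ndarray, dist: np.ndarray, params: WSMEParams, T: float
) -> np.ndarray:
    """Screened Coulomb energy (J/mol) for charge products qq at dist (A)."""
    kappa = _debye_kappa_inv_A(params.ionic_strength, T, params.dielectric)
    return (
        params.elec_scale * qq * _COULOMB_J_A_MOL
        / (params.dielectric * dist) * np.exp(-kappa * dist)
    )


def _pair_energies(cmap: ContactMap, charges, params: WSMEParams, T: float):
    """Total interaction energy per contacting residue pair at T (J/mol)."""
    if T <= 200.0 or T >= 500.0:
        raise ValueError("temperature outside the model's (200, 500) K domain")
    eps = params.xi_vdw + _solvation_per_contact(params, T)
    e = cmap.counts * eps
    if charges is not None:
        q = np.asarray(charges, dtype=float)
        qq = q[cmap.i_idx - 1] * q[cmap.j_idx - 1]
        nz = qq != 0
        if nz.any():
            e = e.copy()
            e[nz] += _electrostatic_pair_energy(
                qq[nz], cmap.min_dist[nz], params, T
            )
    return e


def microstate_free_energy(
    state: Microstate,
    cmap: ContactMap,
    charges,
    params: WSMEParams,
    T: float,
    partition: BlockPartition | None = None,
    interacting_stretches: bool = False,
) -> float:
    """Free energy (J/mol) of one microstate relative to the unfolded state.

    Contacts contribute only when both partners lie inside the same
    folded stretch (strict double-sequence approximation); with
    ``interacting_stretches`` contacts spanning the two stretches count
    as well.  Folded residues pay the entropic penalty -T dS_res each.
    The fully unfolded state has exactly zero free energy.
    """
    if partition is None:
        partition = BlockPartition.uniform(cmap.n_residues, 1)
    if not state.stretches:
        return 0.0
    block_of = partition.block_of_residue()
    nu = partition.nu
    folded = state.folded_blocks(nu)
    stretch_id = np.full(nu, -1, dtype=int)
    for s, (a, b) in enumerate(state.stretches):
        stretch_id[a : b + 1] = s

    e_pairs = _pair_energies(cmap, charges, params, T)
    bi = block_of[cmap.i_idx - 1]
    bj = block_of[cmap.j_idx - 1]
    both = folded[bi] & folded[bj]
    same = stretch_id[bi] == stretch_id[bj]
    active = both & same if not interacting_stretches else both
    energy = float(e_pairs[active].sum())

    n_folded = float(partition.block_sizes()[folded].sum())
    return energy - T * params.dS_res * n_folded


def partition_and_probabilities(ensemble, energies, T: float, partition=None):
    """Boltzmann statistics of an explicit (small) ensemble.

    ``ensemble`` is a sequence of :class:`Microstate`; ``energies`` the
    matching free energies (J/mol).  Returns (state_probabilities,
    per_residue_fold_probability); weights are normalized through
    log-sum-exp so low temperatures cannot overflow.
    """
    states = list(ensemble)
    g = np.asarray(energies, dtype=float)
    if g.shape != (len(states),):
        raise ValueError("ensemble and energies are inconsistent")
    logw = -g / (R * T)
    logZ = logsumexp(logw)
    p = np.exp(logw - logZ)
    if partition is None:
        nu = max((b for st in states for _, b in st.stretches), default=0) + 1
        partition = BlockPartition.uniform(nu, 1)
    block_of = partition.block_of_residue()
    res_prob = np.zeros(partition.n_residues)
    for st, pi in zip(states, p):
        mask = st.folded_blocks(partition.nu)
        res_prob += pi * mask[block_of]
    return p, res_prob


# ---------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------

class WSMEModel:
    """bWSME model bound to one structure: contact map, charges, blocks.

    Thermodynamic sums run over the stretch decomposition (the weight of
    a two-stretch state factorizes under the strict double-sequence
    approximation), so residue probabilities cost O(nu^2) per temperature
    and never require materializing the ensemble.
    """

    def __init__(
        self,
        cmap: ContactMap,
        charges=None,
        params: WSMEParams | None = None,
        block_size: int = 2,
        partition: BlockPartition | None = None,
        segments: dict[str, tuple[int, int]] | None = None,
    ):
        self.cmap = cmap
        self.charges = None if charges is None else np.asarray(charges, float)
        if self.charges is not None and self.charges.size != cmap.n_residues:
            raise ValueError("charges length must equal n_residues")
        self.params = params or WSMEParams()
        self.partition = partition or BlockPartition.uniform(
            cmap.n_residues, block_size
        )
        if self.partition.n_residues != cmap.n_residues:
            raise ValueError("partition does not cover the contact map")
        self.segments = segments or {}
        self._block_of = self.partition.block_of_residue()
        self._block_sizes = self.partition.block_sizes()

    # -- low level -----------------------------------------------------
    @property
    def nu(self) -> int:
        return self.partition.nu

    @property
    def n_microstates(self) -> int:
        return microstate_count(self.nu)

    def with_params(self, **updates) -> "WSMEModel":
        return WSMEModel(
            self.cmap, self.charges, replace(self.params, **updates),
            partition=self.partition, segments=self.segments,
        )

    def mutate_charge(self, residue: int, new_charge: float) -> "WSMEModel":
        """Model with the charge at 1-based ``residue`` replaced.

        Encodes point mutations that alter only the ionizable state
        (e.g. a phosphomimetic substitution): the contact topology is
        untouched, only the electrostatic assignments involving the site
        change.
        """
        q = (self.charges.copy() if self.charges is not None
             else np.zeros(self.cmap.n_residues))
        q[residue - 1] = new_charge
        return WSMEModel(self.cmap, q, self.params,
                         partition=self.partition, segments=self.segments)

    def _block_energy_matrix(self, T: float) -> np.ndarray:
        """Symmetric nu x nu matrix of pair energies aggregated by block."""
        e = _pair_energies(self.cmap, self.charges, self.params, T)
        bi = self._block_of[self.cmap.i_idx - 1]
        bj = self._block_of[self.cmap.j_idx - 1]
        nu = self.nu
        M = np.zeros((nu, nu))
        np.add.at(M, (bi, bj), e)
        np.add.at(M, (bj, bi), e)
        M[np.arange(nu), np.arange(nu)] /= 2.0  # within-block pairs counted once
        return M

    def stretch_free_energies(self, T: float) -> np.ndarray:
        """F[a, b]: free energy of the single folded stretch [a..b] (J/mol).

        Entries with a > b are +inf (absent).  Computed by 2D inclusion-
        exclusion over the block energy matrix.
        """
        nu = self.nu
        M = self._block_energy_matrix(T)
        Csum = np.zeros((nu + 1, nu + 1))
        Csum[1:, 1:] = M.cumsum(axis=0).cumsum(axis=1)
        sizes_cum = np.concatenate([[0.0], np.cumsum(self._block_sizes)])
        diag_cum = np.concatenate([[0.0], np.cumsum(np.diag(M))])

        a = np.arange(nu)[:, None]
        b = np.arange(nu)[None, :]
        sq = (Csum[b + 1, b + 1] - Csum[a, b + 1] - Csum[b + 1, a] + Csum[a, a])
        pair_sum = 0.5 * (sq + (diag_cum[b + 1] - diag_cum[a]))
        n_res = sizes_cum[b + 1] - sizes_cum[a]
        F = pair_sum - T * self.params.dS_res * n_res
        F = np.where(b >= a, F, np.inf)
        return F

    def _log_stretch_weights(self, T: float) -> np.ndarray:
        with np.errstate(over="ignore"):
            return -self.stretch_free_energies(T) / (R * T)

    def log_partition(self, T: float) -> float:
        """ln Z over the full ensemble (unfolded reference weight 1)."""
        lw = self._log_stretch_weights(T)
        nu = self.nu
        finite = np.isfinite(lw)
        log_w1 = logsumexp(lw[finite]) if finite.any() else -np.inf
        # suffix log-weights of stretches starting at >= s
        row_ls = logsumexp(lw, axis=1)  # over b for each a
        log_R = np.full(nu + 2, -np.inf)
        for s in range(nu - 1, -1, -1):
            log_R[s] = np.logaddexp(log_R[s + 1], row_ls[s])
        # double-stretch sum: first stretch (a,b), second starts >= b+2
        terms = lw + log_R[np.minimum(np.arange(nu)[None, :] + 2, nu + 1)]
        finite2 = np.isfinite(terms)
        log_w2 = logsumexp(terms[finite2]) if finite2.any() else -np.inf
        return float(logsumexp([0.0, log_w1, log_w2]))

    def block_fold_probabilities(self, T: float) -> np.ndarray:
        """P(block k folded) via stretch-sum recursions (length nu)."""
        lw = self._log_stretch_weights(T)
        nu = self.nu
        row_ls = logsumexp(lw, axis=1)
        log_R = np.full(nu + 2, -np.inf)  # stretches fully inside [s, nu)
        for s in range(nu - 1, -1, -1):
            log_R[s] = np.logaddexp(log_R[s + 1], row_ls[s])
        col_ls = logsumexp(lw, axis=0)
        log_L = np.full(nu + 1, -np.inf)  # stretches fully inside [0, e]
        for e in range(nu):
            log_L[e] = np.logaddexp(log_L[e - 1] if e else -np.inf, col_ls[e])

        a_idx = np.arange(nu)[:, None]
        b_idx = np.arange(nu)[None, :]
        lR = log_R[np.minimum(b_idx + 2, nu + 1)]
        lL_full = np.full((nu, nu), -np.inf)
        if nu > 2:
            lL_full[2:, :] = log_L[a_idx[2:] - 2]
        log_partner = np.logaddexp(lR, lL_full)  # other-stretch weight

        logZ = self.log_partition(T)
        out = np.empty(nu)
        for k in range(nu):
            cover = lw[: k + 1, k:]
            c_single = logsumexp(cover) if cover.size else -np.inf
            c_double_terms = cover + log_partner[: k + 1, k:]
            fin = np.isfinite(c_double_terms)
            c_double = logsumexp(c_double_terms[fin]) if fin.any() else -np.inf
            out[k] = math.exp(np.logaddexp(c_single, c_double) - logZ)
        return out

    def residue_fold_probabilities(self, T: float) -> np.ndarray:
        return self.block_fold_probabilities(T)[self._block_of]

    # -- explicit ensemble (for coupling maps) --------------------------
    def _enumerate_state_arrays(self):
        """(a1, b1, a2, b2) arrays for all states; -1 marks absent stretches."""
        nu = self.nu
        singles = [(a, b, -1, -1) for a in range(nu) for b in range(a, nu)]
        doubles = [
            (a1, b1, a2, b2)
            for a1 in range(nu)
            for b1 in range(a1, nu - 2)
            for a2 in range(b1 + 2, nu)
            for b2 in range(a2, nu)
        ]
        arr = np.array([(-1, -1, -1, -1)] + singles + doubles, dtype=np.int32)
        return arr

    def joint_fold_probabilities(self, T: float):
        """(marginal, joint-ff) block probabilities by full enumeration.

        Returns (p_marginal[nu], P_ff[nu, nu]) where P_ff[k, l] is the
        probability that blocks k and l are folded simultaneously.
        Chunked so the state ensemble never exceeds ~100 MB.
        """
        states = self._enumerate_state_arrays()
        lw = self._log_stretch_weights(T)
        a1, b1, a2, b2 = states.T
        logw = np.zeros(len(states))
        has1 = a1 >= 0
        logw[has1] = lw[a1[has1], b1[has1]]
        has2 = a2 >= 0
        logw[has2] += lw[a2[has2], b2[has2]]
        logZ = logsumexp(logw)
        p = np.exp(logw - logZ)

        nu = self.nu
        ff = np.zeros((nu, nu))
        marg = np.zeros(nu)
        k_idx = np.arange(nu, dtype=np.int32)
        chunk = max(1, 20_000_000 // (8 * nu))
        for s in range(0, len(states), chunk):
            sl = slice(s, s + chunk)
            X = (
                ((k_idx >= a1[sl, None]) & (k_idx <= b1[sl, None]))
                | ((a2[sl, None] >= 0) & (k_idx >= a2[sl, None])
                   & (k_idx <= b2[sl, None]))
            ).astype(float)
            Xw = X * p[sl, None]
            ff += Xw.T @ X
            marg += Xw.sum(axis=0)
        return marg, ff


# ---------------------------------------------------------------------
# derived observables
# ---------------------------------------------------------------------

def unfolding_curves(
    model: WSMEModel, T_grid, segments: dict[str, tuple[int, int]] | None = None
) -> dict[str, np.ndarray]:
    """Mean residue folding probability per segment across temperatures.

    ``segments`` maps names to 1-based inclusive residue ranges; the
    model's own segments are used when omitted.
    """
    segments = segments or model.segments
    if not segments:
        raise ValueError("no segments defined")
    for name, (a, b) in segments.items():
        if b < a or a < 1 or b > model.cmap.n_residues:
            raise ValueError(f"segment {name!r} is empty or out of range")
    T_grid = np.asarray(T_grid, dtype=float)
    curves = {name: np.empty(T_grid.size) for name in segments}
    for t, T in enumerate(T_grid):
        rp = model.residue_fold_probabilities(float(T))
        for name, (a, b) in segments.items():
            curves[name][t] = rp[a - 1 : b].mean()
    return curves


def segment_midpoint(
    model: WSMEModel,
    segment: tuple[int, int],
    T_lo: float = 250.0,
    T_hi: float = 480.0,
) -> float:
    """Temperature at which the segment's mean fold probability crosses 1/2.

    Returns NaN when the segment never reaches one-half stability in the
    search window (e.g. an always-unfolded linker).
    """
    a, b = segment

    def f(T):
        return model.residue_fold_probabilities(T)[a - 1 : b].mean() - 0.5

    lo, hi = f(T_lo), f(T_hi)
    if lo < 0:  # not even folded at the cold end
        return float("nan")
    if hi > 0:  # never melts inside the window
        return float("nan")
    return float(brentq(f, T_lo, T_hi, xtol=1e-3))


def calibrate_vdw(
    model: WSMEModel,
    target_Tm: float,
    segment: tuple[int, int],
    xi_bounds: tuple[float, float] = (-400.0, -5.0),
    tol: float = 0.1,
    max_iter: int = 100,
) -> float:
    """van der Waals energy per contact that puts a segment's melting
    temperature at ``target_Tm`` (bisection, 0.1 K tolerance).

    The segment midpoint is monotone in the contact strength, so a sign
    change over ``xi_bounds`` brackets the solution; an unreachable
    target raises :class:`CalibrationError`.
    """
    if not (290.0 < target_Tm < 380.0):
        raise ValueError("target melting temperature outside (290, 380) K")

    def midpoint(xi):
        m = model.with_params(xi_vdw=xi)
        tm = segment_midpoint(m, segment)
        if math.isnan(tm):
            # segment entirely unstable (midpoint below window) or
            # entirely stable; map to the window edge for bracketing
            p_cold = m.residue_fold_probabilities(260.0)[
                segment[0] - 1 : segment[1]
            ].mean()
            return 480.0 if p_cold > 0.5 else 250.0
        return tm

    lo, hi = xi_bounds  # lo: strong contacts (high Tm), hi: weak (low Tm)
    f_lo = midpoint(lo) - target_Tm
    f_hi = midpoint(hi) - target_Tm
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target {target_Tm} K unreachable for xi in {xi_bounds}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = midpoint(mid) - target_Tm
        if abs(fm) < tol:
            return mid
        if (fm > 0) == (f_lo > 0):
            lo, f_lo = mid, fm
        else:
            hi, f_hi = mid, fm
    raise CalibrationError("bisection did not reach tolerance")


@dataclass
class CouplingMatrix:
    """Residue-pair coupling free energies dG_c (kJ/mol) at temperature T.

    ``flags`` marks entries where a joint probability vanished and the
    value is a signed-infinity sentinel.
    """

    values: np.ndarray
    T: float
    flags: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("coupling matrix must be square")


def coupling_matrix(model: WSMEModel, T: float, p_floor: float = 0.0) -> CouplingMatrix:
    """Pairwise coupling free-energy map at temperature T.

    dG_c(i, j) = R T ln[P_ff P_uu / (P_fu P_uf)] on the joint block
    fold/unfold probabilities, expanded to residue resolution.  Positive
    values mean the two residues fold and unfold together; the diagonal
    (self-coupling) is +inf by construction and flagged.  Pairs with any
    vanishing joint probability (after optional flooring by ``p_floor``)
    are sentinels: +inf when the pair is perfectly correlated, -inf when
    the two residues never fold together.
    """
    marg, ff = model.joint_fold_probabilities(T)
    pi = marg[:, None]
    pj = marg[None, :]
    p_ff = ff
    p_fu = np.clip(pi - ff, 0.0, 1.0)
    p_uf = np.clip(pj - ff, 0.0, 1.0)
    p_uu = np.clip(1.0 - pi - pj + ff, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.where(p_ff > p_floor, p_ff, 0.0) * np.where(
            p_uu > p_floor, p_uu, 0.0
        )
        den = np.where(p_fu > p_floor, p_fu, 0.0) * np.where(
            p_uf > p_floor, p_uf, 0.0
        )
        vals = R * T * (np.log(num) - np.log(den)) / 1000.0
    flags = ~np.isfinite(vals)
    vals = np.where(np.isnan(vals), -np.inf, vals)  # 0/0: disjoint support
    block_of = model._block_of
    return CouplingMatrix(values=vals[np.ix_(block_of, block_of)], T=T,
                          flags=flags[np.ix_(block_of, block_of)])


def diff_map(m1: CouplingMatrix, m2: CouplingMatrix):
    """Elementwise coupling difference m1 - m2 and per-residue extremum.

    Returns (ddG matrix, per-residue signed extremum over partners),
    ignoring sentinel entries.  Identical models give exactly zero.
    """
    if m1.values.shape != m2.values.shape:
        raise ValueError("coupling matrices have different sizes")
    both_finite = np.isfinite(m1.values) & np.isfinite(m2.values)
    dd = np.zeros_like(m1.values)
    dd[both_finite] = m1.values[both_finite] - m2.values[both_finite]
    n = dd.shape[0]
    extremum = np.zeros(n)
    for i in range(n):
        row = dd[i]
        mask = both_finite[i].copy()
        mask[i] = False
        if mask.any():
            j = np.argmax(np.abs(np.where(mask, row, 0.0)))
            extremum[i] = row[j]
    return dd, extremum
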