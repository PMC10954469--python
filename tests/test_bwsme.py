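"""Block-WSME model: enumeration, energetics, probabilities, calibration
and coupling maps."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp

from hnsemble.bwsme import (
    BlockPartition,
    CalibrationError,
    ContactMap,
    Microstate,
    WSMEModel,
    WSMEParams,
    build_contact_map,
    calibrate_vdw,
    charges_from_sequence,
    coupling_matrix,
    diff_map,
    enumerate_microstates,
    microstate_count,
    microstate_free_energy,
    partition_and_probabilities,
    segment_midpoint,
    unfolding_curves,
)
from hnsemble.core_thermo import R
from hnsemble.synth import gen_toy_structure


def _toy_map(n_res, pairs):
    """ContactMap from {(i, j): count} with a fixed 4.5 A distance."""
    keys = sorted(pairs)
    return ContactMap(
        n_residues=n_res,
        i_idx=np.array([k[0] for k in keys]),
        j_idx=np.array([k[1] for k in keys]),
        counts=np.array([pairs[k] for k in keys], dtype=float),
        min_dist=np.full(len(keys), 4.5),
    )


class TestEnumeration:
    @pytest.mark.parametrize("nu,expected", [(1, 2), (3, 8), (4, 16)])
    def test_small_counts(self, nu, expected):
        part = BlockPartition.uniform(nu, 1)
        states = list(enumerate_microstates(part))
        assert len(states) == expected == microstate_count(nu)

    @pytest.mark.parametrize("nu", range(1, 9))
    def test_exhaustive_generation_matches_closed_form(self, nu):
        part = BlockPartition.uniform(nu, 1)
        states = list(enumerate_microstates(part))
        assert len(states) == microstate_count(nu)
        assert len(states) == 1 + nu * (nu + 1) // 2 + math.comb(nu + 1, 4)
        # no duplicates, all valid
        assert len({s.stretches for s in states}) == len(states)

    def test_single_stretch_mode(self):
        part = BlockPartition.uniform(5, 1)
        states = list(enumerate_microstates(part, max_stretches=1))
        assert len(states) == microstate_count(5, max_stretches=1) == 16

    def test_unsupported_stretch_count(self):
        part = BlockPartition.uniform(3, 1)
        with pytest.raises(ValueError):
            list(enumerate_microstates(part, max_stretches=3))

    def test_invalid_microstates_rejected(self):
        with pytest.raises(ValueError):
            Microstate(((0, 2), (3, 5)))  # adjacent stretches
        with pytest.raises(ValueError):
            Microstate(((2, 1),))


class TestContactMap:
    def test_ideal_helix_contacts_concentrate_at_sep_3_4(self):
        cmap = build_contact_map(gen_toy_structure(12, "helix"))
        seps = cmap.j_idx - cmap.i_idx
        local = cmap.counts[(seps == 3) | (seps == 4)].sum()
        assert local > 0.5 * cmap.counts.sum()
        assert np.all(seps >= 2)

    def test_distant_residues_have_no_contact(self):
        cmap = build_contact_map(gen_toy_structure(30, "helix"))
        seps = cmap.j_idx - cmap.i_idx
        assert seps.max() <= 5  # a straight helix has no long-range contacts

    def test_hairpin_adds_intersegment_contacts(self):
        n = 25
        cmap = build_contact_map(gen_toy_structure(n, "helix-hairpin"))
        h = (n - 1) // 2
        inter = (cmap.i_idx <= h) & (cmap.j_idx > h + 1)
        assert inter.sum() > 0

    def test_doubling_cutoff_never_decreases_counts(self):
        pdb = gen_toy_structure(15, "helix")
        c5 = build_contact_map(pdb, cutoff=5.0)
        c10 = build_contact_map(pdb, cutoff=10.0)
        lut = {(i, j): c for i, j, c in zip(c10.i_idx, c10.j_idx, c10.counts)}
        for i, j, c in zip(c5.i_idx, c5.j_idx, c5.counts):
            assert lut.get((i, j), 0) >= c

    def test_single_residue_has_no_contacts(self):
        with pytest.warns(UserWarning, match="zero native contacts"):
            cmap = build_contact_map(gen_toy_structure(1, "helix"))
        assert cmap.i_idx.size == 0


class TestMicrostateFreeEnergy:
    def test_unfolded_reference_is_zero(self):
        cmap = _toy_map(6, {(1, 4): 3.0})
        part = BlockPartition.uniform(6, 2)
        for T in (280.0, 310.0, 400.0):
            assert microstate_free_energy(
                Microstate(()), cmap, None, WSMEParams(), T, part
            ) == 0.0

    def test_contact_free_stretch_is_pure_entropy(self):
        cmap = _toy_map(6, {(1, 6): 2.0})  # contact outside the stretch
        part = BlockPartition.uniform(6, 1)
        params = WSMEParams()
        T = 310.0
        g = microstate_free_energy(
            Microstate(((2, 3),)), cmap, None, params, T, part
        )
        assert g == pytest.approx(-T * params.dS_res * 2, rel=1e-12)
        assert g > 0  # entropic penalty opposes folding

    def test_manual_arithmetic_on_three_block_toy(self):
        # 6 residues in 3 blocks; contacts (1,4):2 and (2,6):1; charges
        # on residues 1 (+1) and 4 (-1); fold blocks 1-2 (residues 1-4)
        cmap = _toy_map(6, {(1, 4): 2.0, (2, 6): 1.0})
        part = BlockPartition.uniform(6, 2)
        charges = np.array([1.0, 0, 0, -1.0, 0, 0])
        params = WSMEParams()
        T = 298.15
        from hnsemble.bwsme import (
            _debye_kappa_inv_A,
            _COULOMB_J_A_MOL,
            _solvation_per_contact,
        )

        eps = params.xi_vdw + _solvation_per_contact(params, T)
        kappa = _debye_kappa_inv_A(params.ionic_strength, T, params.dielectric)
        elec = (-1.0) * _COULOMB_J_A_MOL / (params.dielectric * 4.5) * math.exp(
            -kappa * 4.5
        )
        expected = 2.0 * eps + elec - T * params.dS_res * 4
        got = microstate_free_energy(
            Microstate(((0, 1),)), cmap, charges, params, T, part
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_cross_stretch_contacts_excluded_by_default(self):
        cmap = _toy_map(6, {(1, 6): 5.0})
        part = BlockPartition.uniform(6, 2)
        params = WSMEParams()
        state = Microstate(((0, 0), (2, 2)))  # blocks 1 and 3 folded
        g_strict = microstate_free_energy(state, cmap, None, params, 300.0, part)
        g_inter = microstate_free_energy(
            state, cmap, None, params, 300.0, part, interacting_stretches=True
        )
        assert g_strict == pytest.approx(-300.0 * params.dS_res * 4, rel=1e-12)
        assert g_inter < g_strict  # the contact now stabilizes

    def test_temperature_domain_enforced(self):
        cmap = _toy_map(4, {(1, 3): 1.0})
        with pytest.raises(ValueError, match="temperature"):
            microstate_free_energy(
                Microstate(((0, 1),)), cmap, None, WSMEParams(), 150.0,
                BlockPartition.uniform(4, 2),
            )


class TestProbabilities:
    def test_equal_energies_give_uniform_distribution(self):
        part = BlockPartition.uniform(3, 1)
        states = list(enumerate_microstates(part))
        p, _ = partition_and_probabilities(states, np.zeros(len(states)), 300.0,
                                           part)
        np.testing.assert_allclose(p, 1.0 / len(states))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_ground_state_dominates_at_low_temperature(self):
        part = BlockPartition.uniform(3, 1)
        states = list(enumerate_microstates(part))
        energies = np.zeros(len(states))
        full = next(
            i for i, s in enumerate(states) if s.stretches == ((0, 2),)
        )
        energies[full] = -5e4
        p, res = partition_and_probabilities(states, energies, 210.0, part)
        assert p[full] > 0.999
        assert np.all(res > 0.999)

    def test_fast_path_matches_explicit_enumeration(self):
        cmap = build_contact_map(gen_toy_structure(12, "helix"))
        model = WSMEModel(cmap, block_size=2)
        states = list(enumerate_microstates(model.partition))
        energies = [
            microstate_free_energy(s, cmap, None, model.params, 320.0,
                                   model.partition)
            for s in states
        ]
        p, res = partition_and_probabilities(states, energies, 320.0,
                                             model.partition)
        np.testing.assert_allclose(
            res, model.residue_fold_probabilities(320.0), atol=1e-12
        )
        logZ = logsumexp(-np.asarray(energies) / (R * 320.0))
        assert model.log_partition(320.0) == pytest.approx(logZ, abs=1e-10)

    def test_unfolded_state_is_ground_state_without_contacts(self):
        # xi = 0 and no electrostatics: entropy alone must keep every
        # stretch free energy positive at any T
        cmap = _toy_map(8, {(1, 5): 3.0})
        model = WSMEModel(
            cmap, params=WSMEParams(xi_vdw=0.0, dCp_cont=0.0), block_size=2
        )
        for T in (250.0, 300.0, 450.0):
            F = model.stretch_free_energies(T)
            assert np.all(F[np.isfinite(F)] > 0)
            assert np.all(model.residue_fold_probabilities(T) < 0.5)


class TestUnfoldingAndCalibration:
    def _two_domain_model(self, dense=(34.0, 38.0), sparse=(30.0, 34.0)):
        pairs = {}
        for i in range(1, 9):  # domain A: residues 1-10, densely packed
            for sep, c in zip((2, 3), dense):
                if i + sep <= 10:
                    pairs[(i, i + sep)] = c
        for i in range(11, 19):  # domain B: residues 11-20, sparser
            for sep, c in zip((2, 3), sparse):
                if i + sep <= 20:
                    pairs[(i, i + sep)] = c
        cmap = _toy_map(20, pairs)
        return WSMEModel(cmap, block_size=2,
                         segments={"A": (1, 10), "B": (11, 20)})

    def test_curves_non_increasing_and_bounded(self):
        model = self._two_domain_model()
        T = np.linspace(260.0, 440.0, 19)
        curves = unfolding_curves(model, T)
        for c in curves.values():
            assert np.all(c >= 0) and np.all(c <= 1)
            assert np.all(np.diff(c) <= 1e-6)

    def test_denser_domain_has_higher_midpoint(self):
        model = self._two_domain_model()
        tm_a = segment_midpoint(model, (1, 10))
        tm_b = segment_midpoint(model, (11, 20))
        assert tm_a > tm_b

    def test_empty_segment_rejected(self):
        model = self._two_domain_model()
        with pytest.raises(ValueError):
            unfolding_curves(model, [300.0], {"bad": (5, 3)})

    def test_calibration_fixed_point(self):
        model = self._two_domain_model()
        tm = segment_midpoint(model, (1, 10))
        xi = calibrate_vdw(model, tm, (1, 10))
        assert xi == pytest.approx(model.params.xi_vdw, abs=2.0)

    def test_raising_target_strengthens_contacts(self):
        model = self._two_domain_model()
        tm = segment_midpoint(model, (1, 10))
        xi_0 = calibrate_vdw(model, tm, (1, 10))
        xi_up = calibrate_vdw(model, tm + 5.0, (1, 10))
        assert xi_up < xi_0  # more negative = stronger

    def test_unreachable_target_raises(self):
        model = self._two_domain_model()
        with pytest.raises(CalibrationError):
            calibrate_vdw(model, 379.9, (1, 10), xi_bounds=(-20.0, -5.0))


@pytest.fixture(scope="module")
def hns():
    from hnsemble.bwsme_hns import hns_model

    return hns_model()


class TestHNSModel:
    def test_dbd_calibrated_to_57C(self, hns):
        from hnsemble.bwsme_hns import DBD_TM_K, HNS_SEGMENTS

        tm = segment_midpoint(hns, HNS_SEGMENTS["dbd"])
        assert tm == pytest.approx(DBD_TM_K, abs=0.5)

    def test_segment_stability_ordering(self, hns):
        from hnsemble.bwsme_hns import HNS_SEGMENTS

        mids = {}
        for name, seg in HNS_SEGMENTS.items():
            tm = segment_midpoint(hns, seg)
            mids[name] = -np.inf if math.isnan(tm) else tm
        assert (
            mids["linker"]
            < mids["dimerization"]
            < mids["dbd"]
            <= mids["backbone_helix"]
        )

    def test_sequence_and_mutation_site(self):
        from hnsemble.bwsme_hns import HNS_SEQUENCE

        assert len(HNS_SEQUENCE) == 137
        assert HNS_SEQUENCE[60] == "Y"   # Y61
        assert HNS_SEQUENCE[108] == "W"  # W109
        assert HNS_SEQUENCE[20:26] == "CTLETL"  # protease-recognition motif

    def test_lon_motif_folding_decreases_with_temperature(self, hns):
        T = np.array([288.15, 298.15, 310.15, 320.15])
        curves = unfolding_curves(hns, T, {"ctletl": (21, 26)})["ctletl"]
        assert np.all(np.diff(curves) < 0)


class TestCoupling:
    def test_independent_two_block_model_has_zero_coupling(self):
        # one block per domain, no inter-block contacts, no charges:
        # the joint probabilities factorize and dG_c vanishes off-diagonal
        pairs = {(1, 3): 8.0, (2, 4): 8.0, (7, 9): 8.0, (8, 10): 8.0}
        cmap = _toy_map(10, pairs)
        part = BlockPartition(((1, 5), (6, 10)))
        model = WSMEModel(cmap, partition=part)
        cm = coupling_matrix(model, 310.0)
        off = cm.values[:5, 5:]
        assert np.all(np.isfinite(off))
        assert np.all(np.abs(off) < 1e-9)

    def test_diagonal_is_maximal_sentinel(self):
        cmap = _toy_map(6, {(1, 4): 4.0, (2, 5): 4.0})
        model = WSMEModel(cmap, block_size=2)
        cm = coupling_matrix(model, 300.0)
        assert np.all(np.isposinf(np.diag(cm.values)))
        assert np.all(cm.flags[np.diag_indices(6)])

    def test_coupled_neighbours_are_positive(self):
        cmap = _toy_map(6, {(1, 4): 6.0, (2, 5): 6.0, (3, 6): 6.0})
        model = WSMEModel(cmap, block_size=2)
        cm = coupling_matrix(model, 300.0)
        vals = cm.values.copy()
        np.fill_diagonal(vals, np.nan)
        finite = np.isfinite(vals)
        assert np.nanmax(vals[finite]) > 0

    def test_identical_models_give_zero_difference(self):
        cmap = _toy_map(8, {(1, 4): 5.0, (3, 7): 5.0})
        model = WSMEModel(cmap, block_size=2)
        cm = coupling_matrix(model, 300.0)
        dd, extremum = diff_map(cm, cm)
        np.testing.assert_allclose(dd, 0.0)
        np.testing.assert_allclose(extremum, 0.0)

    def test_charge_mutation_changes_only_its_electrostatics(self):
        cmap = _toy_map(8, {(1, 4): 5.0, (3, 7): 5.0, (5, 8): 5.0})
        charges = np.zeros(8)
        charges[6] = 1.0  # residue 7, a contact partner of residue 3
        model = WSMEModel(cmap, charges, block_size=2)
        same = model.mutate_charge(2, 0.0)  # no-op mutation
        cm1 = coupling_matrix(model, 300.0)
        cm2 = coupling_matrix(same, 300.0)
        dd, _ = diff_map(cm2, cm1)
        np.testing.assert_allclose(dd, 0.0, atol=1e-12)
        # a real charge change at residue 3 (contacting charged 7) shifts
        # the map
        mutant = model.mutate_charge(3, -1.0)
        cm3 = coupling_matrix(mutant, 300.0)
        dd2, _ = diff_map(cm3, cm1)
        assert np.nanmax(np.abs(dd2)) > 0

    def test_y61e_difference_map_is_nonzero_and_wt_matches_itself(self):
        from hnsemble.bwsme_hns import hns_model, y61e_model

        wt = hns_model(block_size=6, calibrate=False)
        mut = y61e_model(wt)
        T = 298.15
        cm_wt = coupling_matrix(wt, T)
        cm_mut = coupling_matrix(mut, T)
        dd, extremum = diff_map(cm_mut, cm_wt)
        assert np.nanmax(np.abs(dd)) > 0
        assert extremum.shape == (137,)
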