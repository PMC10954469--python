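"""H-NS monomer model for the bWSME ensemble.

The 137-residue H-NS protomer divides into four structural elements: the
N-terminal dimerization site, the long backbone helix carrying the
oligomerization surface at its C-terminal end, a flexible linker, and
the C-terminal DNA-binding domain (DBD).

No experimental coordinate set of the full-length monomer is available
to this package, so the model is built from a SYNTHETIC contact map
(:func:`synthetic_hns_contact_map`): helical i/i+2,3,4 heavy-atom
contact counts assigned per segment to encode the qualitative stability
pattern of the protein — the linker is flexible (no native contacts),
the dimerization site is marginally stable, the backbone helix has high
intrinsic helical propensity (densest local packing), and the DBD is an
independently folding unit with additional tertiary (hairpin-like)
contacts.  Charges come from the real sequence.  Following the
experimental observation that the DBD melts at 57 C independent of
concentration, the van der Waals energy per contact is calibrated to
reproduce that midpoint; every other parameter keeps its default.

The Y61E phosphomimetic mutant is encoded as a charge substitution at
position 61 (tyrosine, neutral, to glutamate, -1): the contact topology
is kept, only electrostatic assignments involving the site change.
"""

from __future__ import annotations

import numpy as np

from .bwsme import (
    ContactMap,
    WSMEModel,
    WSMEParams,
    calibrate_vdw,
    charges_from_sequence,
)

__all__ = [
    "HNS_SEQUENCE",
    "HNS_SEGMENTS",
    "DBD_TM_K",
    "synthetic_hns_contact_map",
    "hns_model",
    "y61e_model",
]

#: Full-length E. coli H-NS sequence (137 residues).
HNS_SEQUENCE = (
    "MSEALKILNNIRTLRAQARECTLETLEEMLEKLEVVVNERREEESAAAAEVEERTRKLQQ"
    "YREMLIADGIDPNELLNSLAAVKSGTKAKRAQRPAKYSYVDENGETKTWTGQGRTPAVIK"
    "KAMDEQGKSLDDFLIKQ"
)

#: Structural elements, 1-based inclusive residue ranges.
HNS_SEGMENTS = {
    "dimerization": (1, 44),
    "backbone_helix": (45, 83),
    "linker": (84, 94),
    "dbd": (95, 137),
}

#: Concentration-independent DBD melting temperature (57 C).
DBD_TM_K = 330.15

# per-segment helical heavy-atom contact counts at separations (2, 3, 4);
# densities scale with the qualitative stability of each element
_HELICAL_COUNTS = {
    "dimerization": (10, 23, 26),
    "backbone_helix": (11, 27, 31),
    "dbd": (8, 20, 24),
}
# DBD tertiary hairpin: residue k pairs with (232 - k), count per pair
_DBD_HAIRPIN_COUNT = 8
_SYNTHETIC_MIN_DIST = 4.5  # representative contact distance, Angstrom


def synthetic_hns_contact_map() -> ContactMap:
    """SYNTHETIC native contact map for the H-NS monomer (see module docs).

    Helical contacts live inside each structured segment; the linker has
    none; the DBD additionally folds back on itself hairpin-fashion.
    """
    n = len(HNS_SEQUENCE)
    pairs: dict[tuple[int, int], float] = {}
    for seg, counts in _HELICAL_COUNTS.items():
        a, b = HNS_SEGMENTS[seg]
        for sep, cnt in zip((2, 3, 4), counts):
            for i in range(a, b - sep + 1):
                pairs[(i, i + sep)] = pairs.get((i, i + sep), 0.0) + cnt
    a, b = HNS_SEGMENTS["dbd"]
    for i in range(a, a + (b - a) // 2):
        j = (a + b) - i
        if j - i >= 2 and j <= b:
            pairs[(i, j)] = pairs.get((i, j), 0.0) + _DBD_HAIRPIN_COUNT
    keys = sorted(pairs)
    return ContactMap(
        n_residues=n,
        i_idx=np.array([k[0] for k in keys]),
        j_idx=np.array([k[1] for k in keys]),
        counts=np.array([pairs[k] for k in keys]),
        min_dist=np.full(len(keys), _SYNTHETIC_MIN_DIST),
        cutoff=5.0,
    )


def hns_model(
    block_size: int = 2,
    params: WSMEParams | None = None,
    calibrate: bool = True,
) -> WSMEModel:
    """Calibrated bWSME model of the wild-type H-NS monomer.

    With ``calibrate`` the van der Waals energy per contact is adjusted
    by bisection so the DBD melts at 57 C, mirroring how the model's one
    free energy scale is pinned experimentally.
    """
    model = WSMEModel(
        synthetic_hns_contact_map(),
        charges=charges_from_sequence(HNS_SEQUENCE),
        params=params or WSMEParams(),
        block_size=block_size,
        segments=HNS_SEGMENTS,
    )
    if calibrate:
        xi = calibrate_vdw(model, DBD_TM_K, HNS_SEGMENTS["dbd"])
        model = model.with_params(xi_vdw=xi)
    return model


def y61e_model(wt: WSMEModel) -> WSMEModel:
    """Y61E phosphomimetic variant of a wild-type H-NS model."""
    if HNS_SEQUENCE[60] != "Y":
        raise AssertionError("position 61 is not tyrosine")  # pragma: no cover
    return wt.mutate_charge(61, -1.0)
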