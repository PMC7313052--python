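"""Rigid-body kinematics of the cytosolic headpiece.

Every structure is first superposed onto the reference (the Ca2+-bound E1
state, 2c9m by convention) over the C-alpha atoms of the TM7-TM10 anchor,
the structurally rigid luminal region. In that common frame, each cytosolic
domain (A, N, P) is Kabsch-fitted from the reference onto the target; the
resulting operator gives the domain's rotation angle and axis, and the
centre-of-geometry (COG) shift gives its displacement distance. The sense
of rotation (clockwise / counterclockwise) is defined viewing from the
cytosol down the membrane normal: a rotation whose axis points against the
normal is clockwise from that viewpoint.

Also provided: inter-domain COG distances (A-N, A-P, N-P) and the
Met1-Asn510 C-alpha distance, a structural proxy for intramolecular FRET
between headpiece-attached fluorophores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import kabsch_superpose, rotation_angle_axis
from .structure import DOMAINS, DomainDefinition, Structure, common_residues, select_coordinates

__all__ = [
    "RigidBodyTransform",
    "anchor_align",
    "domain_transform",
    "cog_distance",
    "residue_pair_distance",
    "HeadpieceKinematics",
    "MEMBRANE_NORMAL",
]

#: Membrane normal of the packaged reference frame: the +z axis of a
#: pre-oriented reference structure, pointing toward the cytosol.
MEMBRANE_NORMAL = np.array([0.0, 0.0, 1.0])

_MIN_ANCHOR_RESIDUES = 10


@dataclass(frozen=True)
class RigidBodyTransform:
    """Rigid-body motion of one domain relative to the reference.

    ``rotation_angle`` is in [0, 180] degrees; flipping ``rotation_axis``
    flips ``sense``. ``displacement`` is the COG shift in Angstrom;
    ``screw_translation`` is the component of that shift along the rotation
    axis (the translation of the equivalent screw motion).
    """

    domain: str
    rotation_angle: float
    rotation_axis: np.ndarray
    sense: str  # "clockwise" | "counterclockwise"
    displacement: float
    screw_translation: float


def anchor_align(
    s: Structure,
    reference: Structure,
    anchor: DomainDefinition = DOMAINS["anchor"],
) -> Structure:
    """Rigidly transform ``s`` so its anchor C-alpha set fits the reference's."""
    shared = common_residues([s, reference], anchor)
    if len(shared) < _MIN_ANCHOR_RESIDUES:
        raise ValueError(
            f"{s.id}: only {len(shared)} common anchor residues with {reference.id} "
            f"(need >= {_MIN_ANCHOR_RESIDUES})"
        )
    region = DomainDefinition("_anchor", tuple((r, r) for r in shared))
    mob = select_coordinates(s, region, atoms="CA")
    tgt = select_coordinates(reference, region, atoms="CA")
    fit = kabsch_superpose(mob.coords, tgt.coords)
    return s.transformed(fit.rotation, fit.translation)


def domain_transform(
    s_aligned: Structure,
    reference: Structure,
    d: DomainDefinition,
    membrane_normal: np.ndarray = MEMBRANE_NORMAL,
) -> RigidBodyTransform:
    """Rotation angle/axis/sense and COG displacement of a domain.

    ``s_aligned`` must already be in the reference frame (see
    :func:`anchor_align`); the Kabsch fit of the reference domain's C-alpha
    set onto the target's yields the rotation operator.
    """
    shared = common_residues([s_aligned, reference], d)
    if len(shared) < _MIN_ANCHOR_RESIDUES:
        raise ValueError(f"domain {d.name}: only {len(shared)} common residues")
    region = DomainDefinition("_dom", tuple((r, r) for r in shared))
    ref_sel = select_coordinates(reference, region, atoms="CA")
    tgt_sel = select_coordinates(s_aligned, region, atoms="CA")
    fit = kabsch_superpose(ref_sel.coords, tgt_sel.coords)
    angle, axis = rotation_angle_axis(fit.rotation)
    normal = np.asarray(membrane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    sense = "clockwise" if float(np.dot(axis, normal)) < 0 else "counterclockwise"
    cog_shift = tgt_sel.coords.mean(axis=0) - ref_sel.coords.mean(axis=0)
    return RigidBodyTransform(
        domain=d.name,
        rotation_angle=angle,
        rotation_axis=axis,
        sense=sense,
        displacement=float(np.linalg.norm(cog_shift)),
        screw_translation=float(np.dot(cog_shift, axis)),
    )


def cog_distance(s: Structure, d1: DomainDefinition, d2: DomainDefinition) -> float:
    """Distance (Angstrom) between unweighted C-alpha centroids of two domains."""
    c1 = select_coordinates(s, d1, atoms="CA").coords.mean(axis=0)
    c2 = select_coordinates(s, d2, atoms="CA").coords.mean(axis=0)
    return float(np.linalg.norm(c1 - c2))


def residue_pair_distance(
    s: Structure, res_a: int = 1, res_b: int = 510, atom: str = "CA"
) -> float:
    """Distance (Angstrom) between named atoms of two residues.

    The default pair, Met1-Asn510, tracks headpiece opening and is the
    structural counterpart of the intramolecular FRET distance.
    """
    return float(np.linalg.norm(s.atom_coord(res_a, atom) - s.atom_coord(res_b, atom)))


class HeadpieceKinematics(TransformerMixin, BaseEstimator):
    """Per-structure headpiece kinematics table, sklearn-transformer shaped.

    Parameters
    ----------
    reference : Structure or None
        Reference structure (anchor frame and domain fit origin). May also
        be supplied to :meth:`fit` as the first element of ``X`` when None.
    domains : dict[str, DomainDefinition] or None
        Domain table; defaults to the packaged A/N/P + anchor definitions.
    membrane_normal : array-like
        Unit membrane normal of the reference frame.
    fret_pair : tuple[int, int]
        Residue pair for the FRET-proxy distance (default Met1-Asn510).

    ``transform`` returns a long-format DataFrame with one row per
    (structure, domain): rotation angle (deg), sense, displacement (A),
    screw translation (A), the three inter-domain COG distances (A) and the
    FRET-proxy distance (A).
    """

    def __init__(
        self,
        reference: Structure | None = None,
        domains: dict[str, DomainDefinition] | None = None,
        membrane_normal=(0.0, 0.0, 1.0),
        fret_pair: tuple[int, int] = (1, 510),
    ):
        self.reference = reference
        self.domains = domains
        self.membrane_normal = membrane_normal
        self.fret_pair = fret_pair

    def _tables(self):
        domains = dict(self.domains) if self.domains is not None else dict(DOMAINS)
        anchor = domains.pop("anchor", DOMAINS["anchor"])
        return domains, anchor

    def fit(self, X=None, y=None):
        """Validate the reference and domain tables; X is unused unless the
        reference was not given at construction, in which case ``X[0]`` is taken."""
        if self.reference is not None:
            self.reference_ = self.reference
        elif X:
            self.reference_ = list(X)[0]
        else:
            raise ValueError("a reference structure is required")
        domains, anchor = self._tables()
        self.domains_ = domains
        self.anchor_ = anchor
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "reference_"):
            self.fit(X)
        normal = np.asarray(self.membrane_normal, dtype=float)
        rows = []
        for s in X:
            aligned = anchor_align(s, self.reference_, self.anchor_)
            names = list(self.domains_)
            cogs = {
                f"cog_{a}{b}_A": cog_distance(aligned, self.domains_[a], self.domains_[b])
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            }
            try:
                fret = residue_pair_distance(aligned, *self.fret_pair)
            except KeyError:
                fret = float("nan")
            for name, d in self.domains_.items():
                t = domain_transform(aligned, self.reference_, d, normal)
                rows.append(
                    {
                        "id": s.id,
                        "domain": name,
                        "rotation_angle_deg": t.rotation_angle,
                        "sense": t.sense,
                        "displacement_A": t.displacement,
                        "screw_translation_A": t.screw_translation,
                        **cogs,
                        "d_fret_pair_A": fret,
                    }
                )
        return pd.DataFrame(rows)
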