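"""Minimal Kabsch-Sander secondary-structure assignment.

Backbone hydrogen bonds are scored with the classic electrostatic model

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol

with a bond declared when E < -0.5 kcal/mol. Amide hydrogens, absent from
crystal structures, are reconstructed geometrically on each nitrogen along
the bisector of the N->C(prev) and N->CA directions at 1.01 Angstrom.
Residues participating in consecutive i -> i+4 turns are labelled H
(alpha-helix); isolated beta bridges and ladders are reduced to E; all
other residues are C. Proline has no amide hydrogen and never donates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import BACKBONE_ATOMS, DomainDefinition, Structure

__all__ = ["SecondaryStructureTrack", "assign_secondary_structure", "helicity_fraction"]

_Q = 0.084 * 332.0  # kcal/mol * Angstrom
_HBOND_CUTOFF = -0.5  # kcal/mol
_CHAIN_BREAK = 2.5  # Angstrom: max C(i-1)-N(i) distance for peptide continuity


@dataclass(frozen=True)
class SecondaryStructureTrack:
    """Per-residue secondary-structure labels from the reduced {H, E, C} alphabet."""

    labels: dict[int, str]

    def __getitem__(self, res_id: int) -> str:
        return self.labels[res_id]

    def fraction(self, residues, label: str = "H") -> float:
        residues = [r for r in residues if r in self.labels]
        if not residues:
            raise ValueError("no mapped residues in range")
        return sum(1 for r in residues if self.labels[r] == label) / len(residues)


def assign_secondary_structure(s: Structure) -> SecondaryStructureTrack:
    """Assign H/E/C labels to every residue of the pump chain.

    Residues missing backbone atoms are labelled C with a warning; they also
    interrupt hydrogen-bond bookkeeping exactly like a chain break.
    """
    res_ids = [int(r) for r in s.residue_ids()]
    n = len(res_ids)
    coords = {a: np.full((n, 3), np.nan) for a in BACKBONE_ATOMS}
    complete = np.zeros(n, dtype=bool)
    for i, res_id in enumerate(res_ids):
        mask = s.atoms.res_id == res_id
        names = {nm: j for j, nm in zip(np.where(mask)[0], s.atoms.atom_name[mask])}
        if all(a in names for a in BACKBONE_ATOMS):
            complete[i] = True
            for a in BACKBONE_ATOMS:
                coords[a][i] = s.coord[names[a]]
    if not complete.all():
        incomplete = [res_ids[i] for i in range(n) if not complete[i]]
        warnings.warn(
            f"{s.id}: {len(incomplete)} residues missing backbone atoms labelled C",
            stacklevel=2,
        )

    res_names = {
        int(r): str(s.atoms.res_name[s.atoms.res_id == r][0]) for r in res_ids
    }

    # Peptide continuity: residue i is bonded to i-1 if numbering is
    # consecutive-ish and the C(i-1)-N(i) distance is peptide-like.
    bonded_prev = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if complete[i] and complete[i - 1]:
            d = np.linalg.norm(coords["N"][i] - coords["C"][i - 1])
            bonded_prev[i] = d < _CHAIN_BREAK

    # Reconstructed amide hydrogen positions (prolines and chain starts: none).
    h_pos = np.full((n, 3), np.nan)
    has_h = np.zeros(n, dtype=bool)
    for i in range(n):
        if not (complete[i] and bonded_prev[i]) or res_names[res_ids[i]] == "PRO":
            continue
        d1 = coords["N"][i] - coords["C"][i - 1]
        d2 = coords["N"][i] - coords["CA"][i]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        bis = d1 + d2
        h_pos[i] = coords["N"][i] + 1.01 * bis / np.linalg.norm(bis)
        has_h[i] = True

    # Hydrogen-bond energy matrix: acceptor C=O of residue i, donor N-H of j.
    hbond = np.zeros((n, n), dtype=bool)
    acceptors = np.where(complete)[0]
    donors = np.where(has_h)[0]
    if len(acceptors) and len(donors):
        o = coords["O"][acceptors]
        c = coords["C"][acceptors]
        nn = coords["N"][donors]
        hh = h_pos[donors]

        def dist(a, b):
            return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

        with np.errstate(divide="ignore"):
            energy = _Q * (1.0 / dist(o, nn) + 1.0 / dist(c, hh)
                           - 1.0 / dist(o, hh) - 1.0 / dist(c, nn))
        for ai, i in enumerate(acceptors):
            for dj, j in enumerate(donors):
                if abs(res_ids[i] - res_ids[j]) >= 2 and energy[ai, dj] < _HBOND_CUTOFF:
                    hbond[i, j] = True

    labels = np.full(n, "C", dtype="U1")

    # Alpha helix: a 4-turn at i means hbond(i, i+4); two consecutive turns
    # make residues i+1 .. i+4 helical (Kabsch-Sander minimal helix).
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if res_ids[i + 4] - res_ids[i] == 4 and hbond[i, i + 4]:
            turn4[i] = True
    for i in range(1, n - 4):
        if turn4[i] and turn4[i - 1]:
            labels[i : i + 4] = "H"

    # Beta bridges (parallel / antiparallel); H takes precedence.
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hbond[i - 1, j] and hbond[j, i + 1]) or (
                hbond[j - 1, i] and hbond[i, j + 1]
            )
            antiparallel = (hbond[i, j] and hbond[j, i]) or (
                hbond[i - 1, j + 1] and hbond[j - 1, i + 1]
            )
            if parallel or antiparallel:
                for k in (i, j):
                    if labels[k] == "C":
                        labels[k] = "E"

    # A residue without its full backbone cannot carry an assignment, even if
    # it falls inside a helical run of its neighbours.
    labels[~complete] = "C"

    return SecondaryStructureTrack(labels={res_ids[i]: str(labels[i]) for i in range(n)})


def helicity_fraction(track: SecondaryStructureTrack, helix: DomainDefinition) -> float:
    """Fraction of mapped residues in the helix range labelled H."""
    return track.fraction(helix.residues, "H")
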