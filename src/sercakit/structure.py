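"""Structure model: parsing, reference numbering, and residue-range selections.

The in-memory container wraps a biotite ``AtomArray`` restricted to the
protein atoms of the pump chain (first model, alternate locations resolved
to highest occupancy). Heteroatoms — waters, ions, lipids, inhibitors,
phospho-mimetic adducts — are kept in a separate ligand table and never
enter geometry operations. Residue numbers follow the SERCA1a reference
convention (1-based, UniProt P04191-2, 994 residues); structures of other
isoforms are renumbered onto it by global pairwise sequence alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as pdb_io
from biotite.structure.io import pdbx as pdbx_io

__all__ = [
    "Structure",
    "DomainDefinition",
    "Selection",
    "BACKBONE_ATOMS",
    "DOMAINS",
    "load_structure",
    "write_structure",
    "map_to_reference_numbering",
    "select_coordinates",
    "common_residues",
    "load_reference_sequence",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Maximum residue number in the SERCA1a reference numbering.
REFERENCE_LENGTH = 994

# Residues treated as protein even though some depositions flag them hetero
# (phospho-aspartate mimics keep their backbone but are excluded anyway
# because their backbone chemistry is modified).
_NONSTANDARD_EXCLUDED = {"ASQ", "PHD"}


class StructureFormatError(ValueError):
    """Raised when a file cannot be parsed as the requested format."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no protein residues."""


class EmptySelectionError(ValueError):
    """Raised when a residue-range selection matches nothing."""


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of inclusive residue-number intervals in reference numbering."""

    name: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ranges = tuple(tuple(r) for r in self.ranges)
        object.__setattr__(self, "ranges", ranges)
        prev_stop = 0
        for start, stop in sorted(ranges):
            if not (1 <= start <= stop <= REFERENCE_LENGTH):
                raise ValueError(
                    f"domain {self.name}: interval {start}-{stop} outside [1, {REFERENCE_LENGTH}]"
                )
            if start <= prev_stop:
                raise ValueError(f"domain {self.name}: overlapping intervals")
            prev_stop = stop

    @property
    def residues(self) -> tuple[int, ...]:
        out: list[int] = []
        for start, stop in sorted(self.ranges):
            out.extend(range(start, stop + 1))
        return tuple(out)

    def __contains__(self, res_id: int) -> bool:
        return any(start <= res_id <= stop for start, stop in self.ranges)

    def __len__(self) -> int:
        return sum(stop - start + 1 for start, stop in self.ranges)


#: Cytosolic-domain and anchor residue ranges of SERCA1a.
DOMAINS: dict[str, DomainDefinition] = {
    "A": DomainDefinition("A", ((1, 40), (115, 241))),
    "N": DomainDefinition("N", ((357, 602),)),
    "P": DomainDefinition("P", ((300, 356), (603, 738))),
    # TM7-TM10: the structurally rigid luminal anchor used as superposition frame.
    "anchor": DomainDefinition("anchor", ((831, 855), (895, 915), (933, 948), (966, 994))),
}


@dataclass
class Structure:
    """A protein structure reduced to the pump chain, reference-numbered.

    Attributes
    ----------
    id : str
        Label, typically the lower-case PDB id.
    atoms : biotite.structure.AtomArray
        Protein atoms of the pump chain, first model only.
    ligands : biotite.structure.AtomArray or None
        Heteroatoms (ions, lipids, inhibitors, regulatory-peptide chains are
        kept here as metadata); excluded from every geometry operation.
    source_format : str
        One of ``pdb``, ``mmcif``, ``synthetic``.
    coord : (n, 3) float64 ndarray
        Working coordinates, row-matched to ``atoms``. The AtomArray holds
        single-precision copies (the convention of structure file I/O);
        geometry operations read and write this double-precision array so
        synthetic ground truth survives superposition arithmetic.
    """

    id: str
    atoms: struc.AtomArray
    ligands: struc.AtomArray | None = None
    source_format: str = "synthetic"
    coord: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.atoms.array_length() == 0:
            raise EmptyStructureError(f"{self.id}: no protein atoms")
        if self.coord is None:
            self.coord = np.asarray(self.atoms.coord, dtype=np.float64)
        else:
            self.coord = np.asarray(self.coord, dtype=np.float64)
            if self.coord.shape != (self.atoms.array_length(), 3):
                raise ValueError(f"{self.id}: coord array does not match atoms")
            self.atoms.coord = self.coord.astype(np.float32)
        if not np.isfinite(self.coord).all():
            raise ValueError(f"{self.id}: non-finite coordinates")
        res_ids = self.residue_ids()
        if np.any(np.diff(res_ids) <= 0):
            raise ValueError(f"{self.id}: residue numbers not strictly increasing")

    # -- residue-level views ------------------------------------------------

    def residue_ids(self) -> np.ndarray:
        """Ordered residue numbers present in the structure."""
        return np.unique(self.atoms.res_id)

    def backbone_complete_residues(self) -> set[int]:
        """Residue numbers with all four backbone atoms (N, CA, C, O) present."""
        complete: set[int] = set()
        for res_id in self.residue_ids():
            names = set(self.atoms.atom_name[self.atoms.res_id == res_id])
            if all(a in names for a in BACKBONE_ATOMS):
                complete.add(int(res_id))
        return complete

    def sequence(self) -> tuple[np.ndarray, str]:
        """(residue numbers, one-letter sequence) of the pump chain."""
        from biotite.sequence import ProteinSequence

        res_ids = self.residue_ids()
        letters = []
        for res_id in res_ids:
            name3 = self.atoms.res_name[self.atoms.res_id == res_id][0]
            try:
                letters.append(ProteinSequence.convert_letter_3to1(name3.capitalize()))
            except Exception:
                letters.append("X")
        return res_ids, "".join(letters)

    def atom_coord(self, res_id: int, atom_name: str) -> np.ndarray:
        mask = (self.atoms.res_id == res_id) & (self.atoms.atom_name == atom_name)
        if not mask.any():
            raise KeyError(f"{self.id}: residue {res_id} has no atom {atom_name}")
        return self.coord[mask][0]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with a rigid transform applied to all protein atoms."""
        moved = self.coord @ np.asarray(rotation).T + np.asarray(translation)
        return Structure(
            id=self.id,
            atoms=self.atoms.copy(),
            ligands=self.ligands,
            source_format=self.source_format,
            coord=moved,
        )


@dataclass(frozen=True)
class Selection:
    """Ordered coordinates for a domain selection, with provenance labels."""

    coords: np.ndarray  # (n, 3), Angstrom
    residue_ids: np.ndarray  # (n,) residue number per atom row
    atom_names: np.ndarray  # (n,) atom name per row
    missing_residues: tuple[int, ...]  # residues of the definition absent or incomplete


# -- I/O ---------------------------------------------------------------------


def _split_protein(atoms: struc.AtomArray, label: str) -> tuple[struc.AtomArray, struc.AtomArray | None]:
    """Separate pump-chain protein atoms from heteroatoms/regulatory chains."""
    is_protein = struc.filter_amino_acids(atoms) & ~atoms.hetero
    for res_name in _NONSTANDARD_EXCLUDED:
        is_protein &= atoms.res_name != res_name
    protein = atoms[is_protein]
    hetero = atoms[~is_protein]
    if protein.array_length() == 0:
        raise EmptyStructureError(f"{label}: no protein residues")
    # Longest protein chain is taken as the pump; PLB/SLN chains go to ligands.
    chains, counts = np.unique(protein.chain_id, return_counts=True)
    pump_chain = chains[np.argmax(counts)]
    other = protein[protein.chain_id != pump_chain]
    protein = protein[protein.chain_id == pump_chain]
    extra = [arr for arr in (hetero, other) if arr.array_length() > 0]
    ligands = None
    if extra:
        ligands = extra[0] if len(extra) == 1 else extra[0] + extra[1]
    return protein, ligands


def load_structure(path: str | Path, format: str = "auto", id: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is read; alternate locations are resolved to the
    highest-occupancy conformer. The longest protein chain becomes the pump;
    everything else (waters, ions, ligands, regulatory peptides) is retained
    in the ligand table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    label = id or path.stem.lower()
    try:
        if format == "pdb":
            pdb_file = pdb_io.PDBFile.read(str(path))
            atoms = pdb_io.get_structure(pdb_file, model=1, altloc="occupancy")
        elif format == "mmcif":
            cif_file = pdbx_io.CIFFile.read(str(path))
            atoms = pdbx_io.get_structure(cif_file, model=1, altloc="occupancy")
        else:
            raise ValueError(f"unknown format {format!r}")
    except (EmptyStructureError, ValueError):
        raise
    except Exception as exc:  # parser-level failure
        raise StructureFormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    protein, ligands = _split_protein(atoms, label)
    return Structure(id=label, atoms=protein, ligands=ligands, source_format=format)


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> Path:
    """Write the pump-chain atoms as PDB or mmCIF (mmCIF is lossless)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format == "pdb":
        pdb_file = pdb_io.PDBFile()
        pdb_io.set_structure(pdb_file, s.atoms)
        pdb_file.write(str(path))
    elif format == "mmcif":
        cif_file = pdbx_io.CIFFile()
        pdbx_io.set_structure(cif_file, s.atoms, data_block=s.id)
        cif_file.write(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def load_reference_sequence(path: str | Path) -> str:
    """Load a reference amino-acid sequence from a single-record FASTA file.

    The canonical reference for the pump is rabbit SERCA1a
    (UniProt P04191-2, 994 residues), which the caller supplies.
    """
    import biotite.sequence.io.fasta as fasta

    fasta_file = fasta.FastaFile.read(str(path))
    sequences = list(fasta_file.values())
    if len(sequences) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(sequences)}")
    return str(sequences[0])


# -- reference numbering ------------------------------------------------------


def map_to_reference_numbering(
    s: Structure, reference_sequence: str, min_identity: float = 0.5
) -> tuple[Structure, dict]:
    """Renumber a structure onto reference numbering by global alignment.

    Residues that do not align to a reference position (insertions relative
    to the reference, e.g. an isoform-specific C-terminal extension) are
    dropped. Returns the renumbered structure and a mapping report with the
    identity and the dropped residue numbers. Mapping an already-mapped
    structure is the identity operation.

    Raises
    ------
    ValueError
        If alignment identity over aligned columns is below ``min_identity``.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    res_ids, seq = s.sequence()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # Terminal gaps are free: crystal structures routinely truncate the ends.
    aligner.end_gap_score = 0.0
    alignment = aligner.align(reference_sequence, seq)[0]

    # Column-wise mapping: structure residue index -> reference position (1-based)
    mapping: dict[int, int] = {}
    identical = 0
    aligned_cols = 0
    for (ref_start, ref_stop), (q_start, q_stop) in zip(*alignment.aligned):
        for offset in range(ref_stop - ref_start):
            ref_pos = ref_start + offset  # 0-based in reference
            q_pos = q_start + offset
            mapping[q_pos] = ref_pos + 1
            aligned_cols += 1
            if reference_sequence[ref_pos] == seq[q_pos]:
                identical += 1
    if aligned_cols == 0:
        raise ValueError(
            f"{s.id}: alignment identity 0% (no aligned residues against reference)"
        )
    identity = identical / aligned_cols
    if identity < min_identity:
        raise ValueError(
            f"{s.id}: alignment identity {identity:.1%} below threshold {min_identity:.0%}; "
            "refusing to renumber"
        )

    old_ids = res_ids
    keep_mask = np.zeros(s.atoms.array_length(), dtype=bool)
    new_res_id = np.array(s.atoms.res_id, dtype=int)
    dropped: list[int] = []
    for idx, old in enumerate(old_ids):
        if idx in mapping:
            sel = s.atoms.res_id == old
            keep_mask |= sel
            new_res_id[sel] = mapping[idx]
        else:
            dropped.append(int(old))
    atoms = s.atoms.copy()
    atoms.res_id = new_res_id
    atoms = atoms[keep_mask]
    mapped = Structure(
        id=s.id,
        atoms=atoms,
        ligands=s.ligands,
        source_format=s.source_format,
        coord=s.coord[keep_mask],
    )
    report = {
        "id": s.id,
        "identity": identity,
        "n_aligned": aligned_cols,
        "dropped_residues": tuple(dropped),
    }
    return mapped, report


# -- selections ---------------------------------------------------------------


def select_coordinates(s: Structure, d: DomainDefinition, atoms: str = "backbone") -> Selection:
    """Coordinates of the requested atom type for residues of ``d`` present in ``s``.

    ``atoms`` is ``backbone`` (N, CA, C, O — residues missing any of the four
    are omitted and reported) or ``CA``. Rows are ordered by residue number,
    then backbone order.
    """
    if atoms == "backbone":
        wanted: Sequence[str] = BACKBONE_ATOMS
    elif atoms in ("CA", "ca"):
        wanted = ("CA",)
    else:
        raise ValueError(f"atoms must be 'backbone' or 'CA', got {atoms!r}")

    present = {int(r) for r in s.residue_ids()}
    coords: list[np.ndarray] = []
    out_res: list[int] = []
    out_names: list[str] = []
    missing: list[int] = []
    for res_id in d.residues:
        if res_id not in present:
            continue
        mask = s.atoms.res_id == res_id
        names = {n: i for i, n in zip(np.where(mask)[0], s.atoms.atom_name[mask])}
        if not all(a in names for a in wanted):
            missing.append(res_id)
            continue
        for a in wanted:
            coords.append(s.coord[names[a]])
            out_res.append(res_id)
            out_names.append(a)
    if not coords:
        raise EmptySelectionError(f"{s.id}: domain {d.name} selects no complete residues")
    return Selection(
        coords=np.array(coords, dtype=float),
        residue_ids=np.array(out_res, dtype=int),
        atom_names=np.array(out_names),
        missing_residues=tuple(missing),
    )


def common_residues(structures: Iterable[Structure], d: DomainDefinition) -> tuple[int, ...]:
    """Residue numbers backbone-complete in *all* structures and within ``d``.

    This intersection replaces loop modelling: every ensemble comparison is
    restricted to residues every member actually resolves.
    """
    structures = list(structures)
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    domain_set = set(d.residues)
    per_structure = [s.backbone_complete_residues() & domain_set for s in structures]
    intersection = set.intersection(*per_structure)
    if not intersection:
        most_restrictive = min(structures, key=lambda s: len(s.backbone_complete_residues() & domain_set))
        raise ValueError(
            f"empty common residue set in domain {d.name}; most restrictive structure: "
            f"{most_restrictive.id}"
        )
    return tuple(sorted(intersection))
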