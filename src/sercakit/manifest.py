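"""Curated-corpus manifest: PDB ids, isoforms, states, and exclusions.

The packaged manifest lists the crystal-corpus entries whose state and
exclusion metadata are established: the E1-2Ca reference 2c9m; the entries
excluded from clustering for low resolution (1kju) or missing regions
(4nab); the two structures excluded from TM-geometry analysis and expected
to resist unequivocal cluster assignment (5zmw, 5ncq); the regulatory
complexes; the SERCA2a/2b isoform structures; and the inhibitor-bound E2
entries. Users analysing the full deposited corpus extend this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["ManifestEntry", "StructureManifest", "load_packaged_manifest"]

COLUMNS = ("pdb_id", "isoform", "cluster_label", "state_label", "exclusion_reason", "tm_excluded")


@dataclass(frozen=True)
class ManifestEntry:
    pdb_id: str
    isoform: str = "SERCA1a"
    cluster_label: str = ""  # C1-C6, "unassigned", or "" when unknown
    state_label: str = ""
    exclusion_reason: str = ""  # non-empty: excluded from clustering entirely
    tm_excluded: bool = False  # excluded from TM-geometry analysis only


@dataclass(frozen=True)
class StructureManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.pdb_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pdb_id in manifest")

    @property
    def included(self) -> tuple[ManifestEntry, ...]:
        return tuple(e for e in self.entries if not e.exclusion_reason)

    @property
    def excluded(self) -> tuple[ManifestEntry, ...]:
        return tuple(e for e in self.entries if e.exclusion_reason)

    @property
    def tm_included(self) -> tuple[ManifestEntry, ...]:
        return tuple(e for e in self.included if not e.tm_excluded)

    def get(self, pdb_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.pdb_id == pdb_id:
                return e
        raise KeyError(pdb_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) | {"tm_excluded": int(e.tm_excluded)} for e in self.entries])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StructureManifest":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(COLUMNS[:5]) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if "tm_excluded" not in df.columns:
            df["tm_excluded"] = "0"
        entries = tuple(
            ManifestEntry(
                pdb_id=row.pdb_id.strip().lower(),
                isoform=row.isoform,
                cluster_label=row.cluster_label,
                state_label=row.state_label,
                exclusion_reason=row.exclusion_reason,
                tm_excluded=row.tm_excluded in ("1", "true", "True"),
            )
            for row in df.itertuples()
        )
        return cls(entries=entries)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def load_packaged_manifest() -> StructureManifest:
    """The manifest shipped with the package (entries with documented metadata)."""
    ref = resources.files("sercakit") / "data" / "serca_manifest.tsv"
    with resources.as_file(ref) as path:
        return StructureManifest.from_tsv(path)
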