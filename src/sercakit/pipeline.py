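"""End-to-end analysis pipeline: manifest -> cluster -> kinematics -> TM metrics.

Outputs are plain TSV tables written atomically (tmp file + rename) so a
re-run with identical config and inputs is byte-identical; the run log
carries the config hash and per-structure failures. A malformed structure
is skipped and reported, never silently dropped and never fatal — except a
missing reference, without which nothing downstream is defined.

Units follow the corpus convention: nm for RMSD, Angstrom for distances,
degrees for angles; every table states units in its column names.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import FULL_CHAIN, RmsdLinkageClustering
from .kinematics import HeadpieceKinematics
from .manifest import StructureManifest, load_packaged_manifest
from .structure import Structure, load_structure, map_to_reference_numbering
from .tm import TransmembraneGeometry

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full corpus run; defaults reproduce the standard protocol."""

    structure_dir: str = "."
    manifest_path: str | None = None  # None: packaged manifest
    reference_id: str = "2c9m"
    cluster_cutoff_nm: float = 0.23
    linkage: str = "single"
    reference_sequence_path: str | None = None  # FASTA; None skips renumbering
    output_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    clusters: pd.DataFrame
    rmsd_matrix: pd.DataFrame
    kinematics: pd.DataFrame
    tm_metrics: pd.DataFrame
    interhelical: pd.DataFrame
    failures: dict[str, str]
    output_dir: Path


def _atomic_write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.6f") -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, float_format=float_format)
    tmp.replace(path)


def _find_structure_file(directory: Path, pdb_id: str) -> Path | None:
    for suffix in (".cif", ".mmcif", ".pdb", ".ent"):
        candidate = directory / f"{pdb_id}{suffix}"
        if candidate.exists():
            return candidate
    return None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config`` and write all tables.

    Raises
    ------
    ValueError
        If the manifest is empty or the reference structure cannot be loaded.
    """
    manifest = (
        StructureManifest.from_tsv(config.manifest_path)
        if config.manifest_path
        else load_packaged_manifest()
    )
    if not manifest.entries:
        raise ValueError("empty manifest: nothing to analyse")
    structure_dir = Path(config.structure_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reference_sequence = None
    if config.reference_sequence_path:
        from .structure import load_reference_sequence

        reference_sequence = load_reference_sequence(config.reference_sequence_path)

    structures: dict[str, Structure] = {}
    failures: dict[str, str] = {}
    log_lines = [
        f"sercakit {__version__}",
        f"config_hash {config.digest()}",
    ]
    for entry in manifest.entries:
        if entry.exclusion_reason:
            failures[entry.pdb_id] = f"excluded: {entry.exclusion_reason}"
            continue
        path = _find_structure_file(structure_dir, entry.pdb_id)
        if path is None:
            failures[entry.pdb_id] = "structure file not found"
            continue
        try:
            s = load_structure(path, id=entry.pdb_id)
            if reference_sequence is not None:
                s, _ = map_to_reference_numbering(s, reference_sequence)
            structures[entry.pdb_id] = s
        except Exception as exc:
            failures[entry.pdb_id] = f"load failed: {exc}"

    if config.reference_id not in structures:
        raise ValueError(
            f"reference structure {config.reference_id!r} unavailable "
            f"({failures.get(config.reference_id, 'not in manifest or directory')})"
        )
    reference = structures[config.reference_id]
    ordered_ids = [i for i in (e.pdb_id for e in manifest.entries) if i in structures]
    ensemble = [structures[i] for i in ordered_ids]

    # -- clustering ---------------------------------------------------------
    clusterer = RmsdLinkageClustering(
        cutoff_nm=config.cluster_cutoff_nm,
        method=config.linkage,
        reference_id=config.reference_id,
        singletons="unassigned",
    )
    clusterer.fit(ensemble)
    cluster_of = dict(zip(clusterer.ids_, clusterer.labels_))
    matrix_df = clusterer.distance_matrix_.to_frame()

    # -- headpiece kinematics ----------------------------------------------
    kin_rows = []
    kin = HeadpieceKinematics(reference=reference).fit()
    for s in ensemble:
        try:
            df = kin.transform([s])
            df.insert(1, "cluster", cluster_of.get(s.id, ""))
            kin_rows.append(df)
        except Exception as exc:
            failures[s.id] = f"kinematics failed: {exc}"
    kinematics_df = pd.concat(kin_rows, ignore_index=True) if kin_rows else pd.DataFrame()

    # -- TM geometry ---------------------------------------------------------
    tm_ids = {e.pdb_id for e in manifest.tm_included}
    tm_structures = [s for s in ensemble if s.id in tm_ids]
    tmg = TransmembraneGeometry().fit()
    tm_rows, ih_rows = [], []
    for s in tm_structures:
        try:
            df = tmg.transform([s])
            df.insert(1, "cluster", cluster_of.get(s.id, ""))
            tm_rows.append(df)
            ih_rows.append(tmg.interhelical_angles([s]))
        except Exception as exc:
            failures[s.id] = f"tm geometry failed: {exc}"
    tm_df = pd.concat(tm_rows, ignore_index=True) if tm_rows else pd.DataFrame()
    ih_df = pd.concat(ih_rows, ignore_index=True) if ih_rows else pd.DataFrame()

    # -- cluster table covering every manifest entry -------------------------
    cluster_df = pd.DataFrame(
        [
            {
                "id": e.pdb_id,
                "cluster": cluster_of.get(e.pdb_id, ""),
                "state": e.state_label,
                "status": "ok" if e.pdb_id in structures else failures.get(e.pdb_id, "missing"),
            }
            for e in manifest.entries
        ]
    )

    matrix_out = matrix_df.reset_index().rename(columns={"index": "id"})
    _atomic_write_tsv(matrix_out, out_dir / "rmsd_matrix_nm.tsv")
    _atomic_write_tsv(cluster_df, out_dir / "clusters.tsv")
    _atomic_write_tsv(kinematics_df, out_dir / "headpiece_kinematics.tsv")
    _atomic_write_tsv(tm_df, out_dir / "tm_metrics.tsv")
    _atomic_write_tsv(ih_df, out_dir / "interhelical_angles.tsv")
    np.savetxt(out_dir / "rmsd_matrix_nm.txt", clusterer.distance_matrix_.values, fmt="%.6f")

    log_lines += [f"failed {pid}: {reason}" for pid, reason in sorted(failures.items())]
    log_lines.append(f"n_structures {len(ensemble)}")
    log_lines.append(f"n_clusters {clusterer.assignment_.cluster_count()}")
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return PipelineResult(
        clusters=cluster_df,
        rmsd_matrix=matrix_df,
        kinematics=kinematics_df,
        tm_metrics=tm_df,
        interhelical=ih_df,
        failures=failures,
        output_dir=out_dir,
    )
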