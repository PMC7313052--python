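"""Transmembrane-helix geometry: helicity, bending, tilt, and crossing angles.

The helicity fraction comes from the hydrogen-bond-based secondary-structure
track; the geometric metrics are computed on C-alpha coordinates. A helix
axis is the principal (largest-variance) direction of its C-alpha set,
oriented N -> C; the tilt angle is measured against the membrane normal and
folded into [0, 90] degrees; interhelical (crossing) angles use the directed
convention, so antiparallel helices score 180 degrees. The bending angle
follows the three-section construction: centroids of the first, middle, and
last ``window`` C-alpha positions define two arm vectors whose angle is the
bend — near zero for a straight helix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .secondary import SecondaryStructureTrack, assign_secondary_structure, helicity_fraction
from .structure import DomainDefinition, Structure, select_coordinates

__all__ = [
    "HelixMetrics",
    "TM_HELICES",
    "LUMINAL_PAIRS",
    "helix_axis",
    "bending_angle",
    "tilt_angle",
    "interhelical_angle",
    "TransmembraneGeometry",
]

#: TM helix residue ranges in SERCA1a reference numbering. TM1a/TM1b,
#: TM4a/TM4b, the TM6 cytosolic segment, and TM7-TM10 follow the reported
#: boundaries; TM2, TM3, TM5 and the remaining full-helix spans are packaged
#: defaults from standard SERCA1a topology annotations and are configurable.
TM_HELICES: dict[str, DomainDefinition] = {
    "TM1": DomainDefinition("TM1", ((48, 78),)),
    "TM1a": DomainDefinition("TM1a", ((48, 55),)),
    "TM1b": DomainDefinition("TM1b", ((61, 78),)),
    "TM2": DomainDefinition("TM2", ((89, 114),)),
    "TM3": DomainDefinition("TM3", ((248, 270),)),
    "TM4": DomainDefinition("TM4", ((290, 329),)),
    "TM4a": DomainDefinition("TM4a", ((290, 306),)),
    "TM4b": DomainDefinition("TM4b", ((311, 329),)),
    "TM5": DomainDefinition("TM5", ((747, 780),)),
    "TM6": DomainDefinition("TM6", ((789, 810),)),
    "TM6cyt": DomainDefinition("TM6cyt", ((800, 808),)),
    "TM7": DomainDefinition("TM7", ((831, 855),)),
    "TM8": DomainDefinition("TM8", ((895, 915),)),
    "TM9": DomainDefinition("TM9", ((933, 948),)),
    "TM10": DomainDefinition("TM10", ((966, 994),)),
}

#: Luminal helix pairs whose crossing angles open up in the E1 -> E2 direction.
LUMINAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("TM2", "TM4a"),
    ("TM2", "TM6"),
    ("TM2", "TM9"),
    ("TM4a", "TM6"),
    ("TM4a", "TM9"),
    ("TM6", "TM9"),
)


@dataclass(frozen=True)
class HelixMetrics:
    """Per-helix metrics: helicity in [0,1], bend in [0,180] deg, tilt in [0,90] deg."""

    helix: str
    helicity: float
    bending_angle: float
    tilt_angle: float
    axis: np.ndarray  # unit, N -> C


def helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of a C-alpha set, oriented N -> C, plus the centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 5:
        raise ValueError("need >= 5 C-alpha positions for an axis")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-8:
        raise ValueError("degenerate geometry: no principal direction")
    axis = vt[0]
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    return axis, centroid


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))))


def bending_angle(coords: np.ndarray, window: int = 4) -> float:
    """Bend (degrees) from bottom/middle/top section centroids of the helix.

    The centroids ``b``, ``m``, ``t`` of the first, middle, and last
    ``window`` C-alpha positions define arm vectors ``m - b`` and ``t - m``;
    the bend is the angle between them.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3 * window:
        raise ValueError(f"need >= {3 * window} residues for window={window}, got {n}")
    b = coords[:window].mean(axis=0)
    mid = (n - window) // 2
    m = coords[mid : mid + window].mean(axis=0)
    t = coords[-window:].mean(axis=0)
    return _angle_deg(m - b, t - m)


def tilt_angle(axis: np.ndarray, membrane_normal: np.ndarray) -> float:
    """Angle (degrees) between a helix axis and the membrane normal, in [0, 90]."""
    return min(_angle_deg(axis, membrane_normal), _angle_deg(-np.asarray(axis), membrane_normal))


def interhelical_angle(axis1: np.ndarray, axis2: np.ndarray) -> float:
    """Directed crossing angle (degrees) between two N->C helix axes, in [0, 180]."""
    return _angle_deg(axis1, axis2)


class TransmembraneGeometry(TransformerMixin, BaseEstimator):
    """Per-structure TM metrics table, sklearn-transformer shaped.

    ``transform`` returns a long-format DataFrame with one row per
    (structure, helix): helicity fraction, bending angle (deg), tilt angle
    (deg) and the axis components. :meth:`interhelical_angles` returns the
    pairwise crossing-angle table for the configured helix pairs.

    Parameters
    ----------
    helices : dict[str, DomainDefinition] or None
        Helix table; defaults to the packaged TM1-TM10 (+ subsegment) spans.
    membrane_normal : array-like
        Membrane normal of the pre-oriented frame (default +z).
    bend_window : int
        Section size for the bending construction (default 4 residues).
    pairs : sequence of (str, str) or None
        Helix pairs for :meth:`interhelical_angles`; defaults to the luminal
        pairs diagnostic for the E1/E2 transition.
    """

    def __init__(
        self,
        helices: dict[str, DomainDefinition] | None = None,
        membrane_normal=(0.0, 0.0, 1.0),
        bend_window: int = 4,
        pairs=None,
    ):
        self.helices = helices
        self.membrane_normal = membrane_normal
        self.bend_window = bend_window
        self.pairs = pairs

    def _helix_table(self) -> dict[str, DomainDefinition]:
        return dict(self.helices) if self.helices is not None else dict(TM_HELICES)

    def fit(self, X=None, y=None):
        self.helices_ = self._helix_table()
        self.pairs_ = tuple(self.pairs) if self.pairs is not None else LUMINAL_PAIRS
        return self

    def _axes(self, s: Structure) -> dict[str, np.ndarray]:
        axes = {}
        for name, d in self.helices_.items():
            try:
                sel = select_coordinates(s, d, atoms="CA")
                axes[name], _ = helix_axis(sel.coords)
            except ValueError:
                continue
        return axes

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "helices_"):
            self.fit(X)
        normal = np.asarray(self.membrane_normal, dtype=float)
        rows = []
        for s in X:
            track = assign_secondary_structure(s)
            for name, d in self.helices_.items():
                try:
                    sel = select_coordinates(s, d, atoms="CA")
                except ValueError:
                    continue
                try:
                    axis, _ = helix_axis(sel.coords)
                    tilt = tilt_angle(axis, normal)
                except ValueError:
                    axis, tilt = None, float("nan")
                try:
                    bend = bending_angle(sel.coords, window=self.bend_window)
                except ValueError:
                    bend = float("nan")
                rows.append(
                    {
                        "id": s.id,
                        "helix": name,
                        "helicity": track.fraction(d.residues),
                        "bend_deg": bend,
                        "tilt_deg": tilt,
                        "axis_x": axis[0] if axis is not None else float("nan"),
                        "axis_y": axis[1] if axis is not None else float("nan"),
                        "axis_z": axis[2] if axis is not None else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def interhelical_angles(self, X) -> pd.DataFrame:
        """Crossing angles (deg) for the configured helix pairs, per structure."""
        if not hasattr(self, "helices_"):
            self.fit(X)
        rows = []
        for s in X:
            axes = self._axes(s)
            for h1, h2 in self.pairs_:
                if h1 in axes and h2 in axes:
                    rows.append(
                        {
                            "id": s.id,
                            "helix_i": h1,
                            "helix_j": h2,
                            "angle_deg": interhelical_angle(axes[h1], axes[h2]),
                        }
                    )
        return pd.DataFrame(rows)
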