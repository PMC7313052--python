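"""All-vs-all backbone RMSD and catalytic-state clustering.

The conformational census of the crystal corpus rests on two steps: a
symmetric backbone-RMSD matrix over the ensemble-wide common residue set
(each pair superposed by Kabsch before measuring), and linkage clustering
of that matrix at a fixed cutoff (0.23 nm by default, single linkage — a
structure joins a cluster when it is within the cutoff of any member, i.e.
connected components of the thresholded distance graph).

Cluster naming follows the catalytic-state convention: the component
containing the reference structure (the Ca2+-bound E1 state, 2c9m) is C1;
remaining clusters are numbered by ascending minimum position in the input
order. Singleton components other than the reference's can optionally be
reported as "unassigned" rather than forced into a cluster of their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .geometry import ANGSTROM_PER_NM, kabsch_superpose
from .structure import DOMAINS, DomainDefinition, Selection, Structure, common_residues, select_coordinates

__all__ = [
    "RmsdMatrix",
    "ClusterAssignment",
    "backbone_rmsd",
    "rmsd_matrix",
    "linkage_cluster",
    "RmsdLinkageClustering",
]

#: Full-chain region used for the corpus-wide matrix.
FULL_CHAIN = DomainDefinition("full", ((1, 994),))


@dataclass(frozen=True)
class RmsdMatrix:
    """Symmetric backbone-RMSD matrix in nanometres."""

    ids: tuple[str, ...]
    values: np.ndarray  # (n, n), nm

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class ClusterAssignment:
    """Structure id -> cluster label ("C1", ..., or "unassigned")."""

    labels: dict[str, str]
    cutoff_nm: float
    linkage: str = "single"

    def cluster_count(self) -> int:
        return len({v for v in self.labels.values() if v != "unassigned"})

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(k for k, v in self.labels.items() if v == label)


def backbone_rmsd(
    a: Structure,
    b: Structure,
    fit_region: DomainDefinition = FULL_CHAIN,
    measure_region: DomainDefinition | None = None,
    residues: tuple[int, ...] | None = None,
) -> float:
    """Backbone RMSD (nm) of ``b`` vs ``a`` after Kabsch fit on ``fit_region``.

    ``residues`` restricts both regions to a pre-computed common set (used by
    :func:`rmsd_matrix` so every pair is measured over identical atoms);
    otherwise the pairwise common backbone-complete set is used.
    """
    if measure_region is None:
        measure_region = fit_region
    if residues is None:
        residues = common_residues([a, b], fit_region)
    fit_set = DomainDefinition("_fit", tuple((r, r) for r in residues))
    sel_a = select_coordinates(a, fit_set, atoms="backbone")
    sel_b = select_coordinates(b, fit_set, atoms="backbone")
    if sel_a.coords.shape != sel_b.coords.shape:
        raise ValueError(f"{a.id} vs {b.id}: backbone selections do not match")
    fit = kabsch_superpose(sel_b.coords, sel_a.coords)
    if measure_region is fit_region or measure_region.ranges == fit_set.ranges:
        return fit.rmsd_nm
    measure_res = [r for r in residues if r in measure_region]
    m_set = DomainDefinition("_measure", tuple((r, r) for r in measure_res))
    m_a = select_coordinates(a, m_set, atoms="backbone")
    m_b = select_coordinates(b, m_set, atoms="backbone")
    moved = fit.apply(m_b.coords)
    return float(np.sqrt(np.mean(np.sum((moved - m_a.coords) ** 2, axis=1)))) / ANGSTROM_PER_NM


def rmsd_matrix(
    structures: list[Structure], region: DomainDefinition = FULL_CHAIN
) -> RmsdMatrix:
    """All-vs-all backbone RMSD (nm) over the ensemble-wide common residue set."""
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    shared = common_residues(structures, region)
    n = len(structures)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = backbone_rmsd(structures[i], structures[j], region, residues=shared)
            values[i, j] = values[j, i] = d
    return RmsdMatrix(ids=tuple(s.id for s in structures), values=values)


def linkage_cluster(
    m: RmsdMatrix,
    cutoff: float = 0.23,
    method: str = "single",
    reference_id: str | None = None,
    singletons: str = "cluster",
) -> ClusterAssignment:
    """Cluster the RMSD matrix at ``cutoff`` (nm) by linkage clustering.

    ``method`` is ``single`` (default: connected components of the
    thresholded graph), ``average`` or ``complete`` for sensitivity checks.
    With ``singletons="unassigned"``, single-membered components that do not
    contain ``reference_id`` are reported as "unassigned" — the convention
    for structures that cannot be unequivocally grouped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if singletons not in ("cluster", "unassigned"):
        raise ValueError("singletons must be 'cluster' or 'unassigned'")
    n = len(m.ids)
    condensed = squareform(m.values, checks=False)
    z = scipy_linkage(condensed, method=method)
    flat = fcluster(z, t=cutoff, criterion="distance")

    # Deterministic label order: reference's component first, then ascending
    # minimum input position.
    groups: dict[int, list[int]] = {}
    for idx, g in enumerate(flat):
        groups.setdefault(int(g), []).append(idx)
    ref_group = None
    if reference_id is not None and reference_id in m.ids:
        ref_group = int(flat[m.ids.index(reference_id)])
    ordered = sorted(groups, key=lambda g: (g != ref_group, min(groups[g])))

    labels: dict[str, str] = {}
    next_label = 1
    for g in ordered:
        members = groups[g]
        if (
            singletons == "unassigned"
            and len(members) == 1
            and g != ref_group
        ):
            labels[m.ids[members[0]]] = "unassigned"
            continue
        name = f"C{next_label}"
        next_label += 1
        for idx in members:
            labels[m.ids[idx]] = name
    return ClusterAssignment(labels=labels, cutoff_nm=cutoff, linkage=method)


class RmsdLinkageClustering(ClusterMixin, BaseEstimator):
    """Catalytic-state clustering estimator over structures or a distance matrix.

    Parameters
    ----------
    cutoff_nm : float
        Linkage cutoff in nanometres (default 0.23).
    method : str
        ``single`` (default), ``average`` or ``complete``.
    reference_id : str or None
        Structure whose component is labelled C1 (default ``"2c9m"``).
    singletons : str
        ``"cluster"`` or ``"unassigned"`` (see :func:`linkage_cluster`).
    region : DomainDefinition
        Residue region over which the matrix is computed when ``fit`` is
        given structures.

    Attributes
    ----------
    ids_ : tuple of str
    distance_matrix_ : RmsdMatrix
    assignment_ : ClusterAssignment
    labels_ : ndarray of str, cluster label per input structure
    """

    def __init__(
        self,
        cutoff_nm: float = 0.23,
        method: str = "single",
        reference_id: str | None = "2c9m",
        singletons: str = "cluster",
        region: DomainDefinition = FULL_CHAIN,
    ):
        self.cutoff_nm = cutoff_nm
        self.method = method
        self.reference_id = reference_id
        self.singletons = singletons
        self.region = region

    def fit(self, X, y=None):
        """Fit on a list of :class:`Structure` or a precomputed :class:`RmsdMatrix`."""
        if isinstance(X, RmsdMatrix):
            matrix = X
        else:
            X = list(X)
            if not X or not isinstance(X[0], Structure):
                raise TypeError("X must be a list of Structure or an RmsdMatrix")
            matrix = rmsd_matrix(X, region=self.region)
        assignment = linkage_cluster(
            matrix,
            cutoff=self.cutoff_nm,
            method=self.method,
            reference_id=self.reference_id,
            singletons=self.singletons,
        )
        self.ids_ = matrix.ids
        self.distance_matrix_ = matrix
        self.assignment_ = assignment
        self.labels_ = np.array([assignment.labels[i] for i in matrix.ids])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
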