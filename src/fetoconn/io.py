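"""Data model and file I/O for weighted structural connectomes.

A connectome is a weighted, undirected graph over a fixed parcellation:
nodes are brain regions, edge weights quantify interregional white-matter
connection strength (fiber-bundle-capacity-like, dimensionless non-negative
reals).  On disk a connectome is a square CSV whose header row and first
column both carry the node ids; a cohort is described by a TSV manifest
(subject_id, age_weeks, matrix_path) plus a shared node table (node_id,
label, hemisphere, lobe, x_mm, y_mm, z_mm).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "Connectome",
    "NodeTable",
    "Cohort",
    "read_connectome",
    "write_connectome",
    "read_node_table",
    "write_node_table",
    "load_cohort",
    "write_cohort",
    "node_distances",
    "export_graphml",
]

#: largest |W - W.T| that is silently symmetrized on read
ASYMMETRY_TOL = 1e-6
#: symmetry required of an in-memory Connectome
SYMMETRY_TOL = 1e-9

HEMISPHERES = ("left", "right", "midline")


@dataclass
class Connectome:
    """A weighted adjacency matrix over a fixed, ordered node set.

    Parameters
    ----------
    weights : (d, d) ndarray
        Symmetric, non-negative, zero-diagonal connection strengths.
    node_ids : sequence of str
        Region identifiers, one per row/column of ``weights``.
    age_weeks : float, optional
        Gestational age of the subject (weeks).
    subject_id : str, optional
    """

    weights: np.ndarray
    node_ids: list[str]
    age_weeks: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        d = w.shape[0]
        if d < 2:
            raise ValueError("connectome needs at least 2 nodes")
        self.node_ids = [str(i) for i in self.node_ids]
        if len(self.node_ids) != d:
            raise ValueError(
                f"{len(self.node_ids)} node ids for a {d}-node matrix"
            )
        if len(set(self.node_ids)) != d:
            raise ValueError("duplicate node ids")
        if np.isnan(w).any():
            raise ValueError("NaN weight")
        if (w < 0).any():
            raise ValueError(f"negative weight (min {w.min():g})")
        asym = np.abs(w - w.T).max()
        if asym > SYMMETRY_TOL:
            raise ValueError(f"asymmetric matrix (max asymmetry {asym:g})")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)  # self-connections are undefined
        self.weights = w
        if self.age_weeks is not None:
            self.age_weeks = float(self.age_weeks)
            if self.age_weeks < 0:
                raise ValueError("age_weeks must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Edge weights as a flat vector over node pairs i < j."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def with_weights(self, weights: np.ndarray) -> "Connectome":
        return replace(self, weights=np.asarray(weights, dtype=float))


@dataclass
class NodeTable:
    """Per-node metadata: label, hemisphere, lobe, centroid (mm)."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("node_id", "label", "hemisphere", "lobe", "x_mm", "y_mm", "z_mm")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"node table missing columns {missing}")
        t = t.copy()
        t["node_id"] = t["node_id"].astype(str)
        if t["node_id"].duplicated().any():
            raise ValueError("duplicate node ids in node table")
        bad_hemi = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemisphere values {sorted(bad_hemi)}")
        xyz = t[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            raise ValueError("non-finite centroid")
        self.table = t.reset_index(drop=True)

    @property
    def node_ids(self) -> list[str]:
        return self.table["node_id"].tolist()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    @property
    def lobes(self) -> list[str]:
        return self.table["lobe"].tolist()

    @property
    def hemispheres(self) -> list[str]:
        return self.table["hemisphere"].tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Cohort:
    """An age-ordered collection of subject connectomes on a shared node set."""

    subjects: list[Connectome]
    node_table: NodeTable | None = None
    age_range: tuple[float, float] = (22.0, 37.0)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("empty cohort")
        ref = self.subjects[0].node_ids
        for s in self.subjects:
            if s.node_ids != ref:
                raise ValueError(
                    f"node order mismatch for subject {s.subject_id!r}"
                )
            if s.age_weeks is None:
                raise ValueError(f"subject {s.subject_id!r} has no age")
        lo, hi = self.age_range
        for s in self.subjects:
            if not (lo <= s.age_weeks <= hi):
                raise ValueError(
                    f"subject {s.subject_id!r} age {s.age_weeks} outside "
                    f"declared range [{lo}, {hi}]"
                )
        if self.node_table is not None and self.node_table.node_ids != ref:
            raise ValueError("node table ids do not match subject node ids")
        self.subjects = sorted(self.subjects, key=lambda s: s.age_weeks)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_weeks for s in self.subjects])

    @property
    def node_ids(self) -> list[str]:
        return self.subjects[0].node_ids

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].n_nodes

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def edge_matrix(self) -> np.ndarray:
        """(n_subjects, n_pairs) upper-triangle edge weights, age order."""
        return np.array([s.upper_triangle() for s in self.subjects])


def read_connectome(
    path: str | os.PathLike,
    age_weeks: float | None = None,
    subject_id: str | None = None,
) -> Connectome:
    """Read a square CSV connectome (header row/column = node ids).

    Asymmetry up to ``ASYMMETRY_TOL`` is averaged out; anything larger is an
    error.  The diagonal is forced to zero.
    """
    df = pd.read_csv(path, index_col=0)
    row_ids = [str(c) for c in df.columns]
    col_ids = [str(i) for i in df.index]
    if row_ids != col_ids:
        raise ValueError(
            f"{path}: header row and index column node ids disagree"
        )
    w = df.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: non-square matrix {w.shape}")
    if np.isnan(w).any():
        raise ValueError(f"{path}: NaN weight")
    if (w < 0).any():
        raise ValueError(f"{path}: negative weight")
    asym = np.abs(w - w.T).max()
    if asym > ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetric matrix (max asymmetry {asym:g})")
    w = (w + w.T) / 2.0
    if subject_id is None:
        subject_id = Path(path).stem
    return Connectome(w, row_ids, age_weeks=age_weeks, subject_id=subject_id)


def write_connectome(c: Connectome, path: str | os.PathLike) -> None:
    """Write a connectome as a square CSV; round-trips to within 1e-12."""
    df = pd.DataFrame(c.weights, index=c.node_ids, columns=c.node_ids)
    df.to_csv(path, float_format="%.17g")


def read_node_table(path: str | os.PathLike) -> NodeTable:
    return NodeTable(pd.read_csv(path, sep="\t"))


def write_node_table(nt: NodeTable, path: str | os.PathLike) -> None:
    nt.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_cohort(
    manifest_path: str | os.PathLike,
    node_table_path: str | os.PathLike | None = None,
    age_range: tuple[float, float] = (22.0, 37.0),
) -> Cohort:
    """Load a cohort from a TSV manifest (subject_id, age_weeks, matrix_path).

    Relative matrix paths are resolved against the manifest's directory.
    Subjects are returned sorted by gestational age.
    """
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "age_weeks", "matrix_path"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if len(manifest) == 0:
        raise ValueError("empty cohort")
    base = Path(manifest_path).parent
    subjects = []
    for row in manifest.itertuples(index=False):
        try:
            age = float(row.age_weeks)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"unparseable age {row.age_weeks!r} for {row.subject_id}"
            ) from exc
        p = Path(row.matrix_path)
        if not p.is_absolute():
            p = base / p
        subjects.append(
            read_connectome(p, age_weeks=age, subject_id=str(row.subject_id))
        )
    nt = read_node_table(node_table_path) if node_table_path else None
    return Cohort(subjects, node_table=nt, age_range=age_range)


def write_cohort(
    cohort: Cohort, out_dir: str | os.PathLike, prefix: str = ""
) -> Path:
    """Write matrices + manifest (+ node table) under ``out_dir``.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{prefix}{s.subject_id}.csv"
        write_connectome(s, out / fname)
        rows.append((s.subject_id, s.age_weeks, fname))
    manifest = pd.DataFrame(rows, columns=["subject_id", "age_weeks", "matrix_path"])
    mpath = out / f"{prefix}manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    if cohort.node_table is not None:
        write_node_table(cohort.node_table, out / f"{prefix}nodes.tsv")
    return mpath


def node_distances(nt: NodeTable) -> np.ndarray:
    """Euclidean inter-centroid distance matrix (mm).

    Used as the reproducible stand-in for streamline-based connection
    length; a user-supplied length matrix may be passed wherever a distance
    matrix is accepted.
    """
    xyz = nt.centroids
    return cdist(xyz, xyz)


def export_graphml(
    c: Connectome, path: str | os.PathLike, nt: NodeTable | None = None
) -> None:
    """Convenience GraphML export (nodes with optional metadata, weighted edges)."""
    import networkx as nx

    g = nx.Graph()
    meta = {}
    if nt is not None:
        if nt.node_ids != c.node_ids:
            raise ValueError("node table ids do not match connectome")
        for row in nt.table.itertuples(index=False):
            meta[row.node_id] = dict(
                label=row.label, hemisphere=row.hemisphere, lobe=row.lobe,
                x_mm=float(row.x_mm), y_mm=float(row.y_mm), z_mm=float(row.z_mm),
            )
    for nid in c.node_ids:
        g.add_node(nid, **meta.get(nid, {}))
    d = c.n_nodes
    for i in range(d):
        for j in range(i + 1, d):
            w = c.weights[i, j]
            if w > 0:
                g.add_edge(c.node_ids[i], c.node_ids[j], weight=float(w))
    nx.write_graphml(g, path)
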