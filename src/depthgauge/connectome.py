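"""Connectome circuit analysis for the larval head of *Platynereis dumerilii*.

The ciliary photoreceptors (cPRC) of the larval brain and the rhabdomeric
photoreceptors (rPRC) of the eyespots and adult eyes sit in two distinct
synaptic circuits.  This module loads synapse-count connectivity matrices
reconstructed from serial-section EM, groups them by cell class, enumerates
short directed synaptic paths ("bridges") leading from one circuit into the
other, and computes ciliary sensory-membrane morphometrics.

Matrix convention: rows are presynaptic, columns are postsynaptic, entries
are nonnegative integer synapse counts.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CELL_CLASSES",
    "SIDES",
    "CellTable",
    "CircuitDefinition",
    "BridgePath",
    "BridgeClassSummary",
    "CiliaryBranchSet",
    "load_connectivity",
    "save_connectivity",
    "group_matrix",
    "find_bridge_paths",
    "classify_bridges",
    "membrane_area",
]

#: Controlled vocabulary of cell classes in the cPRC/rPRC circuits.
CELL_CLASSES = frozenset(
    {
        "cPRC",
        "IN_RGW",
        "IN_NOS",
        "SN_flask",
        "IN_sn",
        "IN_preMN",
        "MS",
        "vMN",
        "IN_pro",
        "rPRC_eyespot",
        "rPRC_adult_eye",
        "Ser_h1",
        "MC",
        "ciliary_band",
        "other",
    }
)

SIDES = frozenset({"left", "right", "median", "unknown"})


@dataclass(frozen=True)
class CellTable:
    """Annotated cells: ``cell_id`` (index), ``name``, ``cell_class``, ``side``."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "cell_class", "side"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        if self.df.index.duplicated().any():
            dupes = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell_ids: {dupes}")
        bad_class = set(self.df["cell_class"]) - CELL_CLASSES
        if bad_class:
            raise ValueError(f"unknown cell classes: {sorted(bad_class)}")
        bad_side = set(self.df["side"]) - SIDES
        if bad_side:
            raise ValueError(f"unknown side labels: {sorted(bad_side)}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df.index)

    def cells_of_class(self, cell_class: str) -> list[str]:
        if cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {cell_class!r}")
        return list(self.df.index[self.df["cell_class"] == cell_class])

    def class_of(self, cell_id: str) -> str:
        return str(self.df.loc[cell_id, "cell_class"])

    def class_counts(self) -> pd.Series:
        return self.df["cell_class"].value_counts().sort_index()

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str, str]]) -> "CellTable":
        df = pd.DataFrame(
            records, columns=["cell_id", "name", "cell_class", "side"]
        ).set_index("cell_id")
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "CellTable":
        df = pd.read_csv(path, dtype=str).set_index("cell_id")
        return cls(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="cell_id")


def _validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {matrix.shape}")
    if list(matrix.index) != list(matrix.columns):
        if set(matrix.index) != set(matrix.columns):
            raise ValueError("row and column cell_ids differ")
        matrix = matrix.loc[:, matrix.index]
    if matrix.index.duplicated().any():
        raise ValueError("duplicate cell_ids in matrix")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("matrix entries must be numeric")
    if np.any(values < 0):
        raise ValueError("synapse counts must be nonnegative")
    if not np.all(values == np.floor(values)):
        raise ValueError("synapse counts must be integers")
    return matrix.astype(np.int64)


def load_connectivity(matrix_path, cells_path=None) -> tuple[CellTable, pd.DataFrame]:
    """Load a synapse-count matrix CSV plus an optional cell-annotation CSV.

    The matrix CSV has cell_ids in the first row and first column; rows are
    presynaptic.  When no annotation file is given every cell is assigned
    class ``other`` and side ``unknown``.  The matrix is aligned to the cell
    table's order.
    """
    matrix = pd.read_csv(matrix_path, index_col=0)
    matrix.index = matrix.index.astype(str).rename(None)
    matrix.columns = matrix.columns.astype(str).rename(None)
    matrix = _validate_matrix(matrix)
    if cells_path is not None:
        cells = CellTable.from_csv(cells_path)
        if set(cells.cell_ids) != set(matrix.index):
            raise ValueError("cell table and matrix cover different cell_ids")
        matrix = matrix.loc[cells.cell_ids, cells.cell_ids]
    else:
        cells = CellTable.from_records(
            [(cid, cid, "other", "unknown") for cid in matrix.index]
        )
    return cells, matrix


def save_connectivity(matrix: pd.DataFrame, matrix_path, cells: CellTable | None = None, cells_path=None) -> None:
    """Write a matrix (and optionally its cell table) back to CSV, round-trip safe."""
    _validate_matrix(matrix).to_csv(matrix_path, index_label="cell_id")
    if cells is not None and cells_path is not None:
        cells.to_csv(cells_path)


def group_matrix(matrix: pd.DataFrame, cells: CellTable) -> pd.DataFrame:
    """Sum the cell-level matrix into a class-level matrix.

    Entry (A, B) is the total synapse count from all cells of class A onto
    all cells of class B; the grand total is conserved.  Classes appear in
    order of first appearance in the cell table.
    """
    matrix = _validate_matrix(matrix)
    missing = set(matrix.index) - set(cells.cell_ids)
    if missing:
        raise ValueError(f"cells missing from annotation table: {sorted(missing)}")
    classes = cells.df.loc[matrix.index, "cell_class"]
    order = list(dict.fromkeys(classes))
    grouped = matrix.groupby(classes, sort=False).sum()
    grouped = grouped.T.groupby(classes, sort=False).sum().T
    return grouped.loc[order, order]


@dataclass(frozen=True)
class CircuitDefinition:
    """The two circuits as disjoint sets of cell classes.

    Defaults follow the study system: the cPRC circuit contains the ciliary
    photoreceptors and their direct postsynaptic partners; the rPRC circuit
    contains the eyespot/adult-eye photoreceptors, their interneuron layers
    and the ventral motoneurons.
    """

    cprc_classes: frozenset[str] = frozenset(
        {"cPRC", "IN_RGW", "IN_NOS", "SN_flask", "Ser_h1", "MC"}
    )
    rprc_classes: frozenset[str] = frozenset(
        {"rPRC_eyespot", "rPRC_adult_eye", "IN_pro", "IN_sn", "vMN"}
    )

    def __post_init__(self) -> None:
        if self.cprc_classes & self.rprc_classes:
            raise ValueError("circuit class sets must be disjoint")
        unknown = (self.cprc_classes | self.rprc_classes) - CELL_CLASSES
        if unknown:
            raise ValueError(f"unknown classes in circuit definition: {sorted(unknown)}")

    def source_target(self, direction: str) -> tuple[frozenset[str], frozenset[str]]:
        token = direction.lower().replace("→", "_to_").replace("->", "_to_").replace("-", "_")
        if token in {"cprc_to_rprc"}:
            return self.cprc_classes, self.rprc_classes
        if token in {"rprc_to_cprc"}:
            return self.rprc_classes, self.cprc_classes
        raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class BridgePath:
    """A directed synaptic path from one circuit into the other.

    ``cells`` holds 2 (direct edge) or more cell_ids; ``synapses`` the
    per-edge synapse counts; ``bridge_class`` names the intermediary cell
    class, or ``direct:<srcclass>-><tgtclass>`` for a one-hop bridge.
    """

    cells: tuple[str, ...]
    synapses: tuple[int, ...]
    bridge_class: str

    def __post_init__(self) -> None:
        if len(self.cells) < 2 or len(self.synapses) != len(self.cells) - 1:
            raise ValueError("path must have >= 2 cells and one count per edge")


def find_bridge_paths(
    matrix: pd.DataFrame,
    cells: CellTable,
    circuits: CircuitDefinition | None = None,
    direction: str = "cprc_to_rprc",
    max_hops: int = 2,
    min_synapses: int = 1,
) -> list[BridgePath]:
    """Enumerate all directed synaptic paths of at most ``max_hops`` edges
    from the source circuit into the target circuit.

    An edge exists when its synapse count is >= ``min_synapses``.
    Intermediary cells must belong to neither circuit (within-circuit relays
    are not bridges).  Paths are returned deduplicated and sorted
    lexicographically by their cell_id sequence.
    """
    if circuits is None:
        circuits = CircuitDefinition()
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    src_classes, tgt_classes = circuits.source_target(direction)
    matrix = _validate_matrix(matrix)
    cls = {cid: cells.class_of(cid) for cid in matrix.index}

    g = nx.from_pandas_adjacency(
        matrix.where(matrix >= min_synapses, 0), create_using=nx.DiGraph
    )
    g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w < min_synapses])

    sources = sorted(c for c in matrix.index if cls[c] in src_classes)
    targets = {c for c in matrix.index if cls[c] in tgt_classes}
    outside = {c for c in matrix.index if cls[c] not in src_classes | tgt_classes}

    paths: list[BridgePath] = []
    for s in sources:
        if s not in g:
            continue
        for path in nx.all_simple_paths(g, s, targets, cutoff=max_hops):
            if any(v not in outside for v in path[1:-1]):
                continue
            counts = tuple(int(g[u][v]["weight"]) for u, v in zip(path[:-1], path[1:]))
            if len(path) == 2:
                bridge = f"direct:{cls[path[0]]}->{cls[path[-1]]}"
            else:
                bridge = cls[path[1]] if len(path) == 3 else "+".join(cls[v] for v in path[1:-1])
            paths.append(BridgePath(tuple(path), counts, bridge))
    paths = sorted(set(paths), key=lambda p: p.cells)
    return paths


@dataclass
class BridgeClassSummary:
    """Tally of one bridge class: paths, synapses and participating cells."""

    bridge_class: str
    n_paths: int = 0
    n_synapses: int = 0
    intermediaries: set[str] = field(default_factory=set)
    source_cells: set[str] = field(default_factory=set)
    target_cells: set[str] = field(default_factory=set)


def classify_bridges(paths: Iterable[BridgePath]) -> dict[str, BridgeClassSummary]:
    """Group bridge paths by bridge class with per-class path/synapse tallies."""
    summaries: dict[str, BridgeClassSummary] = {}
    for p in paths:
        s = summaries.setdefault(p.bridge_class, BridgeClassSummary(p.bridge_class))
        s.n_paths += 1
        s.n_synapses += sum(p.synapses)
        s.intermediaries.update(p.cells[1:-1])
        s.source_cells.add(p.cells[0])
        s.target_cells.add(p.cells[-1])
    return summaries


@dataclass(frozen=True)
class CiliaryBranchSet:
    """Ciliary branches of one or more cPRCs.

    ``diameters_nm`` and ``lengths_um`` are per-branch; ``basal_body_counts``
    is per-cell and, when given, checked against a plausibility range
    (default 12-15 basal bodies per cPRC).
    """

    diameters_nm: np.ndarray
    lengths_um: np.ndarray
    basal_body_counts: tuple[int, ...] | None = None
    basal_body_range: tuple[int, int] | None = (12, 15)

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        length = np.asarray(self.lengths_um, dtype=float)
        object.__setattr__(self, "diameters_nm", d)
        object.__setattr__(self, "lengths_um", length)
        if d.shape != length.shape:
            raise ValueError("diameters and lengths must have equal length")
        if d.size and (np.any(d <= 0) or np.any(length <= 0)):
            raise ValueError("branch diameters and lengths must be positive")
        if self.basal_body_counts is not None and self.basal_body_range is not None:
            lo, hi = self.basal_body_range
            bad = [n for n in self.basal_body_counts if not lo <= n <= hi]
            if bad:
                raise ValueError(
                    f"basal-body counts {bad} outside plausibility range [{lo}, {hi}]"
                )


def membrane_area(branches: CiliaryBranchSet) -> float:
    """Total ciliary membrane surface area in um^2.

    Each branch is modeled as an open cylinder (lateral surface pi*d*L, no
    end caps; branch tips contribute negligibly).  Diameters are in nm,
    lengths in um.
    """
    d_um = branches.diameters_nm * 1e-3
    return float(np.sum(math.pi * d_um * branches.lengths_um))
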