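"""Core domain containers shared by every pipeline stage.

The central object is the :class:`Connectome`: a symmetric, zero-diagonal,
non-negative weight matrix over an ordered set of named nodes, tagged with the
variant it represents.  Three variants are used throughout:

``binary``
    Edge present (1) iff at least one accepted streamline links the region
    pair; weights are exactly 0 or 1.
``fa_weighted``
    Edge weight is the mean fractional anisotropy (FA) of the streamlines
    linking the pair; FA is unitless in [0, 1].
``fa_normalized``
    The FA-weighted matrix divided by its total network strength, so the sum
    of weights over undirected edges (each counted once) is exactly 1.  This
    isolates the distribution of connection strength from its overall level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VARIANTS = ("binary", "fa_weighted", "fa_normalized")

__all__ = [
    "VARIANTS",
    "Connectome",
    "ParcelMap",
    "Streamline",
    "StreamlineSet",
    "SubjectRecord",
]


@dataclass
class Connectome:
    """Symmetric weighted graph over labeled brain regions.

    Parameters
    ----------
    labels : sequence of str
        Ordered node (region) names; one per matrix row/column.
    matrix : (n, n) ndarray
        Symmetric non-negative weights, zero diagonal (no self-loops).
    variant : {"binary", "fa_weighted", "fa_normalized"}
    streamline_counts : (n, n) ndarray, optional
        Per-edge accepted-streamline counts recorded at construction time.
    """

    labels: tuple
    matrix: np.ndarray
    variant: str
    streamline_counts: np.ndarray | None = None

    def __post_init__(self):
        self.labels = tuple(str(l) for l in self.labels)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"connectome matrix must be square, got {m.shape}")
        if m.shape[0] != len(self.labels):
            raise ValueError(
                f"{len(self.labels)} labels for a {m.shape[0]}-node matrix"
            )
        if np.isnan(m).any():
            raise ValueError("connectome matrix contains NaN")
        if not np.array_equal(m, m.T):
            raise ValueError("connectome matrix must be exactly symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("connectome diagonal must be zero (no self-loops)")
        if (m < 0).any():
            raise ValueError("connectome weights must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "binary" and not np.isin(m, (0.0, 1.0)).all():
            raise ValueError("binary connectome weights must be 0 or 1")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def total_strength(self) -> float:
        """Sum of weights over undirected edges, each counted once."""
        return float(np.triu(self.matrix, 1).sum())

    def edge_count(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix, 1)))

    def with_matrix(self, matrix: np.ndarray, variant: str | None = None) -> "Connectome":
        return Connectome(
            labels=self.labels,
            matrix=matrix,
            variant=variant or self.variant,
            streamline_counts=self.streamline_counts,
        )


@dataclass
class ParcelMap:
    """Integer-labeled 3-D voxel grid defining the network nodes.

    ``volume`` holds one non-negative integer label per voxel; 0 is
    background.  ``label_names`` maps each non-zero label to a region name.
    """

    volume: np.ndarray
    label_names: dict
    cerebellum_merged: bool = False

    def __post_init__(self):
        v = np.asarray(self.volume)
        if v.ndim != 3:
            raise ValueError("parcellation volume must be 3-D")
        if not np.issubdtype(v.dtype, np.integer):
            v = v.astype(np.int64)
        if (v < 0).any():
            raise ValueError("parcellation labels must be non-negative")
        self.volume = v
        self.label_names = {int(k): str(n) for k, n in self.label_names.items()}

    @property
    def node_labels(self) -> list:
        """Sorted distinct non-zero labels declared in the label table."""
        return sorted(self.label_names)

    def present_labels(self) -> list:
        """Sorted distinct non-zero labels actually present in the volume."""
        u = np.unique(self.volume)
        return [int(l) for l in u if l != 0]

    def voxel_counts(self) -> dict:
        labels, counts = np.unique(self.volume, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts) if l != 0}


@dataclass
class Streamline:
    """One tractography streamline: ordered 3-D points plus its mean FA."""

    points: np.ndarray
    mean_fa: float

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("streamline points must have shape (k, 3)")
        if p.shape[0] < 2:
            raise ValueError("a streamline needs at least 2 points")
        if not (0.0 <= self.mean_fa <= 1.0):
            raise ValueError(f"mean FA {self.mean_fa} outside [0, 1]")
        self.points = p

    @property
    def endpoints(self) -> tuple:
        return self.points[0], self.points[-1]


@dataclass
class StreamlineSet:
    streamlines: list = field(default_factory=list)

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def fa_values(self) -> np.ndarray:
        return np.array([s.mean_fa for s in self.streamlines], dtype=float)


@dataclass
class SubjectRecord:
    """Covariates, scores, and connectomes attached to one subject.

    gender is coded 0/1 (0 = female, 1 = male); maternal education is a
    3-level ordinal (0, 1, 2); gestational age (GA) is in weeks; ages in
    years.  ``group`` is "control" or "IUGR".
    """

    id: str
    group: str
    ga_weeks: float
    gender: int
    maternal_education: int
    age_at_scan: float
    age_at_test: float
    scores: dict = field(default_factory=dict)
    connectomes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in ("control", "IUGR"):
            raise ValueError(f"group must be 'control' or 'IUGR', got {self.group!r}")
        if self.ga_weeks <= 0:
            raise ValueError("gestational age must be positive")
        if self.age_at_scan <= 0 or self.age_at_test <= 0:
            raise ValueError("ages must be positive")
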