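"""Connectome construction from a labeled parcellation and streamlines.

A region pair (i, j) is connected if at least one streamline has its two
endpoints assigned to i and j respectively (self-loops excluded).  The binary
connectome records presence; the FA-weighted connectome records the arithmetic
mean of the per-streamline mean-FA values over all streamlines linking the
pair; the FA-normalized connectome divides the FA-weighted matrix by its total
network strength so each subject's normalized network has total strength
exactly 1.

Node definition follows the AAL scheme: 90 cortical regions plus a cerebellar
inventory whose parcels are merged by laterality into left cerebellum, right
cerebellum, and vermis, giving 93 network nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Connectome, ParcelMap, Streamline, StreamlineSet

logger = logging.getLogger(__name__)

# AAL cortical inventory: 45 bilateral region names -> 90 parcels, labels 1..90
# in the conventional (L, R) interleaved order.
_AAL_BASE_NAMES = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

AAL_CORTICAL_NAMES = [
    f"{base}_{side}" for base in _AAL_BASE_NAMES for side in ("L", "R")
]

# Default cerebellar inventory: 16 parcels (6 bilateral lobule pairs + 4
# vermis parcels), labels 91..106.  Configurable: any label table whose names
# end in _L / _R (hemispheric) or contain "Vermis" works.
AAL_CEREBELLAR_NAMES = [
    "Cerebelum_Crus1_L", "Cerebelum_Crus1_R",
    "Cerebelum_Crus2_L", "Cerebelum_Crus2_R",
    "Cerebelum_3_L", "Cerebelum_3_R",
    "Cerebelum_4_5_L", "Cerebelum_4_5_R",
    "Cerebelum_6_L", "Cerebelum_6_R",
    "Cerebelum_7b_L", "Cerebelum_7b_R",
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6",
]

MERGED_CEREBELLAR_NAMES = ("Cerebellum_L", "Cerebellum_R", "Vermis")


def aal_label_table() -> dict:
    """Full AAL inventory as label -> name: 90 cortical + 16 cerebellar."""
    names = AAL_CORTICAL_NAMES + AAL_CEREBELLAR_NAMES
    return {i + 1: name for i, name in enumerate(names)}


def _classify_cerebellar(name: str) -> str:
    if name.endswith("_L"):
        return "Cerebellum_L"
    if name.endswith("_R"):
        return "Cerebellum_R"
    return "Vermis"


def merge_cerebellar_labels(
    parcel_map: ParcelMap,
    cerebellar_labels: list | None = None,
    strict: bool = False,
) -> ParcelMap:
    """Merge the cerebellar parcels into 3 nodes by laterality.

    The cerebellar labels (default: the 16 labels named as in
    :data:`AAL_CEREBELLAR_NAMES`) are relabeled to three super-labels — left
    cerebellum, right cerebellum, vermis — leaving all other labels unchanged.
    On the full AAL inventory (90 cortical + 16 cerebellar parcels) the result
    has 93 distinct node labels.

    Parameters
    ----------
    cerebellar_labels : list of int, optional
        Labels to merge.  By default every label whose name appears in
        :data:`AAL_CEREBELLAR_NAMES` (matched by name, not numeric value).
    strict : bool
        If True, missing cerebellar labels raise; otherwise a warning is
        emitted and the map is returned unchanged.
    """
    table = dict(parcel_map.label_names)
    if cerebellar_labels is None:
        wanted = set(AAL_CEREBELLAR_NAMES)
        cerebellar_labels = [l for l, n in table.items() if n in wanted]
        missing = wanted - {table[l] for l in cerebellar_labels}
    else:
        cerebellar_labels = [int(l) for l in cerebellar_labels]
        missing = {l for l in cerebellar_labels if l not in table}
    if missing or not cerebellar_labels:
        msg = f"expected cerebellar labels absent: {sorted(missing) or 'all'}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; returning map unchanged", stacklevel=2)
        return ParcelMap(
            volume=parcel_map.volume.copy(),
            label_names=table,
            cerebellum_merged=parcel_map.cerebellum_merged,
        )

    base = max(table) + 1
    super_labels = {name: base + i for i, name in enumerate(MERGED_CEREBELLAR_NAMES)}
    mapping = {
        l: super_labels[_classify_cerebellar(table[l])] for l in cerebellar_labels
    }

    volume = parcel_map.volume.copy()
    for old, new in mapping.items():
        volume[parcel_map.volume == old] = new

    new_table = {l: n for l, n in table.items() if l not in mapping}
    used = set(mapping.values())
    for name, lab in super_labels.items():
        if lab in used:
            new_table[lab] = name
    return ParcelMap(volume=volume, label_names=new_table, cerebellum_merged=True)


@dataclass
class DiscardLog:
    """Counts of streamlines rejected during endpoint assignment."""

    outside_grid: int = 0
    unassigned: int = 0
    self_loop: int = 0

    @property
    def total(self) -> int:
        return self.outside_grid + self.unassigned + self.self_loop


def _assign_endpoint(point, volume, search_radius: float):
    """Label at the endpoint's voxel, with a nearest-labeled-voxel fallback.

    Background endpoints are assigned the nearest labeled voxel within
    ``search_radius`` (Euclidean, in voxels); ties broken by lowest label,
    then lexicographic voxel index.  Returns 0 if unassignable, -1 if the
    point lies outside the grid.
    """
    idx = np.floor(np.asarray(point, dtype=float)).astype(int)
    shape = volume.shape
    if (idx < 0).any() or (idx >= shape).any():
        return -1
    lab = int(volume[tuple(idx)])
    if lab != 0:
        return lab
    r = int(np.ceil(search_radius))
    best = None  # (distance, label)
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if dx == dy == dz == 0:
                    continue
                v = idx + (dx, dy, dz)
                if (v < 0).any() or (v >= shape).any():
                    continue
                cand = int(volume[tuple(v)])
                if cand == 0:
                    continue
                d = float(np.sqrt(dx * dx + dy * dy + dz * dz))
                if d > search_radius + 1e-12:
                    continue
                key = (d, cand)
                if best is None or key < best:
                    best = key
    return best[1] if best is not None else 0


def endpoints_to_regions(
    streamline: Streamline,
    parcel_map: ParcelMap,
    search_radius: float = 2.0,
    discard_log: DiscardLog | None = None,
):
    """Map a streamline's two endpoints to a region pair, or None.

    Each endpoint takes the label of its containing voxel; endpoints in
    background fall back to the nearest labeled voxel within ``search_radius``
    voxels.  Returns None (and updates ``discard_log``) if either endpoint
    stays unassigned, lies outside the grid, or both endpoints land in the
    same region (self-loop).
    """
    a, b = streamline.endpoints
    la = _assign_endpoint(a, parcel_map.volume, search_radius)
    lb = _assign_endpoint(b, parcel_map.volume, search_radius)
    if la == -1 or lb == -1:
        if discard_log is not None:
            discard_log.outside_grid += 1
        return None
    if la == 0 or lb == 0:
        if discard_log is not None:
            discard_log.unassigned += 1
        return None
    if la == lb:
        if discard_log is not None:
            discard_log.self_loop += 1
        return None
    return (la, lb)


def build_connectomes(
    streamlines: StreamlineSet,
    parcel_map: ParcelMap,
    search_radius: float = 2.0,
):
    """Build the binary and FA-weighted connectomes from a streamline set.

    binary(i, j) = 1 iff at least one accepted streamline links i and j;
    fa_weighted(i, j) = mean of the per-streamline mean-FA values over the
    accepted streamlines linking the pair (0 if none).  Per-edge streamline
    counts are stored on both outputs.

    Returns
    -------
    (binary, fa_weighted) : tuple of Connectome
    """
    labels = parcel_map.node_labels
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    fa_sum = np.zeros((n, n), dtype=float)
    log = DiscardLog()
    for s in streamlines:
        pair = endpoints_to_regions(s, parcel_map, search_radius, discard_log=log)
        if pair is None:
            continue
        i, j = index[pair[0]], index[pair[1]]
        counts[i, j] += 1
        counts[j, i] += 1
        fa_sum[i, j] += s.mean_fa
        fa_sum[j, i] += s.mean_fa
    if log.total:
        logger.info(
            "discarded %d/%d streamlines (outside grid %d, unassigned %d, "
            "self-loop %d)", log.total, len(streamlines), log.outside_grid,
            log.unassigned, log.self_loop,
        )
    if counts.sum() == 0:
        warnings.warn("no accepted streamlines: connectomes are empty", stacklevel=2)
    with np.errstate(invalid="ignore"):
        fa_w = np.where(counts > 0, fa_sum / np.maximum(counts, 1), 0.0)
    names = [parcel_map.label_names[l] for l in labels]
    binary = Connectome(names, (counts > 0).astype(float), "binary", counts)
    weighted = Connectome(names, fa_w, "fa_weighted", counts)
    return binary, weighted


def normalize_total_strength(connectome: Connectome) -> Connectome:
    """Divide every weight by the total network strength.

    Total strength sums each undirected connection once; the output connectome
    has total strength exactly 1 (to floating tolerance) and the same weight
    ratios as the input.
    """
    s = connectome.total_strength()
    if s <= 0:
        raise ValueError("cannot normalize an all-zero connectome")
    out = connectome.with_matrix(connectome.matrix / s, variant="fa_normalized")
    return out


def threshold_edges(connectome: Connectome, tau: float):
    """Edges with weight strictly greater than tau, sorted by descending weight.

    Returns a list of (label_i, label_j, weight) with i < j in node order.
    The strict inequality mirrors the display convention for high-FA
    connections (FA-weight higher than 0.3).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    m = connectome.matrix
    iu, ju = np.triu_indices(connectome.n_nodes, 1)
    keep = m[iu, ju] > tau
    edges = [
        (connectome.labels[i], connectome.labels[j], float(m[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    return edges


def group_average_connectome(connectomes: list) -> Connectome:
    """Entrywise arithmetic mean of same-variant connectomes.

    Absent edges contribute 0 to the mean.  All inputs must share node labels
    and variant; the average of binary connectomes is returned as an
    ``fa_weighted``-style weighted matrix (entry = fraction of subjects with
    the edge) only when all entries stay in {0,1}, otherwise the variant of
    the output is ``fa_weighted`` for binary inputs.
    """
    if not connectomes:
        raise ValueError("need at least one connectome to average")
    first = connectomes[0]
    for c in connectomes[1:]:
        if c.labels != first.labels:
            raise ValueError("mismatched node sets in group average")
        if c.variant != first.variant:
            raise ValueError("mismatched variants in group average")
    mean = np.mean([c.matrix for c in connectomes], axis=0)
    variant = first.variant
    if variant == "binary" and not np.isin(mean, (0.0, 1.0)).all():
        variant = "fa_weighted"  # proportion-of-subjects matrix
    return Connectome(first.labels, mean, variant)
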