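"""File formats and configuration.

Tab-separated text is the canonical interchange format: connectomes are
square matrices with a header row of node labels (plus a ``# variant:``
comment), metadata/score/metric tables are TSVs keyed by ``subject_id``.
Floats are written with ``%.17g`` (matrices) so write/read round-trips are
exact; period decimal separator, UTF-8, Unix newlines.  NIfTI label volumes
and TRK/TCK streamline files are supported as optional import adapters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Connectome, ParcelMap, Streamline, StreamlineSet
from . import synth as _synth

logger = logging.getLogger(__name__)

REQUIRED_METADATA_COLUMNS = [
    "subject_id", "group", "gender", "maternal_education", "ga_weeks",
    "age_at_scan", "age_at_test",
]

__all__ = [
    "PipelineConfig",
    "read_connectome", "write_connectome",
    "read_metadata", "write_metadata",
    "read_scores", "write_scores",
    "read_metric_table", "write_metric_table",
    "write_cohort", "read_cohort",
    "export_graphml",
    "read_parcellation_table", "read_parcellation_nifti",
    "read_streamlines_table", "read_streamlines_trk",
    "load_design", "design_to_dict", "design_from_dict",
]


# ---------------------------------------------------------------------------
# connectome matrices


def write_connectome(connectome: Connectome, path) -> None:
    path = Path(path)
    lines = [f"# variant: {connectome.variant}"]
    lines.append("\t".join(connectome.labels))
    for row in connectome.matrix:
        lines.append("\t".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_connectome(path, variant: str | None = None) -> Connectome:
    """Read a square labeled matrix; symmetrize within 1e-9, else error."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    file_variant = None
    rows = []
    header = None
    for lineno, line in enumerate(text, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            if "variant:" in line:
                file_variant = line.split("variant:", 1)[1].strip()
            continue
        if header is None:
            header = line.rstrip("\n").split("\t")
            continue
        vals = line.rstrip("\n").split("\t")
        if len(vals) != len(header):
            raise ValueError(
                f"{path}: row {lineno} has {len(vals)} values for "
                f"{len(header)} header labels"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError as err:
            raise ValueError(f"{path}: unparseable value in row {lineno}: {err}")
    if header is None or not rows:
        raise ValueError(f"{path}: no matrix data")
    m = np.asarray(rows, dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[0] != len(header):
        raise ValueError(
            f"{path}: matrix shape {m.shape} does not match "
            f"{len(header)} header labels"
        )
    if np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise ValueError(f"{path}: NaN entry at row {i + 1}, column {j + 1}")
    asym = np.abs(m - m.T).max()
    if asym > 1e-9:
        i, j = np.unravel_index(np.argmax(np.abs(m - m.T)), m.shape)
        raise ValueError(
            f"{path}: matrix asymmetric beyond tolerance at ({i + 1}, {j + 1}): "
            f"|delta| = {asym:g}"
        )
    if asym > 0:
        warnings.warn(f"{path}: symmetrizing matrix (max asymmetry {asym:g})",
                      stacklevel=2)
        m = 0.5 * (m + m.T)
    variant = variant or file_variant
    if variant is None:
        variant = "binary" if np.isin(m, (0.0, 1.0)).all() else "fa_weighted"
    return Connectome(labels=header, matrix=m, variant=variant)


# ---------------------------------------------------------------------------
# tabular files


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ValueError(f"{path}: cannot parse TSV: {err}") from err


def read_metadata(path) -> pd.DataFrame:
    """Subject metadata TSV -> DataFrame indexed by subject id."""
    df = _read_tsv(path)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = ~df["group"].isin(["control", "IUGR"])
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path}: invalid group {df.loc[row, 'group']!r} in row {row + 2} "
            "(expected 'control' or 'IUGR')"
        )
    for col in ["gender", "maternal_education", "ga_weeks", "age_at_scan",
                "age_at_test"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: column {col!r} not numeric: {err}")
    return df.set_index("subject_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")


def read_scores(path) -> pd.DataFrame:
    """Score TSV (subject_id + one numeric column per score)."""
    df = _read_tsv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'subject_id'")
    df = df.set_index("subject_id")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: score column {col!r} not numeric: {err}")
    return df


write_scores = write_metadata


def read_metric_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'subject_id'")
    return df.set_index("subject_id")


def write_metric_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.12g", lineterminator="\n")


# ---------------------------------------------------------------------------
# cohorts on disk


def write_cohort(subjects, outdir) -> None:
    """Metadata TSV + scores TSV + one matrix file per subject and variant."""
    outdir = Path(outdir)
    (outdir / "connectomes").mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame([
        dict(subject_id=s.id, group=s.group, gender=s.gender,
             maternal_education=s.maternal_education, ga_weeks=s.ga_weeks,
             age_at_scan=s.age_at_scan, age_at_test=s.age_at_test)
        for s in subjects
    ]).set_index("subject_id")
    write_metadata(meta, outdir / "metadata.tsv")
    if any(s.scores for s in subjects):
        scores = pd.DataFrame([dict(subject_id=s.id, **s.scores) for s in subjects]
                              ).set_index("subject_id")
        write_scores(scores, outdir / "scores.tsv")
    for s in subjects:
        for variant, conn in s.connectomes.items():
            write_connectome(conn, outdir / "connectomes" / f"{s.id}_{variant}.tsv")


def read_cohort(indir):
    """Inverse of :func:`write_cohort`.

    Returns (metadata, scores-or-None, {subject_id: {variant: Connectome}}).
    """
    indir = Path(indir)
    meta = read_metadata(indir / "metadata.tsv")
    scores = None
    if (indir / "scores.tsv").exists():
        scores = read_scores(indir / "scores.tsv")
    conns: dict = {}
    for f in sorted((indir / "connectomes").glob("*.tsv")):
        stem = f.stem
        for variant in ("binary", "fa_weighted", "fa_normalized"):
            if stem.endswith(f"_{variant}"):
                sid = stem[: -len(variant) - 1]
                conns.setdefault(sid, {})[variant] = read_connectome(f, variant)
                break
    return meta, scores, conns


# ---------------------------------------------------------------------------
# optional adapters and exports


def export_graphml(connectome: Connectome, path, tau: float | None = None) -> None:
    """GraphML export of the (optionally thresholded) edge list."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(connectome.labels)
    m = connectome.matrix
    iu, ju = np.triu_indices(connectome.n_nodes, 1)
    for i, j in zip(iu, ju):
        w = m[i, j]
        if w > (tau if tau is not None else 0.0):
            g.add_edge(connectome.labels[i], connectome.labels[j], weight=float(w))
    nx.write_graphml(g, path)


def read_parcellation_table(path, label_names: dict | None = None) -> ParcelMap:
    """Voxel-table parcellation: TSV with columns x, y, z, label."""
    df = _read_tsv(path)
    for c in ("x", "y", "z", "label"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    dims = tuple(int(df[c].max()) + 1 for c in ("x", "y", "z"))
    vol = np.zeros(dims, dtype=np.int64)
    vol[df["x"].to_numpy(int), df["y"].to_numpy(int), df["z"].to_numpy(int)] = (
        df["label"].to_numpy(int)
    )
    if label_names is None:
        label_names = {int(l): f"Region_{int(l)}" for l in np.unique(vol) if l != 0}
    return ParcelMap(volume=vol, label_names=label_names)


def read_parcellation_nifti(path, label_names: dict | None = None) -> ParcelMap:
    """NIfTI label-volume import (voxel-grid coordinates)."""
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj).astype(np.int64)
    if label_names is None:
        label_names = {int(l): f"Region_{int(l)}" for l in np.unique(vol) if l != 0}
    return ParcelMap(volume=vol, label_names=label_names)


def read_streamlines_table(path) -> StreamlineSet:
    """Streamline table: columns streamline_id, x, y, z, fa (one point/row)."""
    df = _read_tsv(path)
    for c in ("streamline_id", "x", "y", "z", "fa"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    out = []
    for sid, g in df.groupby("streamline_id", sort=True):
        fa = g["fa"].to_numpy(float)
        if np.ptp(fa) > 1e-9:
            raise ValueError(
                f"{path}: streamline {sid} has non-constant fa column "
                "(one mean-FA value per streamline expected)"
            )
        out.append(Streamline(points=g[["x", "y", "z"]].to_numpy(float),
                              mean_fa=float(fa[0])))
    return StreamlineSet(out)


def read_streamlines_trk(path, fa_values) -> StreamlineSet:
    """TRK/TCK adapter (voxel coordinates); per-streamline FA supplied separately."""
    import nibabel as nib

    tf = nib.streamlines.load(str(path))
    fa_values = np.asarray(fa_values, dtype=float)
    sl = list(tf.streamlines)
    if fa_values.shape[0] != len(sl):
        raise ValueError(
            f"{len(sl)} streamlines but {fa_values.shape[0]} FA values"
        )
    return StreamlineSet([
        Streamline(points=np.asarray(p, dtype=float), mean_fa=float(f))
        for p, f in zip(sl, fa_values)
    ])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """End-to-end pipeline options.

    tau is the edge-display threshold for high-FA exports; alpha/trend are
    the significance and trend levels of the statistical report.
    """

    out_dir: str = "devconn_out"
    variants: tuple = ("binary", "fa_weighted", "fa_normalized")
    tau: float = 0.3
    alpha: float = 0.05
    trend: float = 0.1
    seed: int = 0
    log_level: str = "INFO"
    design: str | None = None
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}, sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def design_to_dict(design: _synth.CohortDesign) -> dict:
    return {
        "n_nodes": design.n_nodes,
        "gender_p": design.gender_p,
        "edu_probs": list(design.edu_probs),
        "n_clumps": design.n_clumps,
        "fa_floor": design.fa_floor,
        "seed": design.seed,
        "cells": [vars(c).copy() for c in design.cells],
        "score_models": [vars(m).copy() for m in design.score_models],
    }


def design_from_dict(d: dict) -> _synth.CohortDesign:
    cells = [_synth.CellDesign(**c) for c in d.get("cells", [])]
    models = [_synth.ScoreModel(**m) for m in d.get("score_models", [])]
    kwargs = {k: d[k] for k in ("n_nodes", "gender_p", "n_clumps", "fa_floor",
                                "seed") if k in d}
    if "edu_probs" in d:
        kwargs["edu_probs"] = tuple(d["edu_probs"])
    return _synth.CohortDesign(cells=cells, score_models=models, **kwargs)


def load_design(name_or_path: str, seed: int | None = None,
                n_control: int | None = None,
                n_iugr: int | None = None) -> _synth.CohortDesign:
    """Resolve a design name or YAML path.

    Built-in names: ``default`` (all three ages), ``default1y``,
    ``default6y``, ``default10y``.
    """
    named = {
        "default": (1, 6, 10), "default1y": (1,), "default6y": (6,),
        "default10y": (10,),
    }
    if name_or_path in named:
        design = _synth.default_design(ages=named[name_or_path], n_control=n_control,
                                       n_iugr=n_iugr)
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise ValueError(f"unknown design {name_or_path!r} (not a name or a file)")
        design = design_from_dict(yaml.safe_load(path.read_text()))
    if seed is not None:
        design.seed = seed
    return design
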