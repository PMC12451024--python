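"""Readers and writers for the on-disk cohort layout and result tables.

One canonical plain-text layout is shared by the simulator and the
analysis stages, so a real cohort can be dropped in without code changes:

- per subject, one whitespace-delimited square matrix file for streamline
  counts and one for mean FA;
- a tab-delimited manifest with columns ``subject_id, counts_path,
  fa_path, group`` (paths relative to the manifest's directory);
- a tab-delimited behavioral table whose header names exactly the fields
  of :class:`~hubnet.behavior.BehavioralRecord`.

Result tables are tab-delimited with headers; floats are printed at six
significant digits except p-values below 1e-4, which use scientific
notation (the ``%.6g`` format does both).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BEHAVIOR_COLUMNS, BehavioralRecord
from .connectome import BackboneNetwork, SubjectConnectome

MANIFEST_COLUMNS = ["subject_id", "counts_path", "fa_path", "group"]


def _load_matrix(path: Path, subject_id: str, kind: str) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(
            f"subject {subject_id}: {kind} matrix {path} is not square "
            f"(shape {m.shape})"
        )
    if np.any(np.isnan(m)):
        i, j = map(int, np.argwhere(np.isnan(m))[0])
        raise ValueError(
            f"subject {subject_id}: {kind} matrix has NaN at cell ({i}, {j})"
        )
    asym = np.abs(m - m.T).max()
    if asym >= 1e-8:
        i, j = map(int, np.argwhere(np.abs(m - m.T) == asym)[0])
        raise ValueError(
            f"subject {subject_id}: {kind} matrix asymmetric at cell "
            f"({i}, {j}) by {asym:g}"
        )
    return (m + m.T) / 2


def read_cohort(manifest_path: str | Path) -> list[SubjectConnectome]:
    """Load and validate every subject connectome listed in a manifest."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    root = manifest_path.parent
    cohort: list[SubjectConnectome] = []
    for row in manifest.itertuples(index=False):
        counts = _load_matrix(root / row.counts_path, row.subject_id, "count")
        fa = _load_matrix(root / row.fa_path, row.subject_id, "FA")
        if np.any((fa < 0) | (fa > 1)):
            i, j = map(int, np.argwhere((fa < 0) | (fa > 1))[0])
            raise ValueError(
                f"subject {row.subject_id}: FA outside [0, 1] at cell ({i}, {j})"
            )
        support_bad = (fa > 0) & (counts == 0)
        if np.any(support_bad):
            i, j = map(int, np.argwhere(support_bad)[0])
            raise ValueError(
                f"subject {row.subject_id}: FA > 0 where count = 0 at cell "
                f"({i}, {j}) (support mismatch)"
            )
        cohort.append(
            SubjectConnectome(row.subject_id, counts.round().astype(int), fa)
        )
    return cohort


def write_cohort(
    out_dir: str | Path,
    connectomes: Sequence[SubjectConnectome],
    records: Sequence[BehavioralRecord],
    groups: Sequence[str] | None = None,
) -> Path:
    """Write a cohort in the canonical layout; returns the manifest path.

    Count matrices are written as integers and FA matrices at full float
    precision, so a write-read round trip is exact.
    """
    from .behavior import classify_readers, records_to_frame

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if groups is None:
        groups = classify_readers(records)
    rows = []
    for s, g in zip(connectomes, groups):
        counts_name = f"{s.subject_id}_counts.txt"
        fa_name = f"{s.subject_id}_fa.txt"
        np.savetxt(out_dir / counts_name, s.count_matrix, fmt="%d")
        np.savetxt(out_dir / fa_name, s.fa_matrix, fmt="%.17g")
        rows.append((s.subject_id, counts_name, fa_name, g))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    records_to_frame(records).to_csv(
        out_dir / "behavior.tsv", sep="\t", index=False
    )
    return manifest_path


def read_behavior(path: str | Path) -> list[BehavioralRecord]:
    """Load the behavioral table; every record field must be present."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in BEHAVIOR_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"behavioral table missing columns: {missing}")
    if frame[BEHAVIOR_COLUMNS].isna().any().any():
        bad = [c for c in BEHAVIOR_COLUMNS if frame[c].isna().any()]
        raise ValueError(f"behavioral table has missing values in: {bad}")
    return [
        BehavioralRecord(**{c: row[c] for c in BEHAVIOR_COLUMNS})
        for row in frame.to_dict("records")
    ]


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited result table, floats at 6 significant digits."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_backbone(backbone: BackboneNetwork, out_dir: str | Path) -> None:
    """Export a backbone as an edge list and a binary adjacency matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iu = np.triu_indices(backbone.n_regions, 1)
    keep = backbone.adjacency[iu] == 1
    edges = pd.DataFrame(
        {
            "region_i": [backbone.region_labels[i] for i in iu[0][keep]],
            "region_j": [backbone.region_labels[j] for j in iu[1][keep]],
        }
    )
    edges.to_csv(out_dir / "backbone_edges.tsv", sep="\t", index=False)
    np.savetxt(out_dir / "backbone_adjacency.txt", backbone.adjacency, fmt="%d")
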