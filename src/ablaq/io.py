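"""Reading and writing masks, fiducial markups and manifests.

Masks are read with SimpleITK, which handles NIfTI (.nii/.nii.gz) and NRRD
transparently; any nonzero label collapses to foreground 1.  Voxel arrays
are stored index-ordered (i, j, k) to match the header's axis order.

World-coordinate convention: coordinates are used exactly as the files
declare them (SimpleITK reports physical points in LPS).  Markup files and
mask headers are assumed to share one world frame; no anatomical-axis
conversion is performed — see :mod:`ablaq.core`.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import ApplicatorLine, MaskVolume

__all__ = [
    "read_mask",
    "write_mask",
    "read_markups",
    "write_markups_fcsv",
    "applicator_from_markups",
]


def read_mask(path) -> MaskVolume:
    """Read a NIfTI or NRRD label image as a binary MaskVolume.

    Raises ValueError naming the file when the image is empty (all zero).
    """
    path = Path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:
        raise ValueError(f"unreadable mask file {path}: {e}") from e
    arr = sitk.GetArrayFromImage(img)  # (k, j, i)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {arr.ndim}D")
    voxels = np.transpose(arr, (2, 1, 0))
    if not (voxels != 0).any():
        raise ValueError(f"empty mask: {path} contains no foreground voxels")
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return MaskVolume(
        voxels=voxels,
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        direction=direction,
    )


def write_mask(mask: MaskVolume, path) -> None:
    """Write a MaskVolume as NIfTI or NRRD (format chosen by extension)."""
    img = sitk.GetImageFromArray(np.transpose(mask.voxels, (2, 1, 0)))
    img.SetSpacing(tuple(mask.spacing))
    img.SetOrigin(tuple(mask.origin))
    img.SetDirection(tuple(mask.direction.ravel()))
    sitk.WriteImage(img, str(Path(path)))


def _read_fcsv(path: Path):
    labels, points = [], []
    columns = ["id", "x", "y", "z", "label"]
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "columns" in line and "=" in line:
                    columns = [c.strip() for c in line.split("=", 1)[1].split(",")]
                continue
            fields = next(csv.reader([line]))
            row = dict(zip(columns, fields))
            labels.append(row.get("label", row.get("id", str(len(labels)))))
            points.append([float(row["x"]), float(row["y"]), float(row["z"])])
    return labels, np.asarray(points, dtype=float)


def _read_plain_csv(path: Path):
    labels, points = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower(): c for c in (reader.fieldnames or [])}
        if not {"x", "y", "z"} <= set(cols):
            raise ValueError(f"{path}: fiducial CSV needs x,y,z columns")
        label_col = cols.get("label") or cols.get("id")
        for i, row in enumerate(reader):
            labels.append(row[label_col] if label_col else str(i))
            points.append([float(row[cols["x"]]), float(row[cols["y"]]),
                           float(row[cols["z"]])])
    return labels, np.asarray(points, dtype=float)


def _read_mrk_json(path: Path):
    with open(path) as fh:
        data = json.load(fh)
    labels, points = [], []
    for markup in data.get("markups", []):
        for cp in markup.get("controlPoints", []):
            labels.append(cp.get("label", str(len(labels))))
            points.append([float(v) for v in cp["position"]])
    return labels, np.asarray(points, dtype=float)


def read_markups(path):
    """Read labeled world points from a fiducial CSV (.fcsv or plain CSV
    with x,y,z[,label] columns) or a Slicer-style markup JSON.

    Returns (labels, points) with order preserved.  Duplicate labels raise.
    """
    path = Path(path)
    if path.suffix.lower() == ".json" or path.name.endswith(".mrk.json"):
        labels, points = _read_mrk_json(path)
    elif path.suffix.lower() == ".fcsv":
        labels, points = _read_fcsv(path)
    else:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            labels, points = _read_fcsv(path)
        else:
            labels, points = _read_plain_csv(path)
    if len(labels) == 0:
        raise ValueError(f"{path}: no points found")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"{path}: duplicate point labels {dupes}")
    return labels, points


def write_markups_fcsv(labels, points, path) -> None:
    """Write labeled points as a fiducial CSV (id,x,y,z,label columns)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    with open(path, "w", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# columns = id,x,y,z,label\n")
        w = csv.writer(fh)
        for i, (label, p) in enumerate(zip(labels, points)):
            w.writerow([i, repr(float(p[0])), repr(float(p[1])), repr(float(p[2])), label])


def applicator_from_markups(labels, points) -> ApplicatorLine:
    """Build an ApplicatorLine from two points labeled 'shaft' and 'tip'."""
    if len(labels) < 2:
        raise ValueError("applicator markup needs 2 points (shaft and tip)")
    lower = [str(l).lower() for l in labels]
    try:
        i_shaft = lower.index("shaft")
        i_tip = lower.index("tip")
    except ValueError:
        if len(labels) == 2:  # fall back to order: shaft first, tip second
            i_shaft, i_tip = 0, 1
        else:
            raise ValueError(
                "applicator markup must label its points 'shaft' and 'tip'"
            ) from None
    return ApplicatorLine.from_points(points[i_shaft], points[i_tip])
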