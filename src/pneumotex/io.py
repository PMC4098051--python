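"""File plumbing: ROI images, manifests, feature tables, model files.

ROIs travel as 16-bit grayscale PNGs next to a CSV manifest; enhanced
images as 32-bit float TIFFs with a JSON parameter sidecar; trained
network models as structured JSON (layer sizes, row-major weight lists,
hyperparameters, seed).  Every CSV written by the pipeline carries a
``# pneumotex ...`` provenance comment line with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .classify import AnnModel
from .core import LabelledRoi, TextureConfig
from .spectrum import FeatureVector


def config_hash(mapping: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    blob = json.dumps(mapping, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, provenance: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# pneumotex {provenance}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_rois(rois: Iterable[LabelledRoi], manifest: pd.DataFrame, outdir,
               provenance: Optional[str] = None) -> None:
    """Write ROIs as 16-bit PNGs plus the manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for roi in rois:
        arr = np.clip(np.round(roi.pixels), 0, 65535).astype(np.uint16)
        iio.imwrite(outdir / f"{roi.id}.png", arr)
    write_csv(manifest, outdir / "manifest.csv", provenance)


def read_rois(indir, config: Optional[TextureConfig] = None) -> List[LabelledRoi]:
    """Load a PNG/manifest ROI directory back into LabelledRoi objects."""
    indir = Path(indir)
    manifest = read_csv(indir / "manifest.csv")
    config = config or TextureConfig()
    rois = []
    for row in manifest.itertuples():
        pixels = np.asarray(iio.imread(indir / f"{row.id}.png"), dtype=float)
        rois.append(
            LabelledRoi(pixels=pixels, label=row.label, config=config, id=row.id)
        )
    return rois


def write_enhanced(matrix: np.ndarray, params: dict, path) -> None:
    """32-bit float TIFF plus a JSON sidecar of branch parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(matrix, dtype=np.float32))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(params, fh, indent=1, default=str)


def features_frame(features: Dict[str, FeatureVector], labels: Dict[str, str],
                   branches: Iterable[str]) -> pd.DataFrame:
    """Long-format feature table: one row per (ROI, branch)."""
    rows = []
    for roi_id, fv in features.items():
        for branch in branches:
            vec = fv.branch_features[branch]
            ang = fv.angles.get(branch, (np.nan, np.nan))
            row = {
                "id": roi_id,
                "label": labels[roi_id],
                "branch": branch,
                "angle_main": ang[0],
                "angle_second": ang[1],
            }
            row.update({f"f_{i + 1:03d}": v for i, v in enumerate(vec)})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_features(df: pd.DataFrame) -> Tuple[Dict[str, FeatureVector], Dict[str, str]]:
    """Inverse of :func:`features_frame`."""
    feats: Dict[str, FeatureVector] = {}
    labels: Dict[str, str] = {}
    fcols = sorted(c for c in df.columns if c.startswith("f_"))
    for (roi_id,), grp in df.groupby(["id"], sort=False):
        branch_features = {}
        angles = {}
        for row in grp.itertuples():
            vec = np.array([getattr(row, c) for c in fcols], dtype=float)
            vec = vec[~np.isnan(vec)]
            branch_features[row.branch] = vec
            angles[row.branch] = (row.angle_main, row.angle_second)
            labels[roi_id] = row.label
        feats[roi_id] = FeatureVector(branch_features=branch_features, angles=angles)
    return feats, labels


def write_model(model: AnnModel, path, provenance: Optional[str] = None) -> None:
    doc = {
        "format": "pneumotex-ann-v1",
        "provenance": provenance,
        "arch": list(model.arch),
        "w1": model.w1.ravel().tolist(),  # row-major (n_in x n_hidden)
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "hyper": model.hyper,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model(path) -> AnnModel:
    with open(path) as fh:
        doc = json.load(fh)
    n_in, n_hidden, _ = doc["arch"]
    return AnnModel(
        w1=np.array(doc["w1"], dtype=float).reshape(n_in, n_hidden),
        b1=np.array(doc["b1"], dtype=float),
        w2=np.array(doc["w2"], dtype=float),
        b2=float(doc["b2"]),
        hyper=doc.get("hyper", {}),
    )
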