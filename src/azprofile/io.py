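"""Standard-format I/O: TIFF stacks, CSV tables, YAML configs and sidecars.

Stacks travel as multi-page TIFF (ZYX page order).  Physical spacing is
carried in a YAML sidecar next to each stack (``<stack>.yaml``) because
TIFF resolution-tag dialects vary; the sidecar wins over tags on conflict.
Cluster and ground-truth tables are plain CSV with fixed headers; table
metadata (sample id, spacing, mean NND) rides in a sidecar as well.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import (
    CLUSTER_COLUMNS,
    ClusterTable,
    LabelVolume,
    PointSpreadFunction,
    TRUTH_COLUMNS,
    VolumetricImage,
)


def _sidecar_path(path: str) -> str:
    return str(path) + ".yaml"


def _write_sidecar(path: str, payload: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _read_sidecar(path: str) -> Optional[dict]:
    sp = _sidecar_path(path)
    if not os.path.exists(sp):
        return None
    with open(sp) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError(f"{sp}: sidecar must be a YAML mapping")
    return loaded


# ---------------------------------------------------------------------------
# stacks


def write_stack(path, image: VolumetricImage) -> None:
    tifffile.imwrite(str(path), np.asarray(image.data), photometric="minisblack")
    _write_sidecar(str(path), {"spacing_um_zyx": [float(s) for s in image.spacing]})


def read_stack(path, spacing=None) -> VolumetricImage:
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable TIFF stack ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    side = _read_sidecar(str(path))
    if side is not None and "spacing_um_zyx" in side:
        spacing = tuple(side["spacing_um_zyx"])
    elif spacing is None:
        raise ValueError(f"{path}: no spacing sidecar found and none supplied")
    return VolumetricImage(data=data, spacing=tuple(spacing))


def write_labels(path, labels: LabelVolume) -> None:
    tifffile.imwrite(str(path), labels.labels.astype(np.int32),
                     photometric="minisblack")
    _write_sidecar(str(path), {
        "spacing_um_zyx": [float(s) for s in labels.spacing],
        "names": {int(k): str(v) for k, v in labels.names.items()},
    })


def read_labels(path) -> LabelVolume:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    side = _read_sidecar(str(path)) or {}
    spacing = tuple(side.get("spacing_um_zyx", (1.0, 1.0, 1.0)))
    names = {int(k): str(v) for k, v in side.get("names", {}).items()}
    return LabelVolume(labels=data.astype(np.int32), spacing=spacing, names=names)


# ---------------------------------------------------------------------------
# PSF


def write_psf(path, psf: PointSpreadFunction) -> None:
    tifffile.imwrite(str(path), psf.kernel.astype(np.float32),
                     photometric="minisblack")
    _write_sidecar(str(path), {
        "spacing_um_zyx": [float(s) for s in psf.spacing],
        "n_beads_averaged": int(psf.n_beads_averaged),
    })


def read_psf(path) -> PointSpreadFunction:
    kernel = tifffile.imread(str(path)).astype(float)
    side = _read_sidecar(str(path))
    if side is None:
        raise ValueError(f"{path}: PSF requires a YAML sidecar with spacing")
    return PointSpreadFunction(kernel=kernel,
                               spacing=tuple(side["spacing_um_zyx"]),
                               n_beads_averaged=int(side.get("n_beads_averaged", 1)))


# ---------------------------------------------------------------------------
# tables


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def write_table(path, table: ClusterTable) -> None:
    cols = CLUSTER_COLUMNS + [c for c in ("nnd_um", "az_density", "local_intensity")
                              if c in table.df.columns]
    table.df[cols].to_csv(str(path), index=False)
    _write_sidecar(str(path), {
        "sample_id": table.sample_id,
        "condition": table.condition,
        "spacing_um_zyx": None if table.spacing is None
        else [float(s) for s in table.spacing],
        "mean_nnd_um": table.mean_nnd,
        "radius_r_um": table.radius_r,
    })


def read_table(path) -> ClusterTable:
    try:
        df = pd.read_csv(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable CSV table ({exc})") from exc
    _require_columns(df, CLUSTER_COLUMNS, path)
    df["compartment"] = df["compartment"].fillna("").astype(str)
    side = _read_sidecar(str(path)) or {}
    spacing = side.get("spacing_um_zyx")
    return ClusterTable(
        df=df,
        sample_id=str(side.get("sample_id", "") or ""),
        condition=str(side.get("condition", "") or ""),
        spacing=None if spacing is None else tuple(spacing),
        mean_nnd=side.get("mean_nnd_um"),
        radius_r=side.get("radius_r_um"),
    )


def write_truth(path, truth: pd.DataFrame) -> None:
    truth[TRUTH_COLUMNS].to_csv(str(path), index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    _require_columns(df, TRUTH_COLUMNS, path)
    df["compartment"] = df["compartment"].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# configs


def read_yaml(path) -> dict:
    try:
        with open(str(path)) as fh:
            loaded = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: malformed YAML ({exc})") from exc
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return loaded
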