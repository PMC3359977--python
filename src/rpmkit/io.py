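"""File formats: track CSV, observation CSV, nucleus TIFF + YAML sidecar.

Tracks travel as CSV with columns ``cell_id, spot_id, frame, t_s, x_um,
y_um`` (plus optional ``genotype, locus, timepoint_h, paired``);
coordinates are physical projected µm.  Nucleus stacks travel as
multi-page TIFF in (channel, z, y, x) page order with a YAML sidecar
(``<stack>.yaml``) declaring channel order and voxel sizes in µm.  Output
tables are TSV with a ``#``-prefixed provenance header (package version,
config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .bouquet import CHANNELS, NucleusImage
from .pairing import CellSpotObservation
from .rpm import SpotTrack

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_observations",
    "write_observations",
    "read_stack",
    "write_stack",
    "write_table",
]

TRACK_COLUMNS = ("cell_id", "spot_id", "frame", "t_s", "x_um", "y_um")
_TRACK_META = ("genotype", "locus", "timepoint_h", "paired")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_tracks(path) -> list[SpotTrack]:
    """Read per-spot tracks from CSV, validating uniform frame spacing."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACK_COLUMNS, path)
    tracks = []
    for (cell_id, spot_id), grp in df.groupby(["cell_id", "spot_id"], sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            rows = grp.index[np.diff(frames, prepend=frames[0] - 1) != 1].tolist()
            raise ValueError(
                f"{path}: non-contiguous frame numbers for cell {cell_id!r} "
                f"spot {spot_id!r} near data rows {rows[:5]}"
            )
        dts = np.diff(grp["t_s"].to_numpy())
        if len(dts) and not np.allclose(dts, dts[0]):
            raise ValueError(
                f"{path}: non-uniform t_s spacing for cell {cell_id!r} spot {spot_id!r}"
            )
        meta = {}
        for col in _TRACK_META:
            if col in grp.columns:
                v = grp[col].iloc[0]
                meta[col] = None if pd.isna(v) else v
        paired = meta.pop("paired", None)
        tracks.append(
            SpotTrack(
                positions=grp[["x_um", "y_um"]].to_numpy(),
                dt_s=float(dts[0]) if len(dts) else 1.0,
                cell_id=str(cell_id),
                spot_id=str(spot_id),
                paired=None if paired is None else bool(paired),
                genotype=str(meta.get("genotype") or ""),
                locus=str(meta.get("locus") or ""),
                timepoint_h=meta.get("timepoint_h"),
            )
        )
    if not tracks:
        raise ValueError(f"{path}: no tracks found")
    return tracks


def write_tracks(tracks: Iterable[SpotTrack], path) -> None:
    """Write tracks to CSV (positions rounded to 6 decimals of a µm)."""
    rows = []
    for t in tracks:
        for frame, (x, y) in enumerate(t.positions):
            rows.append(
                dict(
                    cell_id=t.cell_id,
                    spot_id=t.spot_id,
                    frame=frame,
                    t_s=frame * t.dt_s,
                    x_um=round(float(x), 6),
                    y_um=round(float(y), 6),
                    genotype=t.genotype,
                    locus=t.locus,
                    timepoint_h=t.timepoint_h,
                    paired=t.paired,
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


OBS_COLUMNS = ("cell_id", "n_spots")


def read_observations(path) -> list[CellSpotObservation]:
    """Read per-cell spot-count observations from CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, OBS_COLUMNS, path)
    obs = []
    for i, row in df.iterrows():
        try:
            sep = row.get("spot_separation_um")
            obs.append(
                CellSpotObservation(
                    cell_id=str(row["cell_id"]),
                    n_spots=int(row["n_spots"]),
                    spot_separation_um=None if pd.isna(sep) else float(sep),
                    stage=str(row.get("stage", "zip1_spots")),
                    trap=str(row.get("trap", "none")),
                    genotype=str(row.get("genotype", "") or ""),
                    locus_pair=str(row.get("locus_pair", "") or ""),
                    timepoint_h=None
                    if pd.isna(row.get("timepoint_h"))
                    else float(row["timepoint_h"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: bad observation at data row {i}: {exc}") from exc
    return obs


def write_observations(observations: Iterable[CellSpotObservation], path) -> None:
    pd.DataFrame([vars(o) for o in observations]).to_csv(path, index=False)


def write_stack(image: NucleusImage, path) -> None:
    """Write a nucleus stack as multi-page TIFF plus a YAML sidecar.

    Pages are ordered channel-major then z; the sidecar records channel
    names, per-axis voxel sizes (µm) and the array shape.
    """
    path = Path(path)
    c, z, y, x = image.voxels.shape
    tifffile.imwrite(path, image.voxels.astype(np.float32).reshape(c * z, y, x))
    sz, sy, sx = image.voxel_size_zyx
    sidecar = {
        "channels": list(CHANNELS),
        "voxel_size_um": {"x": sx, "y": sy, "z": sz},
        "shape": {"channels": c, "z": z, "y": y, "x": x},
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_stack(path, channel_map: Mapping[str, int] | None = None) -> NucleusImage:
    """Read a multi-page TIFF stack with its YAML sidecar.

    ``channel_map`` maps the canonical names TEL/SPB/DNA to channel
    indices in the file; by default the sidecar's channel order is used.
    """
    path = Path(path)
    pages = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = yaml.safe_load(Path(str(path) + ".yaml").read_text())
    shape = sidecar["shape"]
    vols = pages.reshape(shape["channels"], shape["z"], shape["y"], shape["x"])
    names = sidecar["channels"]
    if channel_map is None:
        channel_map = {name: names.index(name) for name in CHANNELS}
    unknown = set(channel_map) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channel names {sorted(unknown)}; expected {CHANNELS}")
    vs = sidecar["voxel_size_um"]
    return NucleusImage(
        voxels=np.stack([vols[channel_map[name]] for name in CHANNELS]),
        voxel_size_zyx=(float(vs["z"]), float(vs["y"]), float(vs["x"])),
        provenance="file",
    )


def write_table(df: pd.DataFrame, path, *, config: Mapping | None = None, seed=None) -> None:
    """Write a results table as TSV with a provenance header.

    The header records the package version, a hash of the run
    configuration, and the seed, so a rerun with identical config can be
    verified to reproduce the output.
    """
    config_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    header = (
        f"# rpmkit {__version__}\n"
        f"# config_hash: {config_hash}\n"
        f"# seed: {seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
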