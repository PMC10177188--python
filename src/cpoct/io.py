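"""Volume, ROI-table and map containers with bit-stable file round-trips.

A CP-OCT acquisition is stored as a directory containing one multi-page TIFF
per polarization channel (axial slices as pages) plus a JSON sidecar carrying
the voxel geometry.  All signal values are linear-scale (never dB) and
non-negative; dB conversion happens only at rendering time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("co", "cross")
CLASS_LABELS = ("AT", "NCT", "HTS", "LDTC", "HDTC")

SIDECAR_NAME = "volume.json"


@dataclass
class OCTVolume:
    """Two-channel 3D linear-scale OCT signal with voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (2, nz, nx, ny)
        Linear-scale signal, channel axis ordered (co, cross).  z = 0 is the
        shallowest pixel (probe side); depth increases with z.
    delta_z : float
        Axial pixel size in mm.
    pitch_xy : float
        Lateral pixel pitch in mm (isotropic in x and y).
    meta : dict
        Free-form acquisition record (wavelength, date, specimen id, ...).
    """

    data: np.ndarray
    delta_z: float
    pitch_xy: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != len(CHANNELS):
            raise ValueError(
                f"volume data must have shape (2, nz, nx, ny); got {self.data.shape}"
            )
        if not (self.delta_z > 0 and self.pitch_xy > 0):
            raise ValueError("delta_z and pitch_xy must be positive")
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN values")
        neg = self.data < 0
        if neg.any():
            ch, z = np.argwhere(neg)[0][:2]
            raise ValueError(
                f"negative signal values (linear scale required); first offending "
                f"plane: channel '{CHANNELS[ch]}', z index {z}"
            )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D (z, x, y) array of one polarization channel."""
        return self.data[channel_index(name)]

    def depth_axis_mm(self) -> np.ndarray:
        return np.arange(self.n_z) * self.delta_z


def channel_index(name: str) -> int:
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}") from None


def write_volume(vol: OCTVolume, path) -> None:
    """Write a volume as per-channel multi-page TIFFs plus a JSON sidecar.

    ``path`` is a directory (created if absent); existing content for the same
    file names is overwritten.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, ch in enumerate(CHANNELS):
        tifffile.imwrite(path / f"{ch}.tif", vol.data[i])
    sidecar = {
        "delta_z_mm": vol.delta_z,
        "pitch_xy_mm": vol.pitch_xy,
        "channels": list(CHANNELS),
        "meta": vol.meta,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_volume(path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`.

    Geometry always comes from the sidecar; a missing sidecar is a hard error,
    never a silent default.
    """
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing geometry sidecar {sidecar_path}; refusing to guess pixel sizes"
        )
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("delta_z_mm", "pitch_xy_mm"):
        if key not in sidecar:
            raise KeyError(f"sidecar {sidecar_path} lacks required key {key!r}")
    planes = [tifffile.imread(path / f"{ch}.tif") for ch in CHANNELS]
    if planes[0].shape != planes[1].shape:
        raise ValueError(
            f"channel shape mismatch: co {planes[0].shape} vs cross {planes[1].shape}"
        )
    data = np.stack(planes, axis=0)
    return OCTVolume(
        data=data,
        delta_z=float(sidecar["delta_z_mm"]),
        pitch_xy=float(sidecar["pitch_xy_mm"]),
        meta=sidecar.get("meta", {}),
    )


ROI_COLUMNS = ("roi_id", "class", "x0", "y0", "width", "height")


@dataclass
class ROISet:
    """Rectangular analysis windows on the lateral (x, y) grid.

    Windows are half-open pixel ranges [x0, x0+width) x [y0, y0+height); class
    labels come from the five-type breast-tissue vocabulary.  Bounds against a
    particular map are checked at use, not at construction.
    """

    table: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table).reset_index(drop=True)
        missing = [c for c in ROI_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ROI table lacks columns {missing}")
        df = df[list(ROI_COLUMNS)]
        bad = sorted(set(df["class"]) - set(CLASS_LABELS))
        if bad:
            raise ValueError(
                f"unknown class label(s) {bad}; allowed labels are {list(CLASS_LABELS)}"
            )
        if df["roi_id"].duplicated().any():
            dupes = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
            raise ValueError(f"duplicate roi_id values: {sorted(set(dupes))}")
        for c in ("x0", "y0", "width", "height"):
            df[c] = df[c].astype(int)
        if (df[["width", "height"]] <= 0).any().any():
            raise ValueError("ROI width and height must be positive")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def counts(self) -> Mapping[str, int]:
        return self.table["class"].value_counts().to_dict()

    def __iter__(self):
        # dict records, because "class" is not a valid namedtuple field name
        return iter(self.table.to_dict("records"))


def write_roi_set(rs: ROISet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rs.table.to_csv(path, index=False)


def read_roi_set(path, provenance: str = "file") -> ROISet:
    df = pd.read_csv(path)
    return ROISet(table=df, provenance=provenance)
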