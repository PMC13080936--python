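"""Movie container, lazy frame access and table/metadata serialization.

The canonical in-memory representation of a movie is a dense 4-axis
``uint16`` array ordered ``(T, C, Y, X)`` — frame, channel, row, column.
Physical calibration (pixel size, frame interval) is never read from TIFF
tags; it is supplied explicitly because tag dialects are unreliable.

Frame and channel indices are 0-based everywhere, including CSV output.
Subpixel positions use ``(y, x)`` floats with the origin at the center of
the top-left pixel, so a spot exactly on pixel ``(i, j)`` has position
``(float(i), float(j))``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MovieStack",
    "MovieReader",
    "RunMetadata",
    "AXIS_ORDERS",
    "SPOTS_COLUMNS",
    "TRACES_COLUMNS",
    "CORRELATION_COLUMNS",
    "COLOC_COLUMNS",
    "load_movie",
    "save_movie",
    "get_frame",
    "export_table",
    "read_table",
    "export_metadata",
    "load_metadata",
]

#: Supported on-disk axis layouts; pages are the leading axes flattened row-major.
AXIS_ORDERS = ("TCYX", "TYXC", "CTYX")

SPOTS_COLUMNS = [
    "frame", "channel", "track_id", "y_px", "x_px", "cell_label", "is_cluster",
    "intensity_total", "intensity_bg_sub", "gauss_amplitude", "gauss_sigma_px",
    "gauss_offset", "snr",
]
TRACES_COLUMNS = ["track_id", "channel", "frame", "time_s", "method", "intensity"]
CORRELATION_COLUMNS = ["lag_s", "G", "sem", "n_pairs"]
COLOC_COLUMNS = ["frame", "id_a", "id_b", "distance_px", "fraction", "method"]

_TABLE_SCHEMAS = {
    "spots": SPOTS_COLUMNS,
    "traces": TRACES_COLUMNS,
    "correlation": CORRELATION_COLUMNS,
    "coloc": COLOC_COLUMNS,
}


@dataclasses.dataclass
class MovieStack:
    """Dense time-lapse movie with physical calibration.

    Parameters
    ----------
    data
        ``(T, C, Y, X)`` array of 16-bit unsigned counts.
    pixel_size_um
        Microns per pixel (> 0).
    frame_interval_s
        Seconds between consecutive frames (> 0); frame ``t`` is acquired
        at ``t * frame_interval_s``.
    channel_names
        One label per channel.
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 1.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"movie data must have 4 axes (T, C, Y, X), got {self.data.ndim}")
        if self.data.dtype != np.uint16:
            if np.issubdtype(self.data.dtype, np.integer) or np.issubdtype(self.data.dtype, np.floating):
                self.data = np.clip(self.data, 0, 65535).astype(np.uint16)
            else:
                raise ValueError(f"unsupported dtype {self.data.dtype}")
        if min(self.data.shape) < 1:
            raise ValueError("all movie axes must have length >= 1")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.channel_names is None:
            self.channel_names = [f"ch{c}" for c in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal the channel axis length")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def times_s(self) -> np.ndarray:
        """Acquisition time of every frame (0-based frames)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def frame(self, t: int, c: int) -> np.ndarray:
        """Single 2D plane (view, not a copy)."""
        return self.data[t, c]


@dataclasses.dataclass
class RunMetadata:
    """Flat record of every parameter and threshold a pipeline run used."""

    parameters: dict = dataclasses.field(default_factory=dict)
    software_version: str = ""
    random_seed: int | None = None
    started: str | None = None
    finished: str | None = None

    def update(self, stage: str, params: dict) -> None:
        """Merge a stage's parameters using ``stage.key`` naming."""
        for key, value in params.items():
            self.parameters[f"{stage}.{key}"] = _jsonable(value)

    def stamp_start(self) -> None:
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def stamp_end(self) -> None:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()


def _jsonable(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, Path):
        return str(value)
    return value


def _permutation_to_canonical(axis_order: str) -> tuple[int, ...]:
    """Axis permutation taking ``axis_order`` to the canonical TCYX layout."""
    if axis_order not in AXIS_ORDERS:
        raise ValueError(f"axis_order must be one of {AXIS_ORDERS}, got {axis_order!r}")
    return tuple(axis_order.index(a) for a in "TCYX")


def save_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as a shaped multi-page TIFF in canonical TCYX page order."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, photometric="minisblack", metadata={"axes": "TCYX"})
    return path


def load_movie(
    path: str | Path,
    axis_order: str = "TCYX",
    n_channels: int | None = None,
    pixel_size_um: float = 1.0,
    frame_interval_s: float = 1.0,
    channel_names: Sequence[str] | None = None,
    rescale_float: bool = False,
) -> MovieStack:
    """Load a multi-page TIFF movie into canonical ``(T, C, Y, X)`` order.

    The file may either carry a 4D shaped series (as written by
    :func:`save_movie`) or be a flat stack of 2D pages, in which case the
    page count together with ``n_channels`` must factor into ``axis_order``.
    Values are converted to ``uint16`` with clipping; floating-point input
    is rejected unless ``rescale_float`` is set, in which case it is scaled
    linearly onto [0, 65535].
    """
    path = Path(path)
    if path.suffix.lower() == ".lif":
        raise ValueError(
            "LIF files are not supported; convert the file to multi-page TIFF first"
        )
    if not path.exists():
        raise FileNotFoundError(str(path))
    perm = _permutation_to_canonical(axis_order)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
    if np.issubdtype(arr.dtype, np.floating):
        if not rescale_float:
            raise ValueError(
                "floating-point TIFF input requires rescale_float=True (values are "
                "linearly rescaled onto the 16-bit range)"
            )
        lo, hi = float(arr.min()), float(arr.max())
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 65535.0
    elif arr.dtype.itemsize > 2:
        arr = np.clip(arr, 0, 65535)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        # Flat page stack: split the leading axis using the declared layout.
        n_pages = arr.shape[0]
        leading = axis_order[:2] if axis_order != "TYXC" else None
        if axis_order == "TYXC":
            raise ValueError(
                "a flat page stack cannot carry the TYXC layout; pages must be 2D planes"
            )
        if n_channels is None:
            raise ValueError("n_channels is required to factor a flat page stack")
        if n_pages % n_channels:
            raise ValueError(
                f"page count {n_pages} does not factor into {n_channels} channels"
            )
        n_frames = n_pages // n_channels
        if leading == "TC":
            arr = arr.reshape(n_frames, n_channels, *arr.shape[1:])
        else:  # CT
            arr = arr.reshape(n_channels, n_frames, *arr.shape[1:])
        arr = arr.transpose(_permutation_to_canonical(axis_order.replace("YX", "") + "YX"))
    elif arr.ndim == 4:
        arr = arr.transpose(perm)
        if n_channels is not None and arr.shape[1] != n_channels:
            raise ValueError(
                f"declared n_channels={n_channels} but file has {arr.shape[1]} channels"
            )
    else:
        raise ValueError(f"cannot interpret a {arr.ndim}-axis TIFF as a movie")
    return MovieStack(
        data=arr.astype(np.uint16, copy=False),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_names=list(channel_names) if channel_names is not None else None,
    )


class MovieReader:
    """On-demand single-plane access to an on-disk movie.

    Only the requested plane is decoded per call; the file stays open until
    :meth:`close` (usable as a context manager). Axis bookkeeping matches
    :func:`load_movie` for flat TCYX/CTYX page stacks and shaped 4D series.
    """

    def __init__(self, path: str | Path, axis_order: str = "TCYX", n_channels: int | None = None):
        self.path = Path(path)
        if axis_order not in AXIS_ORDERS:
            raise ValueError(f"axis_order must be one of {AXIS_ORDERS}")
        self._tif = tifffile.TiffFile(self.path)
        series = self._tif.series[0]
        axes = series.axes
        self._axis_order = axis_order
        if len(series.shape) == 4:
            # Shaped series: trust its own axes string when present.
            order = axes if set(axes) == set("TCYX") else axis_order
            self._shape = tuple(series.shape[order.index(a)] for a in "TCYX")
            self._page_layout = order.replace("Y", "").replace("X", "")
        else:
            n_pages = len(series.pages) if series.pages is not None else series.shape[0]
            if n_channels is None:
                raise ValueError("n_channels is required for flat page stacks")
            if n_pages % n_channels:
                raise ValueError(f"page count {n_pages} does not factor into {n_channels} channels")
            y, x = series.shape[-2:]
            self._shape = (n_pages // n_channels, n_channels, y, x)
            self._page_layout = axis_order[:2]
            if axis_order == "TYXC":
                raise ValueError("flat page stacks cannot carry the TYXC layout")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self._shape

    @property
    def n_frames(self) -> int:
        return self._shape[0]

    @property
    def n_channels(self) -> int:
        return self._shape[1]

    def get_frame(self, t: int, c: int) -> np.ndarray:
        """Read one 2D plane; raises ``IndexError`` out of range."""
        n_t, n_c = self._shape[:2]
        if not (0 <= t < n_t):
            raise IndexError(f"frame index {t} out of range [0, {n_t})")
        if not (0 <= c < n_c):
            raise IndexError(f"channel index {c} out of range [0, {n_c})")
        if self._page_layout == "TC":
            page = t * n_c + c
        else:  # CT
            page = c * n_t + t
        plane = self._tif.series[0].pages[page].asarray()
        return np.clip(plane, 0, 65535).astype(np.uint16, copy=False)

    def iter_planes(self) -> Iterator[tuple[int, int, np.ndarray]]:
        for t in range(self.n_frames):
            for c in range(self.n_channels):
                yield t, c, self.get_frame(t, c)

    def close(self) -> None:
        self._tif.close()

    def __enter__(self) -> "MovieReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def get_frame(path: str | Path, t: int, c: int, axis_order: str = "TCYX",
              n_channels: int | None = None) -> np.ndarray:
    """Convenience one-shot lazy plane read (see :class:`MovieReader`)."""
    with MovieReader(path, axis_order=axis_order, n_channels=n_channels) as reader:
        return reader.get_frame(t, c)


def export_table(records: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Write a stage output table as RFC-4180 CSV with the canonical header.

    Missing values (e.g. intensities at unresolved gap frames) are written
    as empty fields, never as 0. Unknown columns are a schema violation.
    """
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}; one of {sorted(_TABLE_SCHEMAS)}")
    columns = _TABLE_SCHEMAS[schema]
    extra = set(records.columns) - set(columns)
    if extra:
        raise ValueError(f"unknown column(s) {sorted(extra)} for schema {schema!r}")
    out = records.reindex(columns=columns)
    path = Path(path)
    out.to_csv(path, index=False, na_rep="", lineterminator="\r\n")
    return path


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read back a CSV written by :func:`export_table`."""
    if schema not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path)
    missing = set(_TABLE_SCHEMAS[schema]) - set(df.columns)
    if missing:
        raise ValueError(f"file {path} lacks column(s) {sorted(missing)}")
    return df


def export_metadata(meta: RunMetadata, path: str | Path) -> Path:
    """Serialize run metadata as JSON."""
    if not meta.parameters:
        raise ValueError("metadata has no stage parameters; nothing ran")
    path = Path(path)
    payload = {
        "parameters": meta.parameters,
        "software_version": meta.software_version,
        "random_seed": meta.random_seed,
        "started": meta.started,
        "finished": meta.finished,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_metadata(path: str | Path) -> RunMetadata:
    payload = json.loads(Path(path).read_text())
    return RunMetadata(
        parameters=payload["parameters"],
        software_version=payload.get("software_version", ""),
        random_seed=payload.get("random_seed"),
        started=payload.get("started"),
        finished=payload.get("finished"),
    )
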