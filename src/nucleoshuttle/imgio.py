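"""Reading and writing of time-lapse stacks, file-name metadata, and results.

File-name convention
--------------------
One TIFF per imaging position, with well / scene / position encoded in the
name as ``<prefix>_w-<well>_s-<scene>_p-<position>.<ext>`` (e.g.
``exp1_w-B2_s-3_p-5.ome.tif``).  The well is a plate coordinate such as
``B2``; scene and position are 1-based integers.  The condition label is
resolved from a well -> condition table in the run configuration, not from
the file name itself.

Stacks are stored with axes T, C, Y, X (declared in the TIFF metadata); all
pixel coordinates are 0-based, row-major, origin at the top-left.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "PositionMetadata",
    "ImageStack",
    "EmptyInputError",
    "NameParseError",
    "list_position_files",
    "parse_position_name",
    "format_position_name",
    "read_stack",
    "write_stack",
    "write_results",
    "REQUIRED_ROLES",
]

REQUIRED_ROLES = ("nuclear_stain", "nucleolar_marker", "poi")

_NAME_RE = re.compile(
    r"^(?P<prefix>.+)_w-(?P<well>[A-Za-z]+\d+)_s-(?P<scene>\d+)_p-(?P<position>\d+)"
    r"\.(?P<ext>[A-Za-z0-9.]+)$"
)


class EmptyInputError(FileNotFoundError):
    """No input files matched; a silent empty run is forbidden."""


class NameParseError(ValueError):
    """A file name does not follow the position-name convention."""


@dataclass(frozen=True)
class PositionMetadata:
    well: str
    scene: int
    position: int
    condition: str | None = None
    prefix: str = "img"
    ext: str = "ome.tif"

    def __post_init__(self) -> None:
        if self.scene < 1 or self.position < 1:
            raise ValueError("scene and position are 1-based (>= 1)")
        if not re.fullmatch(r"[A-Za-z]+\d+", self.well):
            raise ValueError(f"well {self.well!r} must match letter(s)+digits")


@dataclass
class ImageStack:
    """A T x C x Y x X intensity stack with channel roles and frame timing."""

    pixels: np.ndarray
    channel_roles: dict[str, int]
    frame_interval_min: float
    metadata: PositionMetadata | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be (T, C, Y, X), got {self.pixels.shape}")
        if self.pixels.shape[0] < 1:
            raise ValueError("need at least one time point")
        roles = set(self.channel_roles)
        missing = [r for r in REQUIRED_ROLES if r not in roles]
        if missing:
            raise ValueError(f"channel_roles missing {missing}")
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel_roles must map each role to a distinct channel")
        if max(idx) >= self.pixels.shape[1]:
            raise ValueError(
                f"role index {max(idx)} out of range for {self.pixels.shape[1]} channels"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and (self.pixels < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """(T, Y, X) view of one channel by role."""
        return self.pixels[:, self.channel_roles[role]]

    def frame_times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


def list_position_files(folder: str | Path, pattern: str = "*_w-*_s-*_p-*.*") -> list[Path]:
    """Deterministic lexicographic listing of position files in a folder.

    Non-matching files are ignored with a logged note; an empty result is an
    error so that a misconfigured folder can never produce a silent empty
    analysis run.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"input folder does not exist: {folder}")
    matched = sorted(p for p in folder.glob(pattern) if p.is_file())
    ignored = sorted(p.name for p in folder.iterdir() if p.is_file() and p not in matched)
    if ignored:
        logger.info("ignoring %d non-matching files in %s: %s", len(ignored), folder, ignored)
    if not matched:
        raise EmptyInputError(f"no files matching {pattern!r} in {folder}")
    return matched


def parse_position_name(
    filename: str | Path, conditions: dict[str, str] | None = None
) -> PositionMetadata:
    """Parse well / scene / position from a position file name.

    ``conditions`` is an optional well -> condition table (from the run
    config) used to resolve the condition label.
    """
    name = Path(filename).name
    m = _NAME_RE.match(name)
    if m is None:
        for token, part in (("_w-", "well"), ("_s-", "scene"), ("_p-", "position")):
            if token not in name:
                raise NameParseError(f"{name!r}: missing {part} token {token!r}")
        raise NameParseError(f"{name!r} does not match <prefix>_w-<well>_s-<n>_p-<n>.<ext>")
    well = m["well"]
    condition = conditions.get(well) if conditions else None
    return PositionMetadata(
        well=well,
        scene=int(m["scene"]),
        position=int(m["position"]),
        condition=condition,
        prefix=m["prefix"],
        ext=m["ext"],
    )


def format_position_name(meta: PositionMetadata) -> str:
    """Inverse of :func:`parse_position_name` on the valid-name language."""
    return f"{meta.prefix}_w-{meta.well}_s-{meta.scene}_p-{meta.position}.{meta.ext}"


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (T, C, Y, X), inserting unit axes."""
    axes = axes.upper()
    # squeeze axes tifffile may add (samples, depth of 1, ...)
    for ax in ("S", "Z", "Q", "I"):
        while ax in axes:
            i = axes.index(ax)
            if ax == "I":  # generic sequence axis: treat as time
                axes = axes.replace("I", "T", 1)
                continue
            if data.shape[i] != 1:
                if ax == "Z":
                    raise ValueError("3D (Z > 1) stacks are not supported")
                raise ValueError(f"cannot interpret axis {ax} of size {data.shape[i]}")
            data = np.squeeze(data, axis=i)
            axes = axes[:i] + axes[i + 1:]
    for ax in ("T", "C"):
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "TCYX"]
    if sorted(order) != list(range(4)) or len(axes) != 4:
        raise ValueError(f"cannot normalize axes {axes!r} to TCYX")
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    channel_roles: dict[str, int],
    frame_interval_min: float = 5.0,
    conditions: dict[str, str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF time-lapse stack, normalizing axes to T, C, Y, X.

    Single-time-point files get T=1.  Metadata is parsed from the file name
    when it follows the position-name convention.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
    except (OSError, tifffile.TiffFileError) as e:
        raise OSError(f"cannot read TIFF {path}: {e}") from e
    pixels = _normalize_axes(data, axes)
    n_needed = max(channel_roles.values()) + 1
    if pixels.shape[1] < n_needed:
        raise ValueError(
            f"{path.name}: {pixels.shape[1]} channels but roles require {n_needed}"
        )
    try:
        meta = parse_position_name(path, conditions)
    except NameParseError:
        meta = None
    return ImageStack(
        pixels=pixels,
        channel_roles=dict(channel_roles),
        frame_interval_min=frame_interval_min,
        metadata=meta,
    )


def write_stack(path: str | Path, pixels: np.ndarray) -> Path:
    """Write a (T, C, Y, X) stack as a TIFF with declared axes."""
    path = Path(path)
    if pixels.ndim != 4:
        raise ValueError("expected (T, C, Y, X)")
    data = pixels
    if data.dtype == np.float64:
        data = data.astype(np.float32)  # TIFF-portable float
    tifffile.imwrite(path, data, metadata={"axes": "TCYX"})
    return path


RESULT_COLUMNS = [
    "condition",
    "time_min",
    "iteration",
    "mean_ratio_minus1",
    "sem",
    "n_images",
    "n_cells",
]


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    header_comment: str | None = None,
    also_xlsx: bool = True,
) -> Path:
    """Write a results table as CSV (golden format) plus a spreadsheet.

    The CSV round-trips floats at full precision (``repr`` formatting); the
    ``.xlsx`` twin is written next to it for spreadsheet users.  An optional
    comment line (e.g. a config hash) is prepended with ``#``.
    """
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, index=False)
    if also_xlsx:
        table.to_excel(path.with_suffix(".xlsx"), index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
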