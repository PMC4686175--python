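"""Reading and writing tracking results.

Two dialects are supported:

* the de-facto challenge directory layout — one 16-bit integer label mask per
  frame (``mask000.tif``, ``mask001.tif``, ...; multi-page for 3-D) plus a
  whitespace-separated lineage text file with one line per track,
  ``label t_init t_end parent`` (parent ``0`` meaning none);
* a self-contained JSON fixture dialect listing tracks and explicit marker
  pixel sets, used to make test fixtures independent of any image format.

Both round-trip losslessly and byte-stably, and every read re-validates the
result (mask/track-file cross-consistency is always enforced).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .model import (
    Marker,
    Track,
    TrackingResult,
    validate_tracking_result,
)

__all__ = [
    "DirectoryDialect",
    "FormatError",
    "ConsistencyError",
    "read_tracking_directory",
    "write_tracking_directory",
    "read_fixture_json",
    "write_fixture_json",
    "load_tracking_result",
]


class FormatError(ValueError):
    """A file does not parse under the expected dialect."""


class ConsistencyError(ValueError):
    """Masks and lineage file (or fixture fields) contradict each other."""


@dataclass(frozen=True)
class DirectoryDialect:
    """Naming convention of a tracking directory.

    ``mask_prefix`` + zero-padded frame index (``pad_width`` digits, which
    must accommodate ``n_frames - 1``) + ``.tif``; lineage in
    ``track_file``.
    """

    mask_prefix: str = "mask"
    track_file: str = "res_track.txt"
    pad_width: int = 3

    def mask_name(self, frame: int) -> str:
        return f"{self.mask_prefix}{frame:0{self.pad_width}d}.tif"


#: conventional dialect of ground-truth directories
GT_DIALECT = DirectoryDialect(mask_prefix="man_track", track_file="man_track.txt")
#: conventional dialect of result directories
RES_DIALECT = DirectoryDialect(mask_prefix="mask", track_file="res_track.txt")


def _parse_track_file(path: Path) -> dict[int, Track]:
    tracks: dict[int, Track] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'label begin end parent', got {line!r}")
        try:
            label, begin, end, parent = (int(p) for p in parts)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer field in {line!r}") from exc
        if label in tracks:
            raise FormatError(f"{path}:{lineno}: duplicate track label {label}")
        tracks[label] = Track(
            label=label, t_init=begin, t_end=end, parent=parent if parent != 0 else None
        )
    return tracks


def read_tracking_directory(
    path: Union[str, Path],
    dialect: DirectoryDialect = RES_DIALECT,
    n_frames: Optional[int] = None,
) -> TrackingResult:
    """Load label masks plus lineage file into a validated tracking result.

    Markers are the full support of each non-zero label per frame, connected
    or not.  ``n_frames`` defaults to the number of consecutive mask files
    found starting at frame 0.

    Raises
    ------
    FileNotFoundError
        A mask file inside ``0..n_frames-1`` or the lineage file is missing.
    FormatError
        Non-integer mask data or a malformed lineage line.
    ConsistencyError
        A label's mask support disagrees with its lineage span (marker with
        no track line, or track line with no marker in its span), or the
        result fails structural validation.
    """
    path = Path(path)
    track_path = path / dialect.track_file
    if not track_path.is_file():
        raise FileNotFoundError(f"lineage file not found: {track_path}")
    tracks = _parse_track_file(track_path)

    if n_frames is None:
        n_frames = 0
        while (path / dialect.mask_name(n_frames)).is_file():
            n_frames += 1
        if n_frames == 0:
            raise FileNotFoundError(f"no mask files matching {dialect.mask_name(0)} in {path}")

    markers: dict[tuple[int, int], Marker] = {}
    for frame in range(n_frames):
        mask_path = path / dialect.mask_name(frame)
        if not mask_path.is_file():
            raise FileNotFoundError(f"mask file not found: {mask_path}")
        mask = np.asarray(tifffile.imread(mask_path))
        if not np.issubdtype(mask.dtype, np.integer):
            raise FormatError(f"{mask_path}: expected an integer label mask, got {mask.dtype}")
        for label in np.unique(mask):
            label = int(label)
            if label == 0:
                continue
            coords = np.argwhere(mask == label)
            pixels = frozenset(tuple(int(c) for c in row) for row in coords)
            markers[(label, frame)] = Marker(label=label, frame=frame, pixels=pixels)

    _cross_check(tracks, markers, n_frames, where=str(path))
    result = TrackingResult(n_frames=n_frames, tracks=tracks, markers=markers)
    violations = validate_tracking_result(result)
    if violations:
        raise ConsistencyError(f"{path}: invalid tracking result: {violations[0]}")
    return result


def _cross_check(tracks, markers, n_frames, where: str) -> None:
    offenders = []
    for (label, frame) in markers:
        track = tracks.get(label)
        if track is None:
            offenders.append(f"label {label} present in frame {frame} has no lineage line")
        elif not (track.t_init <= frame <= track.t_end):
            offenders.append(
                f"label {label} present in frame {frame} outside its span "
                f"[{track.t_init}, {track.t_end}]"
            )
    for label, track in tracks.items():
        for t in track.frames:
            if t < n_frames and (label, t) not in markers:
                offenders.append(f"label {label} absent from frame {t} inside its span")
    if offenders:
        raise ConsistencyError(f"{where}: " + "; ".join(offenders))


def write_tracking_directory(
    result: TrackingResult,
    path: Union[str, Path],
    dialect: DirectoryDialect = RES_DIALECT,
    shape: Optional[tuple[int, ...]] = None,
) -> None:
    """Rasterize a tracking result into mask TIFFs plus a lineage file.

    The image ``shape`` defaults to the bounding box of all pixels.  Masks
    are written as 16-bit unsigned integers (labels above 65535 are
    rejected); 3-D markers produce one multi-page TIFF per frame.  Writing is
    deterministic: the same result always produces identical bytes.
    """
    violations = validate_tracking_result(result)
    if violations:
        raise ConsistencyError(f"cannot write invalid tracking result: {violations[0]}")
    if any(label > np.iinfo(np.uint16).max for label in result.tracks):
        raise ValueError("labels above 65535 do not fit the 16-bit mask dtype")

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    ndim = next(iter(result.markers.values())).ndim if result.markers else 2
    if shape is None:
        maxes = [0] * ndim
        for marker in result.markers.values():
            for px in marker.pixels:
                for d, c in enumerate(px):
                    if c < 0:
                        raise ValueError(f"negative coordinate {px} cannot be rasterized")
                    maxes[d] = max(maxes[d], c)
        shape = tuple(m + 1 for m in maxes)

    for frame in range(result.n_frames):
        mask = np.zeros(shape, dtype=np.uint16)
        for marker in result.markers_in_frame(frame):
            for px in marker.pixels:
                if mask[px] != 0:
                    raise ConsistencyError(
                        f"frame {frame}: pixel {px} claimed by markers {int(mask[px])} "
                        f"and {marker.label}; cannot rasterize"
                    )
                mask[px] = marker.label
        tifffile.imwrite(path / dialect.mask_name(frame), mask, photometric="minisblack")

    lines = []
    for label in sorted(result.tracks):
        track = result.tracks[label]
        lines.append(f"{label} {track.t_init} {track.t_end} {track.parent or 0}")
    (path / dialect.track_file).write_text("\n".join(lines) + ("\n" if lines else ""))


def _fixture_to_dict(result: TrackingResult) -> dict:
    return {
        "n_frames": result.n_frames,
        "tracks": [
            {
                "label": t.label,
                "t_init": t.t_init,
                "t_end": t.t_end,
                "parent": t.parent,
            }
            for t in sorted(result.tracks.values(), key=lambda t: t.label)
        ],
        "markers": [
            {
                "label": m.label,
                "frame": m.frame,
                "pixels": sorted(list(p) for p in m.pixels),
            }
            for m in sorted(result.markers.values(), key=lambda m: (m.label, m.frame))
        ],
    }


def write_fixture_json(result: TrackingResult, path: Union[str, Path]) -> None:
    """Serialize to the JSON fixture dialect (sorted, indent 1, byte-stable)."""
    doc = _fixture_to_dict(result)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_fixture_json(path: Union[str, Path]) -> TrackingResult:
    """Parse the JSON fixture dialect into a validated tracking result."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    return fixture_from_dict(doc, where=str(path))


def fixture_from_dict(doc: dict, where: str = "<fixture>") -> TrackingResult:
    """Build a validated tracking result from a fixture-dialect mapping."""
    try:
        n_frames = int(doc["n_frames"])
        tracks = {
            int(t["label"]): Track(
                label=int(t["label"]),
                t_init=int(t["t_init"]),
                t_end=int(t["t_end"]),
                parent=None if t.get("parent") in (None, 0) else int(t["parent"]),
            )
            for t in doc["tracks"]
        }
        markers = {}
        for i, m in enumerate(doc["markers"]):
            pixels = frozenset(tuple(int(c) for c in px) for px in m["pixels"])
            if not pixels:
                raise FormatError(f"{where}: markers[{i}]: empty pixel list")
            markers[(int(m["label"]), int(m["frame"]))] = Marker(
                label=int(m["label"]), frame=int(m["frame"]), pixels=pixels
            )
    except FormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{where}: schema violation: {exc!r}") from exc
    result = TrackingResult(n_frames=n_frames, tracks=tracks, markers=markers)
    violations = validate_tracking_result(result)
    if violations:
        raise ConsistencyError(f"{where}: invalid tracking result: {violations[0]}")
    return result


def load_tracking_result(
    path: Union[str, Path], dialect: DirectoryDialect = RES_DIALECT
) -> TrackingResult:
    """Load either dialect: a ``.json`` fixture file or a mask directory."""
    path = Path(path)
    if path.is_file() and path.suffix == ".json":
        return read_fixture_json(path)
    if path.is_dir():
        return read_tracking_directory(path, dialect)
    raise FileNotFoundError(f"no tracking result at {path}")
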