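"""Readers and writers for every external format the pipeline touches.

TIFF movies go through :mod:`tifffile`; box annotations use Pascal-VOC XML
with a single object class (``cell``); traces go to CSV (or HDF5 for large
runs); configuration round-trips through YAML or JSON.

The VOC convention (1-based, inclusive) is converted to the package's
internal convention (0-based, half-open) here and nowhere else.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import BoundingBox, MovieStack
from .traces import TraceSet

__all__ = [
    "FormatError",
    "read_movie",
    "write_movie",
    "read_voc_boxes",
    "write_voc_boxes",
    "write_traces",
    "read_traces",
    "read_config",
    "write_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# --------------------------------------------------------------------------
# TIFF movies
# --------------------------------------------------------------------------

def read_movie(
    path,
    frame_rate: Optional[float] = None,
    pixel_size: Optional[float] = None,
) -> MovieStack:
    """Read a multi-page grayscale TIFF as a :class:`MovieStack`.

    Frame rate and pixel size are taken from ImageJ-style metadata when
    present; explicit arguments override the file.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            meta = tif.imagej_metadata or {}
    except Exception as exc:  # corrupt or non-TIFF input
        raise FormatError(f"cannot read TIFF movie {path}: {exc}") from exc

    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale (T, H, W) stack, got shape {frames.shape}"
        )

    if frame_rate is None:
        finterval = meta.get("finterval")
        frame_rate = 1.0 / float(finterval) if finterval else 1.0
    if pixel_size is None:
        pixel_size = float(meta.get("spacing", 1.0)) or 1.0

    return MovieStack(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)


def write_movie(stack: MovieStack, path) -> None:
    """Write a movie as a multi-page TIFF; lossless for integer stacks."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.dtype not in (np.uint8, np.uint16, np.int16, np.float32):
        if np.issubdtype(frames.dtype, np.floating):
            frames = frames.astype(np.float32)
        else:
            raise FormatError(f"unsupported bit depth / dtype: {frames.dtype}")
    tifffile.imwrite(
        path,
        frames,
        imagej=True,
        metadata={
            "finterval": 1.0 / stack.frame_rate,
            "spacing": stack.pixel_size,
            "axes": "TYX",
        },
    )


# --------------------------------------------------------------------------
# Pascal-VOC XML boxes
# --------------------------------------------------------------------------

def read_voc_boxes(path) -> List[BoundingBox]:
    """Read bounding boxes from a Pascal-VOC annotation file.

    VOC stores 1-based inclusive corners; they are converted to the internal
    0-based half-open convention (``x_min - 1`` .. ``x_max``).
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"malformed VOC XML {path}: {exc}") from exc

    boxes: List[BoundingBox] = []
    for obj in root.findall("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise FormatError(f"{path}: <object> without <bndbox>")
        vals = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            node = bnd.find(key)
            if node is None or node.text is None:
                raise FormatError(f"{path}: missing <{key}>")
            vals[key] = float(node.text)
        if vals["xmax"] <= vals["xmin"] or vals["ymax"] <= vals["ymin"]:
            raise FormatError(
                f"{path}: degenerate box xmin={vals['xmin']} xmax={vals['xmax']} "
                f"ymin={vals['ymin']} ymax={vals['ymax']}"
            )
        score_node = obj.find("score")
        score = float(score_node.text) if score_node is not None and score_node.text else 1.0
        boxes.append(
            BoundingBox(
                x_min=vals["xmin"] - 1.0,
                y_min=vals["ymin"] - 1.0,
                x_max=vals["xmax"],
                y_max=vals["ymax"],
                score=score,
            )
        )
    return boxes


def write_voc_boxes(
    boxes: Sequence[BoundingBox],
    path,
    image_shape: tuple[int, int],
    filename: Optional[str] = None,
) -> None:
    """Write boxes as a Pascal-VOC annotation (single class, ``cell``).

    Boxes outside the image raise a validation error naming the offenders.
    """
    h, w = image_shape
    offenders = [
        i
        for i, b in enumerate(boxes)
        if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h
    ]
    if offenders:
        raise FormatError(
            f"boxes outside the {h}x{w} image at indices {offenders}"
        )

    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = filename or path.stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "1"
    for box in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = "cell"
        ET.SubElement(obj, "score").text = repr(float(box.score))
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = repr(float(box.x_min + 1.0))
        ET.SubElement(bnd, "ymin").text = repr(float(box.y_min + 1.0))
        ET.SubElement(bnd, "xmax").text = repr(float(box.x_max))
        ET.SubElement(bnd, "ymax").text = repr(float(box.y_max))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


# --------------------------------------------------------------------------
# Traces
# --------------------------------------------------------------------------

def write_traces(traces: TraceSet, path) -> None:
    """Write a trace table: timestamps, bg, one column per identity.

    Frames before an identity's first detection are written as missing
    values (empty CSV cells / NaN in HDF5), never as zeros.  ``.h5``/
    ``.hdf5`` extensions select HDF5, anything else CSV.
    """
    path = Path(path)
    df = traces.to_dataframe()
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["frame_rate"] = traces.frame_rate
            f.create_dataset("bg", data=traces.bg)
            f.create_dataset("time_s", data=traces.times())
            grp = f.create_group("cells")
            for ident in traces.identities:
                grp.create_dataset(str(ident), data=traces.trace(ident))
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_traces(path) -> TraceSet:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            frame_rate = float(f.attrs["frame_rate"])
            bg = np.asarray(f["bg"])
            cells = {int(k): np.asarray(v) for k, v in f["cells"].items()}
        return TraceSet.from_arrays(cells, bg, frame_rate=frame_rate)
    df = pd.read_csv(path)
    return TraceSet.from_dataframe(df)


# --------------------------------------------------------------------------
# Config
# --------------------------------------------------------------------------

def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


def write_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))
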