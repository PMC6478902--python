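"""File formats for frames, slices, transforms, cubes and spectra.

Wide-field frames travel as multi-page TIFF stacks (or per-frame PNG
directories), spectral slices as multi-page TIFF with a JSON sidecar
carrying the wavelength axis and slit geometry, transforms as JSON arrays
of row-major 3x3 matrices, hypercubes in ENVI format (text header + flat
BSQ binary) with an optional multi-page TIFF export, and endmember spectra
as wavelength-first CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .geometry import GeometricTransform
from .preprocess import WidefieldFrame
from .reconstruction import Hypercube, SpectralSlice
from .registration import RegistrationChain

# ---------------------------------------------------------------------------
# wide-field frames


def save_frames(path, frames) -> None:
    """Write a frame sequence as a multi-page float32 TIFF."""
    tifffile.imwrite(
        str(path), np.stack([f.data for f in frames]).astype(np.float32)
    )


def load_frames(path) -> list:
    """Read frames from a multi-page TIFF or a directory of TIFF/PNG files."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        if not files:
            raise FileNotFoundError(f"no frame images found in {path}")
        return [
            WidefieldFrame(np.asarray(iio.imread(f), dtype=float), index=i)
            for i, f in enumerate(files)
        ]
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return [WidefieldFrame(img.astype(float), index=i) for i, img in enumerate(stack)]


# ---------------------------------------------------------------------------
# spectral slices


def save_slices(path, slices) -> None:
    """Write slices as multi-page TIFF plus a JSON sidecar (wavelengths, slit)."""
    path = Path(path)
    tifffile.imwrite(str(path), np.stack([s.data for s in slices]).astype(np.float32))
    meta = {
        "wavelengths": list(map(float, slices[0].wavelengths)),
        "slit_width_px": float(slices[0].slit_width_px),
        "slit_center_x": float(slices[0].slit_center_x),
        "frame_height": int(slices[0].frame_height),
        "frame_indices": [int(s.frame_index) for s in slices],
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_slices(path) -> list:
    path = Path(path)
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    wl = np.asarray(meta["wavelengths"], dtype=float)
    idx = meta.get("frame_indices", list(range(len(stack))))
    return [
        SpectralSlice(
            data=img.astype(float),
            wavelengths=wl,
            frame_index=int(i),
            slit_width_px=meta["slit_width_px"],
            slit_center_x=meta["slit_center_x"],
            frame_height=meta["frame_height"],
        )
        for img, i in zip(stack, idx)
    ]


# ---------------------------------------------------------------------------
# transforms / registration chains


def save_chain(path, chain: RegistrationChain) -> None:
    """Serialise a registration chain as JSON (row-major 3x3 + status per frame)."""
    doc = {
        "reference_index": chain.reference_index,
        "frames": [
            {
                "matrix": None if t is None else [list(map(float, row)) for row in t.matrix],
                "status": s,
                "inliers": int(c),
            }
            for t, s, c in zip(chain.transforms, chain.status, chain.inlier_counts)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_chain(path) -> RegistrationChain:
    doc = json.loads(Path(path).read_text())
    transforms = [
        None if f["matrix"] is None else GeometricTransform(np.array(f["matrix"]))
        for f in doc["frames"]
    ]
    return RegistrationChain(
        transforms,
        [f["status"] for f in doc["frames"]],
        [f["inliers"] for f in doc["frames"]],
        doc.get("reference_index", 0),
    )


def save_transforms(path, transforms) -> None:
    """Write a plain list of 3x3 matrices (e.g. simulation ground truth) as JSON."""
    Path(path).write_text(
        json.dumps([[list(map(float, row)) for row in t.matrix] for t in transforms])
    )


def load_transforms(path) -> list:
    return [
        GeometricTransform(np.array(m)) for m in json.loads(Path(path).read_text())
    ]


# ---------------------------------------------------------------------------
# ENVI hypercubes (text header + raw BSQ binary)

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 1: np.uint8, 2: np.int16, 12: np.uint16}


def save_envi(path, cube: Hypercube) -> None:
    """Write a hypercube as an ENVI header (.hdr) + flat BSQ binary.

    Band-sequential interleave, float32, byte order 0; the wavelength list
    and the canvas offset travel in the header.  NaN (uncovered) values are
    stored as NaN.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    h, w, nb = cube.data.shape
    hdr = [
        "ENVI",
        "description = {endocube reconstructed hypercube}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {nb}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Unknown",
        "wavelength = {" + ", ".join(f"{v:g}" for v in cube.wavelengths) + "}",
        f"y start = {cube.offset[0]:g}",
        f"x start = {cube.offset[1]:g}",
    ]
    path.with_suffix(".hdr").write_text("\n".join(hdr) + "\n")
    np.ascontiguousarray(
        np.moveaxis(cube.data.astype(np.float32), 2, 0)
    ).tofile(path.with_suffix(".img"))
    np.save(str(path.with_suffix(".coverage.npy")), cube.coverage)


def _parse_envi_header(text: str) -> dict:
    fields = {}
    key, buf = None, ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            if val.startswith("{") and not val.endswith("}"):
                buf = val
                continue
            fields[key] = val.strip("{} ")
            key = None
        else:
            buf += " " + line
            if line.endswith("}"):
                fields[key] = buf.strip("{} ")
                key = None
                buf = ""
    return fields

def load_envi(path) -> Hypercube:
    path = Path(path)
    if path.suffix in (".img", ".hdr"):
        path = path.with_suffix("")
    fields = _parse_envi_header(path.with_suffix(".hdr").read_text())
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    w = int(fields["samples"])
    h = int(fields["lines"])
    nb = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields.get("data type", 4))]
    raw = np.fromfile(path.with_suffix(".img"), dtype=dtype)
    data = np.moveaxis(raw.reshape(nb, h, w), 0, 2).astype(np.float32)
    if "wavelength" in fields:
        wl = np.array([float(v) for v in fields["wavelength"].split(",")])
    else:
        wl = np.arange(nb, dtype=float)
    offset = (float(fields.get("y start", 0)), float(fields.get("x start", 0)))
    cov_file = path.with_suffix(".coverage.npy")
    if cov_file.exists():
        cov = np.load(str(cov_file))
    else:
        cov = np.isfinite(data).all(axis=-1).astype(np.int32)
    return Hypercube(data, wl, cov, offset)


def save_cube_tiff(path, cube: Hypercube) -> None:
    """Export a hypercube as a multi-page TIFF, one page per wavelength."""
    tifffile.imwrite(str(path), np.moveaxis(cube.data.astype(np.float32), 2, 0))
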