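"""Micrograph readers and STAR coordinate read/write.

MRC support covers single-image MRC2014 maps (modes 0, 1, 2 and 6); image
stacks are rejected. STAR files use the RELION dialect: one ``data_`` block,
``loop_`` over ``_rlnCoordinateX``/``_rlnCoordinateY`` and, when scores are
present, ``_rlnAutopickFigureOfMerit``. Coordinates are written in the
package's frame (0-based pixel centers, x = column, y = row, origin
top-left) and a comment line in each file states this.
"""

from __future__ import annotations

import logging
import os
import struct
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from .datamodel import Micrograph, Particle, ParticleSet

logger = logging.getLogger("cryofsl")

__all__ = ["read_micrograph", "write_mrc", "read_mrc", "write_star", "read_star"]

PathLike = Union[str, os.PathLike]

_MRC_HEADER_BYTES = 1024
_MRC_MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    6: np.dtype(np.uint16),
}


def _sanitize(pixels: np.ndarray, path: PathLike) -> np.ndarray:
    """Replace non-finite pixels by the finite median (warn), cast to float64."""
    pixels = np.asarray(pixels, dtype=np.float64)
    bad = ~np.isfinite(pixels)
    if bad.any():
        finite = pixels[~bad]
        fill = float(np.median(finite)) if finite.size else 0.0
        logger.warning(
            "replaced %d non-finite pixel(s) with median %.6g in %s",
            int(bad.sum()), fill, path,
        )
        pixels = pixels.copy()
        pixels[bad] = fill
    return pixels


# --------------------------------------------------------------------------
# MRC2014
# --------------------------------------------------------------------------

def write_mrc(path: PathLike, pixels: np.ndarray, pixel_size: Optional[float] = None) -> None:
    """Write a 2D float32 MRC2014 map (mode 2, little-endian)."""
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim != 2:
        raise ValueError("write_mrc expects a 2D array")
    ny, nx = pixels.shape
    apix = float(pixel_size) if pixel_size else 0.0
    header = np.zeros(256, dtype="<i4")
    fheader = header.view("<f4")
    header[0:3] = (nx, ny, 1)          # nx, ny, nz
    header[3] = 2                      # mode 2 = float32
    header[7:10] = (nx, ny, 1)         # mx, my, mz
    fheader[10:13] = (nx * apix, ny * apix, apix)  # cella (0 when apix unknown)
    fheader[13:16] = (90.0, 90.0, 90.0)
    header[16:19] = (1, 2, 3)          # mapc, mapr, maps
    fheader[19] = float(pixels.min()) if pixels.size else 0.0
    fheader[20] = float(pixels.max()) if pixels.size else 0.0
    fheader[21] = float(pixels.mean()) if pixels.size else 0.0
    header[22] = 1                     # ispg: 2D image convention uses 0/1; 1 = volume-style
    header[52] = struct.unpack("<i", b"MAP ")[0]
    header[53] = struct.unpack("<i", bytes((0x44, 0x44, 0, 0)))[0]  # LE machine stamp
    fheader[54] = float(pixels.std()) if pixels.size else 0.0
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(pixels).tobytes())


def read_mrc(path: PathLike) -> Tuple[np.ndarray, Optional[float]]:
    """Read a single-image MRC map; returns (pixels[y, x], pixel_size or None)."""
    with open(path, "rb") as fh:
        raw = fh.read(_MRC_HEADER_BYTES)
        if len(raw) < _MRC_HEADER_BYTES:
            raise IOError(f"{path}: truncated MRC header")
        order = "<"
        nx, ny, nz, mode = struct.unpack(order + "4i", raw[:16])
        if not (0 < nx < 10**6 and 0 < ny < 10**6):  # try big-endian
            order = ">"
            nx, ny, nz, mode = struct.unpack(order + "4i", raw[:16])
            if not (0 < nx < 10**6 and 0 < ny < 10**6):
                raise IOError(f"{path}: not a readable MRC file")
        if nz != 1:
            raise IOError(f"{path}: MRC stacks/volumes (nz={nz}) are unsupported; "
                          "this reader handles single 2D images only")
        if mode not in _MRC_MODE_DTYPES:
            raise IOError(f"{path}: unsupported MRC mode {mode}")
        (nsymbt,) = struct.unpack(order + "i", raw[92:96])
        mx = struct.unpack(order + "i", raw[28:32])[0]
        xlen = struct.unpack(order + "f", raw[40:44])[0]
        pixel_size = None
        if mx > 0 and xlen > 0:
            pixel_size = float(xlen) / float(mx)
        if nsymbt > 0:
            fh.seek(_MRC_HEADER_BYTES + nsymbt)
        dtype = _MRC_MODE_DTYPES[mode].newbyteorder(order)
        data = np.frombuffer(fh.read(nx * ny * dtype.itemsize), dtype=dtype)
        if data.size != nx * ny:
            raise IOError(f"{path}: truncated MRC data section")
        return data.reshape(ny, nx).astype(np.float64), pixel_size


# --------------------------------------------------------------------------
# generic reader
# --------------------------------------------------------------------------

def read_micrograph(path: PathLike) -> Micrograph:
    """Read an MRC (modes 0/1/2/6) or grayscale TIFF/PNG micrograph.

    Integer images are returned with their raw integer values as floats (no
    rescaling); multi-channel images are averaged to one channel; non-finite
    pixels are replaced by the image median with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"micrograph file not found: {path}")
    suffix = path.suffix.lower()
    pixel_size: Optional[float] = None
    if suffix in (".mrc", ".map", ".mrcs"):
        pixels, pixel_size = read_mrc(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        pixels = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    else:
        from PIL import Image

        with Image.open(path) as img:
            pixels = np.asarray(img, dtype=np.float64)
    if pixels.ndim == 3:
        pixels = pixels.mean(axis=-1)
    if pixels.ndim != 2:
        raise IOError(f"{path}: expected a 2D image, got shape {pixels.shape}")
    pixels = _sanitize(pixels, path)
    return Micrograph(pixels=pixels, pixel_size=pixel_size, source_path=str(path))


# --------------------------------------------------------------------------
# STAR
# --------------------------------------------------------------------------

_CONVENTION_COMMENT = (
    "# coordinates: 0-based pixel centers, x = column, y = row, origin top-left"
)


def write_star(particles: ParticleSet, path: PathLike) -> None:
    """Write particle coordinates as a RELION-dialect STAR file."""
    has_scores = any(p.score is not None for p in particles.particles)
    lines: List[str] = [_CONVENTION_COMMENT, "", "data_particles", "", "loop_",
                        "_rlnCoordinateX #1", "_rlnCoordinateY #2"]
    if has_scores:
        lines.append("_rlnAutopickFigureOfMerit #3")
    for p in particles.particles:
        row = f"{p.x:.6f} {p.y:.6f}"
        if has_scores:
            row += f" {p.score if p.score is not None else 0.0:.6f}"
        lines.append(row)
    lines.append("")
    try:
        Path(path).write_text("\n".join(lines))
    except OSError as exc:
        raise IOError(f"cannot write STAR file {path}: {exc}") from exc


def read_star(
    path: PathLike,
    reference_shape: Optional[Tuple[int, int]] = None,
    provenance: str = "predicted",
    default_diameter: float = 1.0,
) -> ParticleSet:
    """Read particle coordinates from a STAR file.

    Unknown columns are ignored. When ``reference_shape`` is omitted it is
    taken just large enough to contain all coordinates.
    """
    text = Path(path).read_text()
    labels: List[str] = []
    rows: List[List[str]] = []
    in_loop = False
    for rawline in text.splitlines():
        line = rawline.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            in_loop = False
            continue
        if line == "loop_":
            in_loop = True
            labels = []
            continue
        if in_loop and line.startswith("_"):
            labels.append(line.split()[0])
            continue
        if in_loop and labels:
            parts = line.split()
            if len(parts) >= len(labels):
                rows.append(parts)
    required = ("_rlnCoordinateX", "_rlnCoordinateY")
    if not all(r in labels for r in required):
        raise ValueError(
            f"{path}: STAR file lacks coordinate columns; available columns: {labels}"
        )
    ix, iy = labels.index("_rlnCoordinateX"), labels.index("_rlnCoordinateY")
    iscore = labels.index("_rlnAutopickFigureOfMerit") if "_rlnAutopickFigureOfMerit" in labels else None
    coords = [(float(r[ix]), float(r[iy]),
               float(r[iscore]) if iscore is not None else None) for r in rows]
    if reference_shape is None:
        h = int(np.ceil(max((y for _, y, _ in coords), default=0.0))) + 1
        w = int(np.ceil(max((x for x, _, _ in coords), default=0.0))) + 1
        reference_shape = (max(h, 1), max(w, 1))
    particles = [
        Particle(x=x, y=y, diameter=default_diameter,
                 score=min(max(s, 0.0), 1.0) if s is not None else None)
        for x, y, s in coords
    ]
    return ParticleSet(particles=particles, reference_shape=reference_shape,
                       provenance=provenance)  # type: ignore[arg-type]
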