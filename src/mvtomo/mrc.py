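"""Minimal MRC2014 volume reader/writer.

Only the subset of the format needed for tomogram/subtomogram work is
supported: modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16), with the
standard 1024-byte header and no extended header on write (an extended
header on read is skipped via ``nsymbt``).

Axis convention: the in-memory array has shape ``(H, W, D)`` with axis 0
(H) stored as the MRC section axis (``nz``), axis 1 (W) as rows (``ny``)
and axis 2 (D) as columns (``nx``).  Coordinates are 0-based voxel indices
throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MrcFormatError", "read_mrc", "write_mrc", "MODE_DTYPES"]

MODE_DTYPES = {
    0: np.dtype("int8"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}

_HEADER_SIZE = 1024


class MrcFormatError(ValueError):
    """Raised when a file does not parse as a supported MRC2014 volume."""


def _header_ints(buf: bytes) -> np.ndarray:
    return np.frombuffer(buf, dtype="<i4", count=256)


def read_mrc(path) -> tuple[np.ndarray, float | None]:
    """Read an MRC file.

    Returns ``(data, voxel_size)`` where ``data`` has shape (H, W, D) and
    ``voxel_size`` is the (isotropic) spacing in Angstrom per voxel, or
    ``None`` when the header does not define a cell.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MrcFormatError(f"{path}: truncated header ({len(header)} bytes)")
        ints = _header_ints(header)
        floats = np.frombuffer(header, dtype="<f4", count=256)
        nx, ny, nz, mode = int(ints[0]), int(ints[1]), int(ints[2]), int(ints[3])
        if min(nx, ny, nz) < 1:
            raise MrcFormatError(
                f"{path}: non-positive dimension field nx/ny/nz = {(nx, ny, nz)}"
            )
        if mode not in MODE_DTYPES:
            raise MrcFormatError(f"{path}: unsupported mode field {mode}")
        nsymbt = int(ints[23])
        if nsymbt < 0:
            raise MrcFormatError(f"{path}: negative nsymbt field {nsymbt}")
        fh.seek(_HEADER_SIZE + nsymbt)
        dtype = MODE_DTYPES[mode]
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) != count * dtype.itemsize:
            raise MrcFormatError(
                f"{path}: data block truncated (expected {count} voxels of {dtype})"
            )
    data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    # cella / m gives the spacing; mx..mz mirror nx..nz for plain volumes
    mx = int(ints[7])
    xlen = float(floats[10])
    voxel_size = None
    if mx > 0 and xlen > 0:
        voxel_size = xlen / mx
    return data, voxel_size


def write_mrc(path, data: np.ndarray, voxel_size: float | None = None, mode: int = 2) -> None:
    """Write ``data`` of shape (H, W, D) as an MRC2014 file."""
    if mode not in MODE_DTYPES:
        raise MrcFormatError(f"unsupported mode {mode}")
    data = np.asarray(data)
    if data.ndim != 3:
        raise MrcFormatError(f"expected a 3D array, got shape {data.shape}")
    out = np.ascontiguousarray(data, dtype=MODE_DTYPES[mode])
    h, w, d = data.shape

    ints = np.zeros(256, dtype="<i4")
    floats = np.zeros(256, dtype="<f4")
    ints[0], ints[1], ints[2] = d, w, h          # nx, ny, nz
    ints[3] = mode
    ints[7], ints[8], ints[9] = d, w, h          # mx, my, mz
    vs = 1.0 if voxel_size is None else float(voxel_size)
    floats[10], floats[11], floats[12] = vs * d, vs * w, vs * h   # cella
    floats[13] = floats[14] = floats[15] = 90.0                   # cellb
    ints[16], ints[17], ints[18] = 1, 2, 3       # mapc, mapr, maps
    floats[19] = float(out.min())
    floats[20] = float(out.max())
    floats[21] = float(np.asarray(out, dtype=np.float64).mean())
    ints[22] = 1 if h * w * d > 1 else 0         # ispg: volume
    header = bytearray(ints.tobytes())
    fbytes = floats.tobytes()
    for idx in (10, 11, 12, 13, 14, 15, 19, 20, 21):
        header[idx * 4 : idx * 4 + 4] = fbytes[idx * 4 : idx * 4 + 4]
    header[52 * 4 : 52 * 4 + 4] = b"MAP "
    header[53 * 4 : 53 * 4 + 4] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    rms = np.asarray(out, dtype=np.float64).std()
    header[54 * 4 : 54 * 4 + 4] = np.float32(rms).tobytes()

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(out.tobytes())
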