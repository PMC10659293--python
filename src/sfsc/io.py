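"""Volume and signal I/O: MRC/CCP4 via gemmi, delimited text for 1-D."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fourier import RealGrid

_TEXT_SUFFIXES = {".txt", ".dat", ".csv", ".tsv"}


class VolumeReadError(ValueError):
    pass


def read_volume(path: str | Path, voxel_size: float | None = None) -> RealGrid:
    """Read an MRC/CCP4 volume (modes 0/1/2) or a single-column text file.

    The voxel size comes from the MRC header cell dimensions; a zero header
    voxel size is rejected unless an explicit ``voxel_size`` override is
    given.  Trailing singleton axes (2-D images stored as N x N x 1) are
    squeezed.
    """
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        values = np.loadtxt(path)
        if values.ndim != 1:
            raise VolumeReadError(f"expected a single-column text signal in {path}")
        return RealGrid(values, voxel_size if voxel_size else 1.0)
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise VolumeReadError(f"cannot read {path} as an MRC/CCP4 map: {exc}") from exc
    values = np.array(m.grid.array, dtype=np.float64)
    header_voxel = m.grid.unit_cell.a / m.grid.nu if m.grid.nu else 0.0
    if voxel_size is None:
        if not header_voxel > 0:
            raise VolumeReadError(
                f"{path} has a zero voxel size in its header; pass an explicit voxel size"
            )
        voxel_size = header_voxel
    while values.ndim > 1 and values.shape[-1] == 1:
        values = values[..., 0]
    return RealGrid(values, float(voxel_size))


def write_volume(g: RealGrid, path: str | Path) -> None:
    """Write a grid as an MRC/CCP4 map (float32, mode 2)."""
    import gemmi

    values = g.values
    while values.ndim < 3:
        values = values[..., np.newaxis]
    grid = gemmi.FloatGrid(np.ascontiguousarray(values, dtype=np.float32))
    grid.unit_cell = gemmi.UnitCell(
        *(n * g.voxel_size for n in values.shape), 90.0, 90.0, 90.0
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_signal(g: RealGrid, path: str | Path) -> None:
    """Write a 1-D grid as a single-column text file."""
    if g.ndim != 1:
        raise ValueError("write_signal handles 1-D grids only")
    np.savetxt(path, g.values)
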