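"""Reading and writing volumes and vector fields (NIfTI / MetaImage).

SimpleITK handles the on-disk formats; arrays keep this package's
(LR, AP, IS) axis order, which maps to SimpleITK's (x, y, z) physical
axes with the array transposed (SimpleITK stores z-major).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import SimpleITK as sitk

from .grids import DeformationField, VoxelGrid

PathLike = Union[str, Path]


def write_volume(grid: VoxelGrid, path: PathLike) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: PathLike) -> VoxelGrid:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    return VoxelGrid(values, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_field(dvf: DeformationField, path: PathLike) -> None:
    arr = np.ascontiguousarray(np.transpose(dvf.displacement, (2, 1, 0, 3)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(dvf.spacing))
    img.SetOrigin(tuple(dvf.origin))
    sitk.WriteImage(img, str(path))


def read_field(path: PathLike, phase: int = 0) -> DeformationField:
    img = sitk.ReadImage(str(path))
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0, 3))
    return DeformationField(
        arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()), phase=phase
    )
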