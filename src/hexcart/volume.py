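"""Label volumes: integer tissue-code grids with world geometry.

Index ``(i, j, k)`` maps to world millimetres as ``origin + index * spacing``
(0-based, cell-centred samples). NIfTI is read/written with nibabel;
NRRD and MetaImage with SimpleITK.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Default tissue-code scheme. The source segmentations ship no published
#: code table, so this documented mapping is used throughout: bones first,
#: then cartilage tissues with the tibial plateau split medio-laterally.
DEFAULT_TISSUE_CODES = {
    "femur": 1,
    "tibia": 2,
    "patella": 3,
    "femoral_cartilage": 4,
    "tibial_cartilage_medial": 5,
    "tibial_cartilage_lateral": 6,
    "patellar_cartilage": 7,
}

BONE_TISSUES = ("femur", "tibia", "patella")


def tissue_class(name: str) -> str:
    """``"bone"`` or ``"cartilage"`` for a tissue name."""
    return "bone" if name in BONE_TISSUES or name == "bone" else "cartilage"


@dataclass
class LabelVolume:
    """3-D integer tissue-code grid with voxel spacing and origin (mm)."""

    codes: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    tissue_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.codes.ndim != 3:
            raise ValueError("codes must be a 3-D array")
        if np.any(self.codes < 0):
            raise ValueError("tissue codes must be non-negative")

    # -- lookups ----------------------------------------------------------
    def code_for(self, tissue: str) -> int:
        for code, name in self.tissue_map.items():
            if name == tissue:
                return int(code)
        raise KeyError(f"tissue {tissue!r} not present in tissue_map")

    def mask(self, code_or_tissue) -> np.ndarray:
        code = (
            self.code_for(code_or_tissue)
            if isinstance(code_or_tissue, str)
            else int(code_or_tissue)
        )
        return self.codes == code

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def with_codes(self, codes: np.ndarray) -> "LabelVolume":
        return LabelVolume(codes, self.spacing.copy(), self.origin.copy(), dict(self.tissue_map))

    # -- file IO ----------------------------------------------------------
    # Image formats carry no tissue names, so save() writes a small JSON
    # sidecar (<file>.tissues.json) with the code -> name map; load()
    # restores it when present and falls back to the default code table.
    def save(self, path) -> None:
        path = Path(path)
        if self.tissue_map:
            import json

            Path(str(path) + ".tissues.json").write_text(
                json.dumps({str(k): v for k, v in self.tissue_map.items()})
            )
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            affine = np.diag(np.append(self.spacing, 1.0))
            affine[:3, 3] = self.origin
            nib.save(nib.Nifti1Image(self.codes.astype(np.int16), affine), str(path))
        elif name.endswith((".nrrd", ".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(
                np.ascontiguousarray(self.codes.astype(np.int16).transpose(2, 1, 0))
            )
            img.SetSpacing(tuple(self.spacing))
            img.SetOrigin(tuple(self.origin))
            sitk.WriteImage(img, str(path))
        else:
            raise ValueError(f"unsupported label volume format: {path.name}")

    @classmethod
    def load(cls, path, tissue_map: dict[int, str] | None = None) -> "LabelVolume":
        path = Path(path)
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            affine = img.affine
            codes = np.asarray(img.dataobj).astype(np.int32)
            spacing = np.abs(np.diag(affine)[:3])
            origin = affine[:3, 3]
        elif name.endswith((".nrrd", ".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            codes = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.int32)
            spacing = np.asarray(img.GetSpacing())
            origin = np.asarray(img.GetOrigin())
        else:
            raise ValueError(f"unsupported label volume format: {path.name}")
        if tissue_map is None:
            sidecar = Path(str(path) + ".tissues.json")
            if sidecar.exists():
                import json

                tissue_map = {
                    int(k): v for k, v in json.loads(sidecar.read_text()).items()
                }
            else:
                present = set(np.unique(codes)) - {0}
                tissue_map = {
                    code: name
                    for name, code in DEFAULT_TISSUE_CODES.items()
                    if code in present
                }
        return cls(codes, spacing, origin, tissue_map)
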