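"""Volumetric containers and NIfTI / tabular I/O.

All cross-volume operations in this package require the inputs to live on an
identical voxel grid (same shape, voxel size, and affine): there is no implicit
resampling.  Each volume carries a ``space_id`` token derived from its affine
(rounded to 0.1 um) so that alignment can be checked cheaply and robustly
against header rounding noise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "Volume4D",
    "LabelAtlas",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "load_atlas",
    "write_lut",
    "check_aligned",
    "load_manifest",
    "write_manifest",
    "write_table",
]

#: Affines are rounded to this many decimals (mm) before hashing, so headers
#: that differ only by float rounding map to the same space token.
_AFFINE_DECIMALS = 4


def space_id_from_affine(affine: np.ndarray) -> str:
    """Opaque alignment token: hash of the affine rounded to 1e-4 mm."""
    rounded = np.round(np.asarray(affine, dtype=np.float64), _AFFINE_DECIMALS)
    rounded += 0.0  # fold -0.0 into +0.0 so the byte hash is sign-stable
    return hashlib.sha1(rounded.tobytes()).hexdigest()[:16]


def _default_affine(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _validate_finite(data: np.ndarray, path=None) -> None:
    bad = np.count_nonzero(~np.isfinite(data))
    if bad:
        where = f" in {path}" if path is not None else ""
        raise ValueError(f"{bad} non-finite voxel value(s){where}")


@dataclass
class Volume3D:
    """A 3D scalar grid with geometry metadata (e.g. a CBF or occupancy map)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    space_id: str = field(default="")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        _validate_finite(self.data)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not self.space_id:
            self.space_id = space_id_from_affine(self.affine)

    @classmethod
    def from_array(cls, data, voxel_size_mm=(2.0, 2.0, 2.0)) -> "Volume3D":
        return cls(np.asarray(data), tuple(voxel_size_mm), _default_affine(voxel_size_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same geometry, new payload."""
        return Volume3D(data, self.voxel_size_mm, self.affine, self.space_id)


@dataclass
class Volume4D:
    """A 4D (X, Y, Z, T) time-series grid, e.g. a BOLD run.

    ``tr_seconds`` is the repetition time: the sampling interval of each
    voxel's time series, which fixes the frequency grid of its spectrum.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_seconds: float
    affine: np.ndarray
    space_id: str = field(default="")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("a 4D volume needs at least 2 time points")
        if not (self.tr_seconds and self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")
        _validate_finite(self.data)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not self.space_id:
            self.space_id = space_id_from_affine(self.affine)

    @classmethod
    def from_array(cls, data, tr_seconds, voxel_size_mm=(2.0, 2.0, 2.0)) -> "Volume4D":
        return cls(np.asarray(data), tuple(voxel_size_mm), float(tr_seconds),
                   _default_affine(voxel_size_mm))

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation with a bilateral lookup table.

    ``lut`` maps each nonzero label to ``(region_name, hemisphere)`` with
    hemisphere in {"L", "R"}.  Every region name must appear in both
    hemispheres (bilateral pairs, as in the Desikan-Killiany cortical atlas
    with 34 named regions per hemisphere).
    """

    labels: np.ndarray
    lut: Mapping[int, tuple[str, str]]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    space_id: str = field(default="")

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("atlas labels must be integer-valued")
            self.labels = as_int
        self.lut = {int(k): (str(v[0]), str(v[1])) for k, v in dict(self.lut).items()}
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if not self.space_id:
            self.space_id = space_id_from_affine(self.affine)
        self._validate()

    def _validate(self):
        present = {int(v) for v in np.unique(self.labels)} - {0}
        missing = sorted(present - set(self.lut))
        if missing:
            raise ValueError(f"grid labels absent from LUT: {missing}")
        hemis_by_region: dict[str, set[str]] = {}
        for _, (name, hemi) in self.lut.items():
            if hemi not in ("L", "R"):
                raise ValueError(f"hemisphere must be 'L' or 'R', got {hemi!r}")
            hemis_by_region.setdefault(name, set()).add(hemi)
        lonely = sorted(n for n, h in hemis_by_region.items() if h != {"L", "R"})
        if lonely:
            raise ValueError(f"regions present in only one hemisphere: {lonely}")

    @property
    def region_names(self) -> list[str]:
        """Sorted bilateral region names (one entry per L/R pair)."""
        return sorted({name for name, _ in self.lut.values()})

    def labels_for(self, region_name: str, hemisphere: str | None = None) -> list[int]:
        return [lab for lab, (name, hemi) in self.lut.items()
                if name == region_name and (hemisphere is None or hemi == hemisphere)]


class AlignmentError(ValueError):
    """Raised when volumes that must share a grid do not."""


def check_aligned(*volumes) -> None:
    """Verify that all inputs share grid shape, voxel size, and space token.

    Accepts any mix of :class:`Volume3D`, :class:`Volume4D` and
    :class:`LabelAtlas`; only the spatial (X, Y, Z) grid is compared.
    Raises :class:`AlignmentError` naming the first field that differs.
    """
    if len(volumes) < 2:
        raise ValueError("need at least two volumes to compare")

    def spatial(v):
        grid = v.labels if isinstance(v, LabelAtlas) else v.data
        return grid.shape[:3], v.voxel_size_mm, v.space_id

    ref_shape, ref_vox, ref_space = spatial(volumes[0])
    for i, vol in enumerate(volumes[1:], start=1):
        shape, vox, space = spatial(vol)
        if shape != ref_shape:
            raise AlignmentError(
                f"volume {i}: grid shape {shape} != {ref_shape}")
        if not np.allclose(vox, ref_vox, atol=1e-4):
            raise AlignmentError(
                f"volume {i}: voxel_size_mm {vox} != {ref_vox}")
        if space != ref_space:
            raise AlignmentError(
                f"volume {i}: space_id {space} != {ref_space} (affines differ)")


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> Volume3D | Volume4D:
    """Read a NIfTI file into a :class:`Volume3D` or :class:`Volume4D`.

    Geometry (voxel size, affine) comes from the header; for 4D images the
    repetition time is taken from the 4th pixdim and must be positive.
    Non-finite voxel values are an error (the count is reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    _validate_finite(data, path)
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    if data.ndim == 3:
        return Volume3D(data, voxel_size, img.affine)
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"4D image {path} has no positive TR in its header")
        return Volume4D(data, voxel_size, tr, img.affine)
    raise ValueError(f"unsupported image dimensionality {data.ndim} in {path}")


def write_volume(vol: Volume3D | Volume4D, path) -> Path:
    """Write a volume as NIfTI-1; float payloads are stored as float32."""
    path = Path(path)
    data = vol.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    zooms = list(vol.voxel_size_mm)
    if isinstance(vol, Volume4D):
        zooms.append(vol.tr_seconds)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_atlas(label_path, lut_path) -> LabelAtlas:
    """Load a labelled parcellation volume plus its lookup table.

    The LUT is a TSV with header columns ``label``, ``region_name``,
    ``hemisphere``.  Validation requires every nonzero grid label to appear in
    the LUT and every region name to form a bilateral (L, R) pair.
    """
    vol = read_volume(label_path)
    if isinstance(vol, Volume4D):
        raise ValueError("atlas labels must be a 3D image")
    lut_df = pd.read_csv(lut_path, sep="\t", dtype={"label": int})
    required = {"label", "region_name", "hemisphere"}
    if not required.issubset(lut_df.columns):
        raise ValueError(f"LUT must have columns {sorted(required)}")
    lut = {int(r.label): (r.region_name, r.hemisphere) for r in lut_df.itertuples()}
    labels = np.round(vol.data).astype(np.int64)
    if not np.allclose(vol.data, labels):
        raise ValueError("atlas grid is not integer-valued")
    return LabelAtlas(labels, lut, vol.voxel_size_mm, vol.affine, vol.space_id)


def write_lut(lut: Mapping[int, tuple[str, str]], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [(lab, name, hemi) for lab, (name, hemi) in sorted(lut.items())],
        columns=["label", "region_name", "hemisphere"],
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Manifests and result tables

_MANIFEST_REQUIRED = ["subject_id", "age", "sex", "group"]


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load a subject manifest TSV.

    Columns: subject_id, age (years), sex (M/F), group (case/control), plus
    any number of ``*_path`` columns pointing at per-subject image files.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be M or F, got {sorted(bad_sex)}")
    if check_files:
        for col in df.columns:
            if col.endswith("_path"):
                for p in df[col]:
                    if pd.notna(p) and not Path(p).exists():
                        raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def write_manifest(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_table(df: pd.DataFrame, path, float_digits: int = 6) -> Path:
    """Write a result table as TSV with floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")
    return path


def write_sidecar(path, payload: dict) -> Path:
    """JSON provenance sidecar next to an artifact (seeds, hashes, settings)."""
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return sidecar
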