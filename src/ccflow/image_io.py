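"""Reading and writing en-face OCTA images, masks and cohort manifests.

En-face choriocapillaris images arrive as single-channel 8- or 16-bit
TIFF or PNG exports. Intensities are normalized by the bit-depth maximum
(255 or 65535) into [0, 1] — never by the per-image maximum, so that the
absolute-intensity terms of the local threshold remain comparable across
eyes. The physical lateral scale (µm per pixel) is required metadata and
is never inferred from image headers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "EnFaceImage",
    "SlabSpec",
    "ManifestRow",
    "CohortManifest",
    "read_enface",
    "load_manifest",
    "write_mask",
    "read_mask",
    "write_enface",
    "GROUPS",
    "MNV_STATUSES",
    "MODALITIES",
    "LATERALITIES",
]

GROUPS = ("angioid_streaks", "control")
MNV_STATUSES = ("mnv", "no_mnv", "not_applicable")
MODALITIES = ("flow", "structure", "compensated")
LATERALITIES = ("OD", "OS")

MANIFEST_COLUMNS = (
    "eye_id",
    "group",
    "mnv_status",
    "flow_path",
    "structure_path",
    "pixel_pitch_um",
)


@dataclass
class EnFaceImage:
    """A 2-D grayscale en-face grid with physical pixel pitch.

    Parameters
    ----------
    pixels : ndarray
        Float intensities in [0, 1], shape (rows, cols). Row 0 is superior.
    pixel_pitch_um : float
        Lateral scale in µm per pixel, strictly positive.
    modality : str
        One of ``flow``, ``structure`` or ``compensated``.
    eye_id : str
        Opaque identifier; empty for anonymous images.
    """

    pixels: np.ndarray
    pixel_pitch_um: float
    modality: str = "flow"
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"pixels must be 2-D single-channel, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty grid")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1], found range [{lo:g}, {hi:g}]"
            )
        if not self.pixel_pitch_um > 0:
            raise ValueError(
                f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um!r}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray, modality: str | None = None) -> "EnFaceImage":
        """Copy metadata onto a new pixel grid."""
        return EnFaceImage(
            pixels=pixels,
            pixel_pitch_um=self.pixel_pitch_um,
            modality=self.modality if modality is None else modality,
            eye_id=self.eye_id,
        )


@dataclass(frozen=True)
class SlabSpec:
    """Depth slab the en-face projection was taken over (metadata only).

    Defaults follow the common choriocapillaris convention: a 15 µm slab
    starting 16 µm below the RPE / Bruch's membrane band.
    """

    offset_below_rpe_um: float = 16.0
    thickness_um: float = 15.0

    def __post_init__(self) -> None:
        if not (self.offset_below_rpe_um > 0 and self.thickness_um > 0):
            raise ValueError("slab offset and thickness must be strictly positive")


@dataclass(frozen=True)
class ManifestRow:
    eye_id: str
    group: str
    mnv_status: str
    flow_path: str
    structure_path: str
    pixel_pitch_um: float


@dataclass
class CohortManifest:
    """Row-ordered cohort listing; image paths are checked lazily at run time."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def eye_ids(self) -> list[str]:
        return [r.eye_id for r in self.rows]

    def subset(self, **where: str) -> "CohortManifest":
        """Filter rows by exact field values, e.g. subset(group='control')."""
        rows = [
            r
            for r in self.rows
            if all(getattr(r, k) == v for k, v in where.items())
        ]
        return CohortManifest(rows=rows)


def read_enface(
    path: str | Path,
    pixel_pitch_um: float,
    modality: str = "flow",
    eye_id: str = "",
) -> EnFaceImage:
    """Read an 8/16-bit single-channel TIFF or PNG as an EnFaceImage.

    Intensities are rescaled linearly by the bit-depth maximum (255 for
    uint8, 65535 for uint16) so the full code range maps onto [0, 1].
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise ValueError(f"unreadable image file {path}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[2] == 1:
        raw = raw[:, :, 0]
    if raw.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {raw.shape}"
        )
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(
            f"{path}: expected 8- or 16-bit integer pixels, got dtype {raw.dtype}"
        )
    if not pixel_pitch_um > 0:
        raise ValueError(f"pixel_pitch_um must be > 0, got {pixel_pitch_um!r}")
    return EnFaceImage(
        pixels=raw.astype(np.float64) / scale,
        pixel_pitch_um=float(pixel_pitch_um),
        modality=modality,
        eye_id=eye_id,
    )


def write_enface(img: EnFaceImage, path: str | Path, bit_depth: int = 16) -> None:
    """Write an image as uint8/uint16 TIFF or PNG by rounding to the code range."""
    if bit_depth == 8:
        arr = np.rint(img.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.rint(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    _write_array(arr, Path(path))


def _write_array(arr: np.ndarray, path: Path) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask(mask, path: str | Path) -> None:
    """Write a binary deficit mask losslessly: deficit -> 255, background -> 0."""
    pixels = np.asarray(mask.pixels, dtype=bool)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"mask must be a nonempty 2-D grid, got shape {pixels.shape}")
    _write_array(np.where(pixels, 255, 0).astype(np.uint8), Path(path))


def read_mask(path: str | Path, pixel_pitch_um: float):
    """Read a mask written by :func:`write_mask` back to a BinaryDeficitMask."""
    from .binarization import BinaryDeficitMask

    raw = iio.imread(Path(path))
    if raw.ndim != 2:
        raise ValueError(f"{path}: mask files must be single-channel")
    return BinaryDeficitMask(pixels=raw > 127, pixel_pitch_um=pixel_pitch_um)


def load_manifest(path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    The header must name exactly the six fields
    ``eye_id,group,mnv_status,flow_path,structure_path,pixel_pitch_um``.
    Group and MNV labels come from closed vocabularies; eye_id must be
    unique. Errors name the offending row (1-based, excluding header).
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: manifest is missing column(s) {missing}")
        rows: list[ManifestRow] = []
        seen: dict[str, int] = {}
        for i, rec in enumerate(reader, start=1):
            eye_id = (rec["eye_id"] or "").strip()
            if not eye_id:
                raise ValueError(f"{path} row {i}: empty eye_id")
            if eye_id in seen:
                raise ValueError(
                    f"{path} row {i}: duplicate eye_id {eye_id!r} "
                    f"(first seen at row {seen[eye_id]})"
                )
            seen[eye_id] = i
            group = rec["group"].strip()
            if group not in GROUPS:
                raise ValueError(
                    f"{path} row {i}: unknown group {group!r}; must be one of {GROUPS}"
                )
            mnv = rec["mnv_status"].strip()
            if mnv not in MNV_STATUSES:
                raise ValueError(
                    f"{path} row {i}: unknown mnv_status {mnv!r}; "
                    f"must be one of {MNV_STATUSES}"
                )
            try:
                pitch = float(rec["pixel_pitch_um"])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path} row {i}: pixel_pitch_um is not a number: "
                    f"{rec['pixel_pitch_um']!r}"
                ) from exc
            if not pitch > 0:
                raise ValueError(f"{path} row {i}: pixel_pitch_um must be > 0")
            rows.append(
                ManifestRow(
                    eye_id=eye_id,
                    group=group,
                    mnv_status=mnv,
                    flow_path=rec["flow_path"].strip(),
                    structure_path=rec["structure_path"].strip(),
                    pixel_pitch_um=pitch,
                )
            )
    return CohortManifest(rows=rows)


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest back to CSV (inverse of :func:`load_manifest`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in manifest.rows:
            writer.writerow(
                [
                    r.eye_id,
                    r.group,
                    r.mnv_status,
                    r.flow_path,
                    r.structure_path,
                    repr(r.pixel_pitch_um),
                ]
            )
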