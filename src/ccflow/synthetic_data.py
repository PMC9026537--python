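"""Synthetic en-face choriocapillaris image pairs with known ground truth.

No public choriocapillaris OCTA dataset accompanies this package, so
every pipeline stage is validated against generated images whose
flow-deficit structure is known exactly.

Texture model: a seeded white-noise field is smoothed with a Gaussian
of physical scale ``correlation_length_um`` (default 24 µm, the
intercapillary-distance scale of the choriocapillaris), and all pixels
below the empirical ``void_fraction``-quantile are marked as flow
voids. Quantile thresholding pins the realized void fraction to the
target up to grid quantization. The flow image renders the bright
capillary mesh at mean 0.75 and the voids at mean 0.15, then adds
Gaussian speckle and clips to [0, 1].

Shadowing: a multiplicative attenuation field A in (1 - depth, 1] —
one minus a depth-scaled maximum of randomly placed Gaussian dark
blobs — darkens the flow image; the structure image is A times a
bright base plus fine texture, so the same shadow appears in both
channels exactly as the compensation stage assumes.

Cohorts: per-eye seeds derive deterministically from (master seed, eye
index), so whole cohorts are reproducible and any single eye can be
regenerated in isolation. Disease eyes draw their void fraction from a
truncated normal with higher mean than controls and use a longer
texture correlation length, emulating both the higher deficit fraction
and the larger, more confluent deficits of diseased choriocapillaris.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .compensation import BOUNDARY_MODE
from .image_io import CohortManifest, EnFaceImage, ManifestRow, save_manifest, write_enface

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "generate_flow_truth",
    "apply_attenuation",
    "generate_eye",
    "generate_cohort",
    "CONTROL_PARAMS",
    "DISEASE_PARAMS",
]

#: mesh / void rendering levels of the flow image
MESH_LEVEL = 0.75
VOID_LEVEL = 0.15
#: structure-image bright base and texture amplitude
STRUCTURE_BASE = 0.8
STRUCTURE_TEXTURE_SD = 0.05


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings for one eye (or one group's template).

    void_fraction is the target deficit area fraction; in cohort
    generation it is the mean of a truncated normal with SD
    ``void_fraction_sd``. Attenuation blobs have Gaussian profiles with
    sigma drawn uniformly from ``blob_sigma_um`` and a shared maximum
    ``attenuation_depth`` (0 disables shadowing).
    """

    side_px: int = 512
    pixel_pitch_um: float = 6.6
    void_fraction: float = 0.4
    void_fraction_sd: float = 0.0
    correlation_length_um: float = 24.0
    n_attenuation_blobs: int = 4
    blob_sigma_um: tuple[float, float] = (80.0, 250.0)
    attenuation_depth: float = 0.5
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.void_fraction < 1.0:
            raise ValueError(f"void_fraction must be in (0, 1), got {self.void_fraction!r}")
        if self.side_px < 64:
            raise ValueError(f"side_px must be >= 64, got {self.side_px!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.attenuation_depth < 1.0:
            raise ValueError("attenuation_depth must lie in [0, 1)")
        if self.correlation_length_um <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("correlation_length_um and pixel_pitch_um must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one generated image pair."""

    void_mask: np.ndarray  # bool, True = no flow
    true_void_fraction: float
    attenuation_field: np.ndarray | None = None  # multiplicative, in (1-depth, 1]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible substreams per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_flow_truth(params: SyntheticParams) -> tuple[EnFaceImage, SyntheticTruth]:
    """Generate a shadow-free flow image and its ground-truth void mask.

    Deterministic given ``params.seed``; the realized void fraction
    matches the target to within grid quantization (2/side_px).
    """
    n = params.side_px
    sigma_px = params.correlation_length_um / params.pixel_pitch_um
    field = ndimage.gaussian_filter(
        _rng(params.seed, 0).standard_normal((n, n)), sigma=sigma_px, mode=BOUNDARY_MODE
    )
    cut = np.quantile(field, params.void_fraction)
    void = field <= cut
    flow = np.where(void, VOID_LEVEL, MESH_LEVEL)
    if params.noise_sd > 0:
        flow = flow + _rng(params.seed, 1).normal(0.0, params.noise_sd, (n, n))
    img = EnFaceImage(
        pixels=np.clip(flow, 0.0, 1.0),
        pixel_pitch_um=params.pixel_pitch_um,
        modality="flow",
    )
    return img, SyntheticTruth(void_mask=void, true_void_fraction=float(void.mean()))


def _attenuation_field(params: SyntheticParams) -> np.ndarray:
    """A = 1 - depth * max_i blob_i, blobs Gaussian with random centers."""
    n = params.side_px
    if params.attenuation_depth == 0.0 or params.n_attenuation_blobs == 0:
        return np.ones((n, n))
    rng = _rng(params.seed, 2)
    yy, xx = np.mgrid[0:n, 0:n]
    lo, hi = params.blob_sigma_um
    bump = np.zeros((n, n))
    for _ in range(params.n_attenuation_blobs):
        cy, cx = rng.uniform(0, n, size=2)
        sigma = rng.uniform(lo, hi) / params.pixel_pitch_um
        amp = rng.uniform(0.7, 1.0)
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        np.maximum(bump, amp * np.exp(-r2 / (2.0 * sigma * sigma)), out=bump)
    return 1.0 - params.attenuation_depth * bump


def apply_attenuation(
    flow: EnFaceImage, truth: SyntheticTruth, params: SyntheticParams
) -> tuple[EnFaceImage, EnFaceImage]:
    """Shadow the flow image and synthesize the matching structure image.

    Returns ``(attenuated_flow, structure)``; the attenuation field is
    recorded on ``truth`` bit-exactly as applied. With depth 0 the flow
    image is returned unchanged and the structure carries no shadow.
    """
    a = _attenuation_field(params)
    truth.attenuation_field = a
    n = params.side_px
    texture = ndimage.gaussian_filter(
        _rng(params.seed, 3).standard_normal((n, n)), sigma=1.5, mode=BOUNDARY_MODE
    )
    structure = a * (STRUCTURE_BASE + STRUCTURE_TEXTURE_SD * texture)
    att_flow = flow.with_pixels(np.clip(a * flow.pixels, 0.0, 1.0))
    structure_img = EnFaceImage(
        pixels=np.clip(structure, 0.0, 1.0),
        pixel_pitch_um=params.pixel_pitch_um,
        modality="structure",
        eye_id=flow.eye_id,
    )
    return att_flow, structure_img


def generate_eye(params: SyntheticParams) -> tuple[EnFaceImage, EnFaceImage, SyntheticTruth]:
    """Full single-eye generation: (attenuated flow, structure, truth)."""
    flow, truth = generate_flow_truth(params)
    att_flow, structure = apply_attenuation(flow, truth, params)
    return att_flow, structure, truth


#: study-condition templates for cohort generation
CONTROL_PARAMS = SyntheticParams(void_fraction=0.39, void_fraction_sd=0.06, correlation_length_um=24.0)
DISEASE_PARAMS = SyntheticParams(void_fraction=0.48, void_fraction_sd=0.08, correlation_length_um=32.0)


def _eye_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo=0.02, hi=0.98) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    raise RuntimeError("truncated normal draw failed; check mean/sd")


def generate_cohort(
    control: SyntheticParams,
    disease: SyntheticParams,
    n_per_group: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[CohortManifest, Path]:
    """Write a full two-group cohort to disk and return its manifest.

    Creates ``2 * n_per_group`` flow/structure TIFF pairs (16-bit),
    ``manifest.csv`` and a ``truth.csv`` sidecar recording each eye's
    drawn void fraction, realized void fraction and per-eye seed.
    Disease eyes are labeled ``angioid_streaks``; the first
    ``ceil(3/4·n)`` of them carry MNV, matching the typical prevalence
    in such cohorts (21 of 27).
    """
    if n_per_group < 2:
        raise ValueError(f"n_per_group must be >= 2, got {n_per_group}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    draw_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    rows: list[ManifestRow] = []
    truth_rows = []
    n_mnv = int(np.ceil(0.75 * n_per_group))
    for idx in range(2 * n_per_group):
        is_disease = idx >= n_per_group
        template = disease if is_disease else control
        vf = _truncnorm(draw_rng, template.void_fraction, template.void_fraction_sd)
        eye_seed = _eye_seed(seed, idx)
        params = replace(template, void_fraction=vf, void_fraction_sd=0.0, seed=eye_seed)
        flow, structure, truth = generate_eye(params)
        group = "angioid_streaks" if is_disease else "control"
        eye_id = f"{'AS' if is_disease else 'CT'}{(idx % n_per_group) + 1:03d}"
        flow_path = out_dir / f"{eye_id}_flow.tif"
        structure_path = out_dir / f"{eye_id}_structure.tif"
        write_enface(flow, flow_path)
        write_enface(structure, structure_path)
        if is_disease:
            mnv = "mnv" if (idx - n_per_group) < n_mnv else "no_mnv"
        else:
            mnv = "not_applicable"
        rows.append(
            ManifestRow(
                eye_id=eye_id,
                group=group,
                mnv_status=mnv,
                flow_path=str(flow_path),
                structure_path=str(structure_path),
                pixel_pitch_um=params.pixel_pitch_um,
            )
        )
        truth_rows.append(
            {
                "eye_id": eye_id,
                "group": group,
                "drawn_void_fraction": vf,
                "true_void_fraction": truth.true_void_fraction,
                "seed": eye_seed,
            }
        )
    manifest = CohortManifest(rows=rows)
    manifest_path = out_dir / "manifest.csv"
    save_manifest(manifest, manifest_path)
    with open(out_dir / "truth.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(truth_rows[0]))
        writer.writeheader()
        writer.writerows(truth_rows)
    return manifest, manifest_path
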