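"""Synthetic confocal scene generator with exact ground truth.

No public image data exist for the perfusion experiment this package
analyses, so every downstream stage (projection, segmentation, texture,
statistics) is exercised on simulated three-channel z-stacks whose
ground truth — cell placement, nucleus/cytoplasm masks, phenotype and
true nuclear marker intensity — is known exactly.

Two actin phenotypes are modelled, following the two cytoskeletal
states described for mesenchymal stem cells before and during
osteogenic commitment:

* ``homogeneous_filaments`` — a large number of thin, aligned
  filaments distributed across the whole cytoplasm;
* ``peripheral_stress_fibres`` — a few thick, bright actin bundles
  confined to an annulus at the outermost cell periphery, with a
  dimmer diffuse interior.

Both phenotypes are rendered at a matched whole-cell mean intensity so
that downstream texture differences reflect spatial organisation, not
brightness.  The noise model is scaled Poisson shot noise plus additive
Gaussian read noise plus a constant background, the standard first-order
description of confocal photon statistics.

All randomness flows from a single ``numpy`` Generator seeded from the
scene spec; identical (spec, seed) pairs produce bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .stacks import ImageStack

__all__ = [
    "PhenotypeSpec",
    "NoiseSpec",
    "SceneSpec",
    "GroundTruth",
    "PlacementError",
    "render_phenotype",
    "generate_scene",
    "NOISELESS",
]

HOMOGENEOUS = "homogeneous_filaments"
PERIPHERAL = "peripheral_stress_fibres"
_KINDS = (HOMOGENEOUS, PERIPHERAL)


class PlacementError(RuntimeError):
    """Could not place the requested number of cells under the constraints."""


@dataclass(frozen=True)
class PhenotypeSpec:
    """Parameters of one actin-organisation phenotype.

    The quantitative values (filament counts, thicknesses, relative
    intensities) are modelling choices made for visual and statistical
    plausibility; only the qualitative contrast between the two kinds —
    many thin distributed filaments versus few thick peripheral
    bundles — is taken from the biology.
    """

    kind: str = HOMOGENEOUS
    filament_count: int = 40
    filament_thickness: float = 1.0
    filament_intensity: float = 4.0
    orientation_dispersion: float = 15.0
    peripheral_band_fraction: float = 0.25
    interior_level: float = 1.0
    interior_filament_count: int = 0
    interior_filament_intensity: float = 2.0
    blur_sigma: float = 0.7

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phenotype kind {self.kind!r}; expected one of {_KINDS}")
        if self.filament_count < 1:
            raise ValueError("filament_count must be >= 1")
        if self.filament_thickness < 1:
            raise ValueError("filament_thickness must be >= 1 px")
        if not 0 < self.peripheral_band_fraction <= 1:
            raise ValueError("peripheral_band_fraction must be in (0, 1]")

    @staticmethod
    def homogeneous(**overrides) -> "PhenotypeSpec":
        """Many thin aligned filaments across the whole cytoplasm."""
        return replace(
            PhenotypeSpec(
                kind=HOMOGENEOUS,
                filament_count=150,
                filament_thickness=1.0,
                filament_intensity=2.0,
                orientation_dispersion=15.0,
                interior_level=1.0,
                blur_sigma=1.6,
            ),
            **overrides,
        )

    @staticmethod
    def peripheral(**overrides) -> "PhenotypeSpec":
        """A few thick bright stress fibres at the outermost periphery."""
        return replace(
            PhenotypeSpec(
                kind=PERIPHERAL,
                filament_count=4,
                filament_thickness=4.0,
                filament_intensity=6.0,
                orientation_dispersion=15.0,
                peripheral_band_fraction=0.25,
                interior_level=0.5,
                interior_filament_count=20,
                interior_filament_intensity=3.0,
                blur_sigma=1.0,
            ),
            **overrides,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Scaled-Poisson shot noise + Gaussian read noise + flat background."""

    poisson_scale: float = 1.0
    gaussian_sd: float = 8.0
    background_level: float = 100.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be >= 0")


#: Convenience spec that disables every noise source.
NOISELESS = NoiseSpec(poisson_scale=0.0, gaussian_sd=0.0, background_level=0.0)


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic field of view.

    Acquisition defaults (1024 x 1024 pixels, 20 z-planes at 5 um
    spacing) mirror the confocal protocol the analysis was designed
    for; tests use smaller fields for speed by overriding them.
    """

    image_size: Tuple[int, int] = (1024, 1024)
    n_planes: int = 20
    pixel_size_um: float = 1.14
    z_spacing_um: float = 5.0
    n_cells: int = 25
    cell_radius_range: Tuple[float, float] = (26.0, 38.0)
    nucleus_radius_range: Tuple[float, float] = (7.0, 11.0)
    runx2_mean: float = 1000.0
    runx2_sd: float = 150.0
    dapi_intensity: float = 800.0
    actin_mean: float = 250.0
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec.homogeneous)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    min_cell_separation: float = 90.0
    allow_border_cells: bool = False
    allow_overlaps: bool = False
    bit_depth: int = 16
    z_profile_sd: float = 1.5
    max_placement_attempts: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("cell_radius_range", "nucleus_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got {(lo, hi)}")


@dataclass
class GroundTruth:
    """Exact per-cell truth for one generated scene.

    ``nucleus_labels`` / ``cell_labels`` are full-size integer label
    maps (0 = background; label k in both maps is the same cell);
    ``cells`` has one row per cell with centroid, phenotype kind, the
    true (integer) nuclear Runx-2 level and mask areas.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cells: pd.DataFrame
    spec: SceneSpec
    seed: int


# ---------------------------------------------------------------------------
# phenotype rendering


def _disk_mask(shape: Tuple[int, int], center: Tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _thicken(canvas: np.ndarray, thickness: float) -> np.ndarray:
    r = int(round((thickness - 1) / 2))
    if r <= 0:
        return canvas
    # grey dilation with a disk footprint spreads each filament to width
    footprint = _disk_mask((2 * r + 1, 2 * r + 1), (r, r), r + 0.5)
    return ndi.grey_dilation(canvas, footprint=footprint)


def _clipped_line(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, value: float) -> None:
    h, w = canvas.shape
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc = skdraw.line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    canvas[rr[keep], cc[keep]] = np.maximum(canvas[rr[keep], cc[keep]], value)


def render_phenotype(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    radius: float,
    phenotype: PhenotypeSpec,
    rng: np.random.Generator,
    target_mean: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one cell's noiseless actin layer.

    Returns ``(layer, cell_mask)`` where ``layer`` is a float image that
    is zero outside ``cell_mask``.  When ``target_mean`` is given the
    layer is rescaled so its mean over the cell mask equals it exactly,
    enforcing the matched-brightness contract between phenotypes.
    """
    mask = _disk_mask(shape, center, radius)
    canvas = np.zeros(shape, dtype=np.float64)

    if phenotype.kind == HOMOGENEOUS:
        base_angle = rng.uniform(0.0, 180.0)
        for _ in range(phenotype.filament_count):
            # anchor point uniform over the disc, orientation near base_angle
            rho = radius * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2 * math.pi)
            anchor = np.array([center[0] + rho * math.sin(phi), center[1] + rho * math.cos(phi)])
            theta = math.radians(base_angle + rng.normal(0.0, phenotype.orientation_dispersion))
            direction = np.array([math.sin(theta), math.cos(theta)])
            # chord through the anchor, clipped to the disc by half-length
            offset = anchor - np.asarray(center)
            perp = offset - direction * float(offset @ direction)
            half = math.sqrt(max(radius**2 - float(perp @ perp), 1.0))
            _clipped_line(canvas, anchor - direction * half, anchor + direction * half,
                          phenotype.filament_intensity)
    else:
        inner = radius * (1.0 - phenotype.peripheral_band_fraction)
        for _ in range(phenotype.filament_count):
            arc_radius = rng.uniform(inner, max(inner + 1.0, radius - 1.5))
            start = rng.uniform(0.0, 2 * math.pi)
            extent = rng.uniform(math.pi / 3, math.pi * 0.8)
            thetas = np.linspace(start, start + extent, max(8, int(arc_radius * extent) + 1))
            rr = np.round(center[0] + arc_radius * np.sin(thetas)).astype(int)
            cc = np.round(center[1] + arc_radius * np.cos(thetas)).astype(int)
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            canvas[rr[keep], cc[keep]] = phenotype.filament_intensity
        canvas = _thicken(canvas, phenotype.filament_thickness)
        # sparse dim filament remnants left in the interior after the
        # cytoskeleton condenses into the peripheral bundles
        for _ in range(phenotype.interior_filament_count):
            rho = inner * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2 * math.pi)
            anchor = np.array([center[0] + rho * math.sin(phi), center[1] + rho * math.cos(phi)])
            theta = rng.uniform(0.0, math.pi)
            direction = np.array([math.sin(theta), math.cos(theta)])
            offset = anchor - np.asarray(center)
            perp = offset - direction * float(offset @ direction)
            half = math.sqrt(max(inner**2 - float(perp @ perp), 1.0))
            _clipped_line(canvas, anchor - direction * half, anchor + direction * half,
                          phenotype.interior_filament_intensity)

    if phenotype.filament_thickness > 1 and phenotype.kind == HOMOGENEOUS:
        canvas = _thicken(canvas, phenotype.filament_thickness)

    layer = np.where(mask, np.maximum(canvas, phenotype.interior_level), 0.0)
    if phenotype.blur_sigma > 0:
        layer = ndi.gaussian_filter(layer, phenotype.blur_sigma)
        layer = np.where(mask, layer, 0.0)

    if target_mean is not None:
        current = layer[mask].mean()
        if current > 0:
            layer *= target_mean / current
    return layer, mask


# ---------------------------------------------------------------------------
# scene assembly


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> List[Tuple[float, float, float]]:
    h, w = spec.image_size
    placed: List[Tuple[float, float, float]] = []
    for i in range(spec.n_cells):
        for _ in range(spec.max_placement_attempts):
            radius = rng.uniform(*spec.cell_radius_range)
            if spec.allow_border_cells:
                row = rng.uniform(0, h - 1)
                col = rng.uniform(0, w - 1)
            else:
                pad = radius + 3
                if h - pad <= pad or w - pad <= pad:
                    raise PlacementError(
                        f"image {spec.image_size} too small for interior cells of radius {radius:.0f}"
                    )
                row = rng.uniform(pad, h - 1 - pad)
                col = rng.uniform(pad, w - 1 - pad)
            ok = True
            for (r2, c2, rad2) in placed:
                dist = math.hypot(row - r2, col - c2)
                min_dist = spec.min_cell_separation
                if not spec.allow_overlaps:
                    min_dist = max(min_dist, radius + rad2 + 3)
                if dist < min_dist:
                    ok = False
                    break
            if ok:
                placed.append((row, col, radius))
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{spec.n_cells} after "
                f"{spec.max_placement_attempts} attempts (min_cell_separation="
                f"{spec.min_cell_separation}, allow_overlaps={spec.allow_overlaps})"
            )
    return placed


def _nucleus_mask(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    radii: Tuple[float, float],
    rotation: float,
) -> np.ndarray:
    rr, cc = skdraw.ellipse(
        center[0], center[1], radii[0], radii[1], shape=shape, rotation=rotation
    )
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def generate_scene(spec: SceneSpec) -> Tuple[ImageStack, GroundTruth]:
    """Generate one three-channel z-stack plus its exact ground truth.

    Deterministic: the same spec (including its ``seed``) always yields
    bit-identical arrays.  Raises :class:`PlacementError` when the
    requested cells cannot be placed under the separation constraints.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size)
    placed = _place_cells(spec, rng)

    ideal = {name: np.zeros(shape, dtype=np.float64) for name in ("dapi", "phalloidin", "runx2")}
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    z_centers: List[float] = []
    records = []

    for label, (row, col, radius) in enumerate(placed, start=1):
        actin, cell_mask = render_phenotype(
            shape, (row, col), radius, spec.phenotype, rng, target_mean=spec.actin_mean
        )
        nuc_a = rng.uniform(*spec.nucleus_radius_range)
        nuc_b = rng.uniform(*spec.nucleus_radius_range)
        rotation = rng.uniform(-math.pi / 2, math.pi / 2)
        nuc_mask = _nucleus_mask(shape, (row, col), (nuc_a, nuc_b), rotation) & cell_mask
        runx2_true = max(0.0, round(rng.normal(spec.runx2_mean, spec.runx2_sd)))
        z_center = rng.uniform(0.3, 0.7) * max(spec.n_planes - 1, 1)
        z_centers.append(z_center)

        ideal["phalloidin"] = np.maximum(ideal["phalloidin"], actin)
        ideal["dapi"][nuc_mask] = spec.dapi_intensity
        ideal["runx2"][nuc_mask] = runx2_true
        nucleus_labels[nuc_mask] = label
        cell_labels[cell_mask] = label
        records.append(
            {
                "label": label,
                "row": row,
                "col": col,
                "cell_radius": radius,
                "phenotype": spec.phenotype.kind,
                "runx2_true": runx2_true,
                "z_center": z_center,
                "nucleus_area": int(nuc_mask.sum()),
                "cell_area": int(cell_mask.sum()),
            }
        )

    stack = _rasterize(spec, ideal, z_centers, cell_labels, rng)
    cells = pd.DataFrame(
        records,
        columns=[
            "label", "row", "col", "cell_radius", "phenotype",
            "runx2_true", "z_center", "nucleus_area", "cell_area",
        ],
    )
    truth = GroundTruth(
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        cells=cells,
        spec=spec,
        seed=spec.seed,
    )
    return stack, truth


def _rasterize(
    spec: SceneSpec,
    ideal: Dict[str, np.ndarray],
    z_centers: List[float],
    cell_labels: np.ndarray,
    rng: np.random.Generator,
) -> ImageStack:
    """Spread the ideal 2-D signal over z with per-cell Gaussian axial
    profiles (peak weight exactly 1, so a max projection recovers the
    ideal image), then apply the noise model plane by plane."""
    shape = tuple(spec.image_size)
    n_planes = spec.n_planes
    max_value = float(2**spec.bit_depth - 1)

    # per-pixel axial weight per plane, from the owning cell's z profile
    weights = np.ones((n_planes, *shape), dtype=np.float64) if z_centers else np.ones(
        (n_planes, *shape), dtype=np.float64
    )
    if z_centers:
        planes = np.arange(n_planes, dtype=np.float64)
        per_cell = np.empty((len(z_centers) + 1, n_planes))
        per_cell[0] = 1.0  # background label 0: flat profile
        for idx, zc in enumerate(z_centers, start=1):
            prof = np.exp(-((planes - zc) ** 2) / (2.0 * spec.z_profile_sd**2))
            per_cell[idx] = prof / prof.max()
        weights = per_cell[cell_labels.ravel(), :].T.reshape(n_planes, *shape)

    noise = spec.noise
    out: Dict[str, np.ndarray] = {}
    for name in ("dapi", "phalloidin", "runx2"):
        stack = ideal[name][None, :, :] * weights + noise.background_level
        if noise.poisson_scale > 0:
            stack = rng.poisson(stack / noise.poisson_scale).astype(np.float64) * noise.poisson_scale
        if noise.gaussian_sd > 0:
            stack = stack + rng.normal(0.0, noise.gaussian_sd, size=stack.shape)
        out[name] = np.clip(np.rint(stack), 0, max_value).astype(np.uint16)

    return ImageStack(
        channels=out,
        pixel_size_um=spec.pixel_size_um,
        z_spacing_um=spec.z_spacing_um,
        bit_depth=spec.bit_depth,
    )
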