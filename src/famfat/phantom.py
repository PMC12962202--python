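"""Digital phantoms: the 16-vial PDFF x T1 grid and a schematic liver slice.

The vial phantom emulates a quantitative fat-fraction phantom containing a
4 x 4 grid of cylindrical vials with simultaneously controlled PDFF
(0, 10, 20, 30 %) and water T1 (200, 600, 1000, 1400 ms); fat T1 is about
300 ms throughout.  Vials are rendered with a two-voxel anti-aliased edge on
the proton-density map so that partial-volume effects stay at the rim; ROI
analysis is restricted to vial centers.

The liver phantom is a geometric stand-in for a nine-segment liver slice:
an ellipse partitioned into nine angular sectors with smooth PDFF and R2*
fields.  Only the nine-label bookkeeping is anatomically meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

PDFF_LEVELS = (0.0, 0.10, 0.20, 0.30)
T1W_LEVELS_MS = (200.0, 600.0, 1000.0, 1400.0)
T1_FAT_MS = 300.0


@dataclass(frozen=True)
class Vial:
    center_cm: tuple[float, float]
    radius_cm: float
    pdff: float
    t1w_ms: float


@dataclass
class PhantomImage:
    """Voxelwise parameter maps on the acquisition grid plus vial layout."""

    m0: np.ndarray
    pdff: np.ndarray
    t1_water_ms: np.ndarray
    t1_fat_ms: np.ndarray
    r2star_s: np.ndarray
    psi_hz: np.ndarray
    fov_cm: tuple[float, float]
    vial_layout: list[Vial] = field(default_factory=list)
    labels: np.ndarray | None = None  # integer region labels (0 = background)

    def __post_init__(self) -> None:
        shape = self.m0.shape
        for name in ("pdff", "t1_water_ms", "t1_fat_ms", "r2star_s", "psi_hz"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} map shape {arr.shape} != m0 shape {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.m0.shape

    def grid_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center coordinates (cm), origin at the image center."""
        nx, ny = self.shape
        dx, dy = self.fov_cm[0] / nx, self.fov_cm[1] / ny
        x = (np.arange(nx) - (nx - 1) / 2.0) * dx
        y = (np.arange(ny) - (ny - 1) / 2.0) * dy
        return np.meshgrid(x, y, indexing="ij")


def make_pdff_t1_phantom(
    matrix: tuple[int, int] = (144, 144),
    fov_cm: tuple[float, float] = (44.0, 44.0),
    *,
    vial_radius_cm: float = 1.5,
    spacing_cm: float = 4.4,
    r2star_s: float = 40.0,
    psi_hz: float | np.ndarray = 0.0,
    edge_voxels: float = 2.0,
) -> PhantomImage:
    """Build the 16-vial PDFF x T1w phantom on the acquisition grid.

    Rows vary the water T1 (200/600/1000/1400 ms) and columns the PDFF
    (0/10/20/30 %).  Fat T1 is 300 ms everywhere; R2* defaults to
    40 1/s (typical for agar-based emulsion gels) and the field offset to 0.
    """
    nx, ny = matrix
    dx = fov_cm[0] / nx
    if 2 * vial_radius_cm / dx < 8:
        raise ValueError("matrix too coarse: each vial must span >= 8 voxels")
    if spacing_cm < 2 * vial_radius_cm:
        raise ValueError("vials would overlap at the given spacing")
    if 3 * spacing_cm + 2 * vial_radius_cm > min(fov_cm):
        raise ValueError("vial grid does not fit inside the field of view")

    m0 = np.zeros(matrix)
    pdff = np.zeros(matrix)
    t1w = np.full(matrix, T1W_LEVELS_MS[0])
    t1f = np.full(matrix, T1_FAT_MS)
    r2s = np.zeros(matrix)
    labels = np.zeros(matrix, dtype=int)
    vials: list[Vial] = []

    # PDFF varies along x (the fully sampled readout axis) and T1w along y
    # (the phase-encode axis): phase-encode-direction ringing then couples
    # vials that share a nominal PDFF, keeping fat/water leakage symmetric
    for i, t1w_val in enumerate(T1W_LEVELS_MS):
        for j, pdff_val in enumerate(PDFF_LEVELS):
            center = ((j - 1.5) * spacing_cm, (i - 1.5) * spacing_cm)
            vials.append(Vial(center, vial_radius_cm, pdff_val, t1w_val))

    phantom = PhantomImage(
        m0=m0, pdff=pdff, t1_water_ms=t1w, t1_fat_ms=t1f, r2star_s=r2s,
        psi_hz=np.broadcast_to(np.asarray(psi_hz, float), matrix).copy(),
        fov_cm=fov_cm, vial_layout=vials, labels=labels,
    )
    xx, yy = phantom.grid_cm()
    for idx, vial in enumerate(vials, start=1):
        dist = np.hypot(xx - vial.center_cm[0], yy - vial.center_cm[1])
        inside = dist <= vial.radius_cm
        # smooth proton-density edge over ~edge_voxels; parameter maps are
        # crisp so quantitative values are exact away from the rim
        soft = np.clip((vial.radius_cm - dist) / (edge_voxels * dx) + 0.5, 0.0, 1.0)
        m0[:] = np.maximum(m0, soft)
        pdff[inside] = vial.pdff
        t1w[inside] = vial.t1w_ms
        r2s[inside] = r2star_s
        labels[inside] = idx
    return phantom


@dataclass(frozen=True)
class ROI:
    """Circular region of interest in grid coordinates."""

    name: str
    mask: np.ndarray
    pdff_nominal: float | None = None
    t1w_nominal_ms: float | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def vial_rois(phantom: PhantomImage, diameter_cm: float = 1.4) -> list[ROI]:
    """Centered circular ROIs (default diameter 1.4 cm), one per vial."""
    if not phantom.vial_layout:
        raise ValueError("phantom has no vial layout")
    radius = diameter_cm / 2.0
    xx, yy = phantom.grid_cm()
    rois = []
    for vial in phantom.vial_layout:
        if radius >= vial.radius_cm:
            raise ValueError("ROI diameter must be smaller than the vial diameter")
        mask = np.hypot(xx - vial.center_cm[0], yy - vial.center_cm[1]) <= radius
        if not mask.any():
            raise ValueError("ROI contains no voxels; matrix too coarse")
        name = f"pdff{vial.pdff * 100:.0f}_t1w{vial.t1w_ms:.0f}"
        rois.append(ROI(name, mask, pdff_nominal=vial.pdff, t1w_nominal_ms=vial.t1w_ms))
    return rois


def make_synthetic_liver(
    matrix: tuple[int, int] = (144, 144),
    fov_cm: tuple[float, float] = (44.0, 44.0),
    *,
    pdff_level: float = 0.10,
    r2star_range_s: tuple[float, float] = (30.0, 60.0),
    heterogeneity: float = 0.0,
    t1_water_ms: float = 809.0,
    seed: int = 0,
) -> PhantomImage:
    """Schematic liver slice partitioned into nine labeled segments.

    An ellipse occupying the upper-left portion of the field of view is
    divided into nine angular sectors (labels 1..9).  PDFF varies smoothly
    around ``pdff_level`` with amplitude ``heterogeneity`` (fraction units)
    and R2* ramps across the configured range.  This is a pipeline-testing
    stand-in, not anatomy.
    """
    if not 0.0 <= pdff_level <= 0.4:
        raise ValueError("pdff_level must lie in [0, 0.4]")
    nx, ny = matrix
    base = PhantomImage(
        m0=np.zeros(matrix), pdff=np.zeros(matrix),
        t1_water_ms=np.full(matrix, t1_water_ms),
        t1_fat_ms=np.full(matrix, T1_FAT_MS),
        r2star_s=np.zeros(matrix), psi_hz=np.zeros(matrix),
        fov_cm=fov_cm,
    )
    xx, yy = base.grid_cm()
    cx, cy = -0.1 * fov_cm[0], -0.1 * fov_cm[1]
    ax, ay = 0.32 * fov_cm[0], 0.26 * fov_cm[1]
    inside = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    theta = np.arctan2(yy - cy, xx - cx)  # (-pi, pi]
    sector = np.minimum((theta + np.pi) / (2 * np.pi) * 9, 8.999).astype(int) + 1
    labels = np.where(inside, sector, 0)

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    smooth = np.sin(2 * np.pi * xx / fov_cm[0] + phase[0]) * np.cos(
        2 * np.pi * yy / fov_cm[1] + phase[1]
    )
    pdff = np.clip(pdff_level + heterogeneity * smooth, 0.0, 1.0)
    r_lo, r_hi = r2star_range_s
    ramp = (xx - xx.min()) / (xx.max() - xx.min())
    r2s = r_lo + (r_hi - r_lo) * ramp

    base.m0[inside] = 1.0
    base.pdff[inside] = pdff[inside]
    base.r2star_s[inside] = r2s[inside]
    base.labels = labels
    return base


def segment_rois(phantom: PhantomImage) -> list[ROI]:
    """One ROI per labeled liver segment (labels 1..9)."""
    if phantom.labels is None:
        raise ValueError("phantom carries no label map")
    rois = []
    for lab in range(1, int(phantom.labels.max()) + 1):
        mask = phantom.labels == lab
        if mask.any():
            rois.append(ROI(f"segment{lab}", mask))
    return rois


def save_layout_json(phantom: PhantomImage, path) -> None:
    payload = {
        "fov_cm": list(phantom.fov_cm),
        "vials": [
            {
                "center_cm": list(v.center_cm),
                "radius_cm": v.radius_cm,
                "pdff": v.pdff,
                "t1w_ms": v.t1w_ms,
            }
            for v in phantom.vial_layout
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
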