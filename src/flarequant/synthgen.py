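"""Synthetic two-channel yeast microscopy with exact ground truth.

Emulates the imaging regimes used to quantify fluorescent lipid reporters
(FLAREs) in budding yeast: an equatorial-plane view of elliptical cells with
a bright plasma-membrane (PM) ring seen by a reference PI(4,5)P2 reporter
(2xPH-like), and a tested reporter channel whose signal is split between the
PM and the cytosol. Cells can carry inward PM invaginations (finger-shaped
membrane tubes enriched in both reporters), intracellular foci (endosome-like
puncta of the tested reporter), and internalization kinetics after a
treatment time. A separate generator paints spherical lipid droplets into a
3-D stack for volumetry.

Every painted region is returned as a binary mask together with the analytic
noise-free intensity assigned to it, so downstream measurements (Pearson
colocalization, PM/cytoplasm enrichment, sorting coefficient, invagination
area, droplet volume) can be checked against a recoverable truth.

Intensity model of the tested channel
-------------------------------------
A cell emits a photon budget ``base_intensity * cell_area``. A fraction
``pm_fraction`` (p) is membrane-bound and spread uniformly over the membrane
pixels (ring + invaginations); the rest is cytosolic and spread uniformly
over all cell pixels. Per-pixel expectations (photons):

* cytoplasm:     ``c = base_intensity * (1 - p)``
* plain PM ring: ``c + m`` with ``m = base_intensity * p * A_cell / A_mem``
* invagination:  ``sorting_factor * invagination_enrichment * (c + m)``
* focus:         ``c + foci_intensity``

The reference channel paints ``base_intensity`` on the ring,
``invagination_enrichment * base_intensity`` in invaginations (the reference
reporter accumulates there), and a fixed cytosolic floor. By construction the
ratio-of-ratios (tested/reference in invagination over tested/reference on
plain PM) equals ``sorting_factor`` exactly in the noise-free image, and the
true PM/cytoplasm contrast of the tested channel is
``1 + p/(1-p) * A_cell/A_mem``.

Camera model: ``Poisson(photons) * gain + Normal(0, read_sigma) +
background_level + background_gradient * column``. One shared RNG stream per
call; the seed is recorded in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .types import ImageStack, LabelMask

__all__ = [
    "CellSpec",
    "KineticsSpec",
    "NoiseSpec",
    "GroundTruth",
    "PlacementError",
    "generate_field",
    "generate_timelapse",
    "generate_droplet_stack",
    "truth_profile_lines",
    "pm_fraction_curve",
]

DEFAULT_PIXEL_SIZE_UM = 0.1  # 63x/100x oil objectives, yeast ~4-5 um across
REF_CYTO_FRACTION = 0.2  # cytosolic floor of the reference reporter
FOCUS_RADIUS_PX = 2.0


class PlacementError(ValueError):
    """Two cells were placed closer than the sum of their radii."""


@dataclass(frozen=True)
class CellSpec:
    """Generative parameters of one synthetic cell.

    ``center`` and all geometry are in pixels, ``(row, col)``, 0-based.
    ``pm_fraction`` is the share of the tested reporter bound to the
    membrane; ``sorting_factor`` is the true invagination enrichment of the
    tested reporter relative to the reference (the quantity the sorting
    coefficient estimates). Intensities are photon expectations.
    """

    center: tuple[float, float]
    radii: tuple[float, float] = (22.0, 20.0)
    pm_ring_width: float = 3.0
    pm_fraction: float = 0.6
    sorting_factor: float = 1.0
    n_invaginations: int = 0
    invagination_depth: float = 8.0
    invagination_width: float = 3.0
    invagination_enrichment: float = 3.0
    n_foci: int = 0
    foci_intensity: float = 300.0
    base_intensity: float = 200.0

    def __post_init__(self) -> None:
        if not (min(self.radii) > self.pm_ring_width > 0):
            raise ValueError("need radii > pm_ring_width > 0")
        if not 0.0 <= self.pm_fraction <= 1.0:
            raise ValueError("pm_fraction must be in [0, 1]")
        if self.sorting_factor < 0:
            raise ValueError("sorting_factor must be >= 0")
        if self.n_invaginations < 0 or self.n_foci < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class KineticsSpec:
    """Internalization kinetics of the tested reporter after treatment.

    The true membrane-bound fraction follows, for t >= t_treat (t0):

        p(t) = p_end + (p0 + a * exp(-d (t - t0)) - p_end) * exp(-k (t - t0))

    and p(t) = p0 before t0. ``a`` (spike_amplitude) is a transient increase
    at the moment of treatment, ``d`` its decay, ``k`` the internalization
    rate, ``p_end`` the plateau. Signal leaving the membrane reappears in
    intracellular foci (mass-conserving redistribution).
    """

    t_treat_min: float = 5.0
    spike_amplitude: float = 0.0
    spike_decay_per_min: float = 1.0
    internalization_rate_per_min: float = 0.0
    pm_fraction_end: float = 0.2
    foci_growth_rate_per_min: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "spike_amplitude",
            "spike_decay_per_min",
            "internalization_rate_per_min",
            "foci_growth_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.pm_fraction_end <= 1.0:
            raise ValueError("pm_fraction_end must be in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Camera model: Poisson shot noise, gain, Gaussian read noise, background."""

    gain: float = 2.0  # ADU / photon
    read_sigma: float = 2.0  # ADU
    background_level: float = 100.0  # ADU
    background_gradient: float = 0.0  # ADU / px along columns
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseSpec":
        """Unit gain, no shot/read noise, zero background: image == expectation."""
        return cls(gain=1.0, read_sigma=0.0, background_level=0.0,
                   background_gradient=0.0, shot_noise=False, seed=seed)


@dataclass
class GroundTruth:
    """Everything the generator knows: specs, region masks, analytic values.

    ``region_masks[label]`` holds pairwise-disjoint boolean masks
    (``pm_ring``, ``invaginations``, ``cytoplasm``, ``foci``) whose union is
    the painted cell. ``expected[label][channel][region]`` is the noise-free
    photon expectation per pixel of that region. ``pm_contrast[label]`` is
    the analytic tested-channel PM/cytoplasm mean ratio (inf if the
    cytosolic pool is empty). For timelapses ``pm_fraction_t[label]`` is the
    true membrane-bound fraction per frame. For droplet stacks the per-object
    voxel-exact volumes are stored.
    """

    cell_specs: list[CellSpec] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    region_masks: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    expected: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    pm_contrast: dict[int, float] = field(default_factory=dict)
    invagination_axes: dict[int, list[tuple[tuple[float, float], tuple[float, float]]]] = field(
        default_factory=dict
    )
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0
    times_min: np.ndarray | None = None
    pm_fraction_t: dict[int, np.ndarray] | None = None
    kinetics: KineticsSpec | None = None
    droplet_volumes_um3: list[float] = field(default_factory=list)
    droplet_centers: list[tuple[float, float, float]] = field(default_factory=list)
    voxel_size_um: tuple[float, float, float] | None = None

    def region_map(self, shape: tuple[int, int]) -> np.ndarray:
        """uint8 map: 0 bg, 1 PM ring, 2 invagination, 3 cytoplasm, 4 focus."""
        codes = {"pm_ring": 1, "invaginations": 2, "cytoplasm": 3, "foci": 4}
        out = np.zeros(shape, dtype=np.uint8)
        for masks in self.region_masks.values():
            for name, code in codes.items():
                out[masks[name]] = code
        return out

    def to_dict(self) -> dict:
        """JSON-serializable summary (masks excluded; write those as TIFF)."""
        d: dict = {
            "schema": "flarequant.groundtruth/1",
            "seed": self.seed,
            "pixel_size_um": self.pixel_size_um,
            "labels": list(self.labels),
            "cell_specs": [asdict(s) for s in self.cell_specs],
            "expected": self.expected,
            "pm_contrast": self.pm_contrast,
            "invagination_axes": {
                str(k): [[list(p0), list(p1)] for p0, p1 in v]
                for k, v in self.invagination_axes.items()
            },
            "droplet_volumes_um3": list(self.droplet_volumes_um3),
        }
        if self.kinetics is not None:
            d["kinetics"] = asdict(self.kinetics)
        if self.times_min is not None:
            d["times_min"] = self.times_min.tolist()
        if self.pm_fraction_t is not None:
            d["pm_fraction_t"] = {str(k): v.tolist() for k, v in self.pm_fraction_t.items()}
        if self.voxel_size_um is not None:
            d["voxel_size_um"] = list(self.voxel_size_um)
        return d


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    ry, rx = radii
    return ((rr - center[0]) / ry) ** 2 + ((cc - center[1]) / rx) ** 2 <= 1.0


def _radial_extent(radii, theta) -> float:
    """Distance from center to the ellipse boundary along direction theta."""
    ry, rx = radii
    return 1.0 / math.sqrt((math.cos(theta) / ry) ** 2 + (math.sin(theta) / rx) ** 2)


def _segment_mask(shape, p0, p1, half_width) -> np.ndarray:
    """Pixels within half_width of the segment p0-p1 (row, col coords)."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    v = np.array(p1, float) - np.array(p0, float)
    L2 = float(v @ v)
    if L2 == 0:
        d2 = (rr - p0[0]) ** 2 + (cc - p0[1]) ** 2
        return d2 <= half_width**2
    t = ((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    d2 = (rr - (p0[0] + t * v[0])) ** 2 + (cc - (p0[1] + t * v[1])) ** 2
    return d2 <= half_width**2


def _paint_cell_regions(shape, spec: CellSpec, rng: np.random.Generator):
    """Return disjoint region masks and invagination axis endpoints."""
    cy, cx = spec.center
    cell = _ellipse_mask(shape, spec.center, spec.radii)
    inner_radii = (spec.radii[0] - spec.pm_ring_width, spec.radii[1] - spec.pm_ring_width)
    inner = _ellipse_mask(shape, spec.center, inner_radii)
    ring = cell & ~inner

    invag = np.zeros(shape, bool)
    axes = []
    if spec.n_invaginations > 0:
        theta0 = rng.uniform(0, 2 * math.pi)
        for i in range(spec.n_invaginations):
            theta = theta0 + 2 * math.pi * i / spec.n_invaginations
            u = np.array([math.sin(theta), math.cos(theta)])
            r_in = _radial_extent(inner_radii, theta)
            p0 = np.array([cy, cx]) + r_in * u
            p1 = np.array([cy, cx]) + max(r_in - spec.invagination_depth, 0.0) * u
            invag |= _segment_mask(shape, p0, p1, spec.invagination_width / 2.0) & inner
            axes.append((tuple(p0), tuple(p1)))

    foci = np.zeros(shape, bool)
    if spec.n_foci > 0:
        margin = spec.pm_ring_width + FOCUS_RADIUS_PX + 2
        allowed_radii = (max(spec.radii[0] - margin, 1.0), max(spec.radii[1] - margin, 1.0))
        placed = 0
        for _ in range(200 * spec.n_foci):
            if placed == spec.n_foci:
                break
            t = rng.uniform(0, 2 * math.pi)
            r = math.sqrt(rng.uniform(0, 1))
            fy = cy + r * allowed_radii[0] * math.sin(t)
            fx = cx + r * allowed_radii[1] * math.cos(t)
            disk = _segment_mask(shape, (fy, fx), (fy, fx), FOCUS_RADIUS_PX)
            if not disk.any() or (disk & (invag | ring | foci | ~cell)).any():
                continue
            foci |= disk
            placed += 1

    cytoplasm = inner & ~invag & ~foci
    return {
        "cell": cell,
        "pm_ring": ring,
        "invaginations": invag,
        "cytoplasm": cytoplasm,
        "foci": foci,
    }, axes


def _region_values(spec: CellSpec, masks: dict[str, np.ndarray], pm_fraction: float,
                   foci_extra: float = 0.0) -> dict[str, dict[str, float]]:
    """Analytic noise-free photon expectation per region and channel."""
    p = min(max(pm_fraction, 0.0), 1.0)
    B = spec.base_intensity
    a_cell = int(masks["cell"].sum())
    a_mem = int(masks["pm_ring"].sum()) + int(masks["invaginations"].sum())
    c = B * (1.0 - p)
    m = B * p * a_cell / a_mem if a_mem else 0.0
    e = spec.invagination_enrichment
    return {
        "reference": {
            "pm_ring": B,
            "invaginations": e * B,
            "cytoplasm": REF_CYTO_FRACTION * B,
            "foci": REF_CYTO_FRACTION * B,
        },
        "tested": {
            "pm_ring": c + m,
            # s-fold enrichment relative to the reference, which is itself
            # e-fold enriched in the invagination: ratio-of-ratios truth = s
            "invaginations": spec.sorting_factor * e * (c + m),
            "cytoplasm": c,
            "foci": c + spec.foci_intensity + foci_extra,
        },
    }


def _check_placement(cell_specs: list[CellSpec]) -> None:
    for i, a in enumerate(cell_specs):
        for b in cell_specs[i + 1 :]:
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < max(a.radii) + max(b.radii):
                raise PlacementError(
                    f"cells at {a.center} and {b.center} overlap "
                    f"(distance {d:.1f} < sum of radii)"
                )


def _apply_camera(expected: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.shot_noise:
        img = rng.poisson(expected).astype(np.float64) * noise.gain
    else:
        img = expected * noise.gain
    if noise.read_sigma > 0:
        img = img + rng.normal(0.0, noise.read_sigma, size=expected.shape)
    cols = np.arange(expected.shape[-1], dtype=np.float64)
    img = img + noise.background_level + noise.background_gradient * cols
    return np.asarray(img, np.float64)  # float64 so noise-free images are exact


def _expected_images(shape, specs, all_masks, values_per_cell):
    ref = np.zeros(shape, np.float64)
    tst = np.zeros(shape, np.float64)
    for masks, values in zip(all_masks, values_per_cell):
        for region in ("pm_ring", "invaginations", "cytoplasm", "foci"):
            ref[masks[region]] = values["reference"][region]
            tst[masks[region]] = values["tested"][region]
    return ref, tst


# ---------------------------------------------------------------------------
# public generators


def generate_field(
    cell_specs: list[CellSpec],
    noise: NoiseSpec = NoiseSpec(),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = (256, 256),
) -> tuple[ImageStack, LabelMask, GroundTruth]:
    """Paint a two-channel still image (reference, tested) of the given cells.

    Cells may deliberately overlap the image border (they are clipped); cells
    whose centers are closer than the sum of their radii raise
    :class:`PlacementError`.
    """
    if not cell_specs:
        raise ValueError("need at least one CellSpec")
    _check_placement(cell_specs)
    rng = np.random.default_rng(noise.seed)

    gt = GroundTruth(cell_specs=list(cell_specs), pixel_size_um=pixel_size_um, seed=noise.seed)
    label_img = np.zeros(shape, np.uint16)
    all_masks, all_values = [], []
    for i, spec in enumerate(cell_specs, start=1):
        masks, axes = _paint_cell_regions(shape, spec, rng)
        values = _region_values(spec, masks, spec.pm_fraction)
        label_img[masks["cell"]] = i
        gt.labels.append(i)
        gt.region_masks[i] = {k: masks[k] for k in ("pm_ring", "invaginations", "cytoplasm", "foci")}
        gt.expected[i] = values
        t = values["tested"]
        gt.pm_contrast[i] = (
            t["pm_ring"] / t["cytoplasm"] if t["cytoplasm"] > 0 else math.inf
        )
        gt.invagination_axes[i] = axes
        all_masks.append(masks)
        all_values.append(values)

    ref, tst = _expected_images(shape, cell_specs, all_masks, all_values)
    img = np.stack([_apply_camera(ref, noise, rng), _apply_camera(tst, noise, rng)])
    stack = ImageStack(img, "CYX", pixel_size_um=pixel_size_um,
                       channel_names=("reference", "tested"))
    return stack, LabelMask(label_img, pixel_size_um), gt


def pm_fraction_curve(p0: float, kinetics: KineticsSpec, times_min: np.ndarray) -> np.ndarray:
    """True membrane-bound fraction p(t) (clipped to [0, 1])."""
    t0 = kinetics.t_treat_min
    a = kinetics.spike_amplitude
    d = kinetics.spike_decay_per_min
    k = kinetics.internalization_rate_per_min
    p_end = kinetics.pm_fraction_end
    t = np.asarray(times_min, float)
    dt = t - t0
    p = np.where(
        dt < 0,
        p0,
        p_end + (p0 + a * np.exp(-d * np.maximum(dt, 0)) - p_end) * np.exp(-k * np.maximum(dt, 0)),
    )
    return np.clip(p, 0.0, 1.0)


def generate_timelapse(
    cell_specs: list[CellSpec],
    kinetics: KineticsSpec = KineticsSpec(),
    noise: NoiseSpec = NoiseSpec(),
    n_frames: int = 31,
    frame_interval_min: float = 1.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    shape: tuple[int, int] = (256, 256),
) -> tuple[ImageStack, LabelMask, GroundTruth]:
    """Two-channel timelapse with internalization kinetics after treatment.

    The default regime is 31 frames at 1-min intervals (a 30-min observation
    window). Signal lost from the membrane is redistributed into the cell's
    foci so that the tested channel is mass-conserving; cells without foci
    return it to the cytosolic pool implicitly via ``c = B (1 - p)``.
    """
    if n_frames < 2:
        raise ValueError("need n_frames >= 2")
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    if not cell_specs:
        raise ValueError("need at least one CellSpec")
    _check_placement(cell_specs)
    rng = np.random.default_rng(noise.seed)
    times = np.arange(n_frames, dtype=float) * frame_interval_min

    gt = GroundTruth(cell_specs=list(cell_specs), pixel_size_um=pixel_size_um,
                     seed=noise.seed, times_min=times, pm_fraction_t={}, kinetics=kinetics)
    label_img = np.zeros(shape, np.uint16)
    all_masks = []
    curves = []
    for i, spec in enumerate(cell_specs, start=1):
        masks, axes = _paint_cell_regions(shape, spec, rng)
        label_img[masks["cell"]] = i
        gt.labels.append(i)
        gt.region_masks[i] = {k: masks[k] for k in ("pm_ring", "invaginations", "cytoplasm", "foci")}
        gt.invagination_axes[i] = axes
        p_t = pm_fraction_curve(spec.pm_fraction, kinetics, times)
        gt.pm_fraction_t[i] = p_t
        all_masks.append(masks)
        curves.append(p_t)
        # truth/expected at frame 0 (pre-treatment state)
        values0 = _region_values(spec, masks, p_t[0])
        gt.expected[i] = values0
        t0v = values0["tested"]
        gt.pm_contrast[i] = (
            t0v["pm_ring"] / t0v["cytoplasm"] if t0v["cytoplasm"] > 0 else math.inf
        )

    frames = []
    for f in range(n_frames):
        values_per_cell = []
        for spec, masks, p_t in zip(cell_specs, all_masks, curves):
            a_foci = int(masks["foci"].sum())
            internalized = max(spec.pm_fraction - p_t[f], 0.0)
            extra = (
                spec.base_intensity * internalized * int(masks["cell"].sum()) / a_foci
                if a_foci
                else 0.0
            )
            values_per_cell.append(_region_values(spec, masks, p_t[f], foci_extra=extra))
        ref, tst = _expected_images(shape, cell_specs, all_masks, values_per_cell)
        frames.append(
            np.stack([_apply_camera(ref, noise, rng), _apply_camera(tst, noise, rng)])
        )

    stack = ImageStack(np.stack(frames), "TCYX", pixel_size_um=pixel_size_um,
                       frame_interval_min=frame_interval_min,
                       channel_names=("reference", "tested"))
    return stack, LabelMask(label_img, pixel_size_um), gt


def generate_droplet_stack(
    n_droplets: int,
    radii_um: float | list[float] = 0.25,
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1),
    noise: NoiseSpec = NoiseSpec(),
    shape: tuple[int, int, int] = (24, 96, 96),
    intensity: float = 400.0,
    centers: list[tuple[float, float, float]] | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """Paint spherical lipid droplets into a 3-D stack (ZYX).

    Truth volumes are voxel-exact: painted voxel count times voxel volume.
    Droplet radii must be at least one voxel in every axis; a droplet whose
    sphere leaves the field raises ``ValueError``. When ``centers`` is not
    given, non-touching placements are drawn from the RNG.
    """
    radii = list(np.broadcast_to(np.asarray(radii_um, float), (n_droplets,)))
    vz, vy, vx = voxel_size_um
    for r in radii:
        if r < max(voxel_size_um):
            raise ValueError(f"droplet radius {r} um is smaller than one voxel")
    rng = np.random.default_rng(noise.seed)

    if centers is None:
        centers = []
        for r in radii:
            rad_vox = np.array([r / vz, r / vy, r / vx])
            for _ in range(1000):
                c = np.array([rng.uniform(rad_vox[d] + 1, shape[d] - rad_vox[d] - 2)
                              for d in range(3)])
                ok = all(
                    np.linalg.norm((c - np.array(c2)) * np.array([vz, vy, vx]))
                    > r + r2 + 2 * max(voxel_size_um)
                    for c2, r2 in zip(centers, radii)
                )
                if ok:
                    centers.append(tuple(c))
                    break
            else:
                raise ValueError("could not place droplets without contact")
    elif len(centers) != n_droplets:
        raise ValueError("need one center per droplet")

    expected = np.zeros(shape, np.float64)
    gt = GroundTruth(seed=noise.seed, voxel_size_um=voxel_size_um,
                     pixel_size_um=vy, droplet_centers=list(centers))
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    voxel_volume = vz * vy * vx
    for (cz, cy, cx), r in zip(centers, radii):
        d2 = ((zz - cz) * vz) ** 2 + ((yy - cy) * vy) ** 2 + ((xx - cx) * vx) ** 2
        sphere = d2 <= r**2
        if not sphere.any():
            raise ValueError("droplet paints no voxels")
        touches = (
            sphere[0].any() or sphere[-1].any()
            or sphere[:, 0].any() or sphere[:, -1].any()
            or sphere[:, :, 0].any() or sphere[:, :, -1].any()
        )
        if touches:
            raise ValueError(f"droplet at {(cz, cy, cx)} extends outside the field")
        expected[sphere] += intensity
        gt.droplet_volumes_um3.append(float(sphere.sum()) * voxel_volume)

    img = _apply_camera(expected, noise, rng)
    stack = ImageStack(img, "ZYX", pixel_size_um=vy, voxel_size_um=voxel_size_um)
    return stack, gt


def random_cell_specs(
    n_cells: int,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    border_cells: int = 0,
    jitter_px: float = 3.0,
    **overrides,
) -> list[CellSpec]:
    """Place ``n_cells`` non-overlapping cells on a jittered grid.

    Radii are drawn uniformly from 20-25 px (yeast at ~0.1 um/px);
    ``overrides`` are passed to every :class:`CellSpec`. ``border_cells``
    additional cells are centred on the field edge so they clip the border
    (exercising border-cell exclusion).
    """
    rng = np.random.default_rng(seed)
    r_max = 25.0
    spacing = int(2 * r_max + 2 * jitter_px + 4)
    margin = int(r_max + jitter_px + 2)
    rows = np.arange(margin, shape[0] - margin + 1, spacing)
    cols = np.arange(margin, shape[1] - margin + 1, spacing)
    if border_cells > 0:
        rows = rows[rows >= spacing + margin]  # reserve the top band for border cells
    slots = [(float(r), float(c)) for r in rows for c in cols]
    if n_cells > len(slots) or border_cells > len(cols):
        raise ValueError(f"cells do not fit a {shape} field without overlap")
    rng.shuffle(slots)

    def _spec(center) -> CellSpec:
        ry = rng.uniform(20.0, 25.0)
        rx = rng.uniform(0.85, 1.0) * ry
        return CellSpec(center=center, radii=(ry, rx), **overrides)

    specs = [
        _spec((r + rng.uniform(-jitter_px, jitter_px), c + rng.uniform(-jitter_px, jitter_px)))
        for r, c in slots[:n_cells]
    ]
    specs.extend(_spec((0.0, float(c))) for c in cols[:border_cells])
    return specs


def truth_profile_lines(gt: GroundTruth, label: int, invagination_index: int = 0):
    """Ground-truth-guided line placements for sorting-coefficient checks.

    Returns a dict with two vertex lists (``(row, col)`` pairs):
    ``"invagination"`` runs along the axis of the chosen invagination, inset
    one pixel from either end so bilinear samples stay inside the painted
    finger; ``"pm"`` is a tangential segment of the same length centred on a
    plain-membrane point on the opposite side of the cell, at mid-ring depth.
    """
    spec = gt.cell_specs[gt.labels.index(label)]
    axes = gt.invagination_axes[label]
    if not axes:
        raise ValueError(f"cell {label} has no invaginations")
    p0, p1 = (np.array(p, float) for p in axes[invagination_index])
    u = p1 - p0
    length = float(np.linalg.norm(u))
    u = u / length
    inset = 1.0
    inv_a = p0 + inset * u
    inv_b = p1 - inset * u
    seg_len = float(np.linalg.norm(inv_b - inv_a))

    cy, cx = spec.center
    theta_inv = math.atan2(p0[0] - cy, p0[1] - cx)
    theta = theta_inv + math.pi  # far side of the cell: plain membrane
    mid_radii = (
        spec.radii[0] - spec.pm_ring_width / 2.0,
        spec.radii[1] - spec.pm_ring_width / 2.0,
    )
    r_mid = _radial_extent(mid_radii, theta)
    anchor = np.array([cy + r_mid * math.sin(theta), cx + r_mid * math.cos(theta)])
    tangent = np.array([math.cos(theta), -math.sin(theta)])
    pm_a = anchor - tangent * seg_len / 2.0
    pm_b = anchor + tangent * seg_len / 2.0
    return {
        "invagination": [tuple(inv_a), tuple(inv_b)],
        "pm": [tuple(pm_a), tuple(pm_b)],
    }
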