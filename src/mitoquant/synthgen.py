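"""Ground-truthed synthetic two-channel time-lapse stacks.

Emulates the statistical structure of super-resolution time-lapse recordings
of a small dividing cell (~5-7 um across) containing tubular mitochondria
(100-300 nm diameter):

* channel 0 ("red"): plasma-membrane shell plus a chromatin blob;
* channel 1 ("green"): mitochondrial matrix marker — capsules swept along
  3-D random-walk centrelines with bounded curvature;
* linear photobleaching per acquisition event with multiplicative
  timepoint-to-timepoint fluctuations;
* a fixed fraction of the red emission bleeding into the green channel;
* per-slice rigid motion jitter (the cell moves while the z-stack is
  scanned);
* 3-D PSF blur, Poisson shot noise and Gaussian read noise, quantised to
  16 bits.

Every voxel of every mitochondrion is tracked in an integer label volume, so
downstream segmentation can be scored against exact ground truth.  A
simulated cell division translates each capsule's voxel set by an integer
number of voxels into one of two daughter ellipsoids, conserving the total
foreground voxel count exactly (no biogenesis, no mitophagy).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from ._fft import FFTConvolver
from .rois import ROISet
from .stackio import ImageStack

__all__ = [
    "SceneSpec",
    "BleachSchedule",
    "JitterModel",
    "NoiseModel",
    "Scene",
    "GroundTruth",
    "SimulationResult",
    "SceneGenerationError",
    "generate_scene",
    "divide_scene",
    "simulate_timeseries",
    "cell_rois",
    "save_ground_truth",
]


class SceneGenerationError(RuntimeError):
    pass


@dataclass
class SceneSpec:
    """Geometry and sampling parameters of one synthetic cell scene.

    cell_semi_axes is (x, y, z) in um; voxel_size and fov_shape are
    (z, y, x).  Defaults follow the imaging conditions the pipeline is
    built for: 42.5 nm pixels, 130 nm z-steps, a ~6 x 5 x 3 um cell and 15
    mitochondria of 0.10-0.30 um diameter and 0.5-2.0 um length.
    """

    cell_semi_axes: tuple[float, float, float] = (3.0, 2.5, 1.5)
    n_mitochondria: int = 15
    mito_diameter_range: tuple[float, float] = (0.10, 0.30)
    mito_length_range: tuple[float, float] = (0.5, 2.0)
    membrane_thickness: float = 0.15
    membrane_standoff: float = 0.30   # min gap between mito surface and membrane, um
    chromatin_centre: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z) um
    chromatin_radius: float = 0.9
    chromatin_standoff: float = 0.20  # min gap between mito surface and chromatin, um
    voxel_size: tuple[float, float, float] = (0.130, 0.0425, 0.0425)
    fov_shape: tuple[int, int, int] = (28, 128, 152)
    amplitude_green: float = 400.0   # expected photons per fully occupied voxel
    amplitude_red: float = 400.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        ax, ay, az = self.cell_semi_axes
        minor = min(self.cell_semi_axes)
        dlo, dhi = self.mito_diameter_range
        if not (0 < dlo <= dhi < minor):
            raise ValueError("mito_diameter_range must lie within (0, cell minor axis)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_mitochondria < 0:
            raise ValueError("n_mitochondria must be non-negative")

    @property
    def semi_axes_zyx(self) -> tuple[float, float, float]:
        ax, ay, az = self.cell_semi_axes
        return (az, ay, ax)


@dataclass
class BleachSchedule:
    """Linear photobleaching per acquisition event with lognormal jitter.

    decay_rate_per_min: fractional loss of mean intensity per minute of
    acquisition (green marker default 1.75 %/min; a typical red marker
    bleaches faster, ~4.13 %/min).  Bleach accrues per acquisition event:
    the multiplier before event t (0-based) is 1 - rate * interval_min * t,
    jittered multiplicatively by a mean-one lognormal with sd
    ``fluctuation_sd`` and the step-to-step swing capped at
    ``max_step_change``.
    """

    decay_rate_per_min: float = 0.0175
    interval_s: float = 60.0
    fluctuation_sd: float = 0.05
    n_timepoints: int = 13
    max_step_change: float = 0.30

    def trend(self) -> np.ndarray:
        t = np.arange(self.n_timepoints)
        trend = 1.0 - self.decay_rate_per_min * (self.interval_s / 60.0) * t
        bad = np.nonzero(trend <= 0)[0]
        if bad.size:
            raise ValueError(
                f"bleach trend reaches zero at timepoint {int(bad[0])}; "
                "shorten the series or lower the decay rate"
            )
        return trend

    def multipliers(self, rng: np.random.Generator) -> np.ndarray:
        trend = self.trend()
        if self.fluctuation_sd <= 0:
            return trend
        sigma = math.sqrt(math.log(1.0 + self.fluctuation_sd**2))
        eps = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=self.n_timepoints)
        m = trend * eps
        # cap consecutive swings (they can reach but not exceed max_step_change)
        for t in range(1, self.n_timepoints):
            lo = m[t - 1] * (1.0 - self.max_step_change)
            hi = m[t - 1] * (1.0 + self.max_step_change)
            m[t] = min(max(m[t], lo), hi)
        return m


@dataclass
class JitterModel:
    """Per-slice rigid motion: uniform translation (px) and rotation (deg)."""

    translation_px: float = 3.0
    rotation_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.translation_px > 5.0 or self.rotation_deg > 2.0:
            raise ValueError("jitter bounds exceed the supported range (5 px, 2 deg)")

    def draw(self, rng: np.random.Generator, n_slices: int) -> np.ndarray:
        """(n_slices, 3) array of (rotation_deg, dy, dx)."""
        out = np.empty((n_slices, 3))
        out[:, 0] = rng.uniform(-self.rotation_deg, self.rotation_deg, n_slices)
        out[:, 1:] = rng.uniform(-self.translation_px, self.translation_px, (n_slices, 2))
        return out


@dataclass
class NoiseModel:
    """Poisson shot noise on expected photons, Gaussian read noise, 16-bit ADC.

    The read-noise default (1 photon rms) reflects the near-zero background
    floor of processed super-resolution stacks, which is what the pipeline
    consumes; raise it to emulate rawer detector output.
    """

    gain: float = 40.0        # digital numbers per photon
    read_sd: float = 1.0      # photons rms
    offset: float = 0.0       # digital numbers

    def apply(self, expected_photons: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        photons = rng.poisson(np.clip(expected_photons, 0, None)).astype(np.float64)
        photons += rng.normal(0.0, self.read_sd, size=photons.shape)
        dn = self.gain * photons + self.offset
        return np.clip(np.rint(dn), 0, 65535).astype(np.uint16)


@dataclass
class _Capsule:
    label: int
    radius_um: float
    length_um: float
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]   # hard (centre-in) indices
    occ_voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    occ_values: np.ndarray


@dataclass
class _CellBody:
    centre_um: np.ndarray       # (z, y, x) um, relative to FOV centre
    semi_axes_um: np.ndarray    # (z, y, x) um


@dataclass
class Scene:
    spec: SceneSpec
    cells: list[_CellBody]
    green: np.ndarray           # noise-free emission (photons/voxel), (z, y, x)
    red: np.ndarray
    labels: np.ndarray          # int32 mitochondrion labels, (z, y, x)
    capsules: list[_Capsule]

    @property
    def true_foreground_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))


@dataclass
class GroundTruth:
    """What the simulator actually did, for scoring the analysis against."""

    labels_per_timepoint: list[np.ndarray]
    true_foreground_voxels: list[int]
    transforms: np.ndarray            # (t, z, 3): rotation_deg, dy, dx
    multipliers_green: np.ndarray
    multipliers_red: np.ndarray
    rng_seed: Optional[int] = None


@dataclass
class SimulationResult:
    stack: ImageStack
    ground_truth: GroundTruth


def _grid_coords_um(spec: SceneSpec):
    """Voxel-centre coordinates (um) per axis, origin at the FOV centre."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * dv
        for n, dv in zip(spec.fov_shape, spec.voxel_size)
    ]


def _ellipsoid_q(coords, centre, semi) -> np.ndarray:
    """Normalised ellipsoid radius q (q<=1 inside) on the voxel grid."""
    z, y, x = coords
    qz = (z - centre[0]) / semi[0]
    qy = (y - centre[1]) / semi[1]
    qx = (x - centre[2]) / semi[2]
    return np.sqrt(
        qz[:, None, None] ** 2 + qy[None, :, None] ** 2 + qx[None, None, :] ** 2
    )


def _point_q(p, centre, semi) -> float:
    return float(np.sqrt(np.sum(((np.asarray(p) - centre) / semi) ** 2)))


def _sample_point_in_ellipsoid(rng, centre, semi) -> np.ndarray:
    while True:
        u = rng.uniform(-1.0, 1.0, 3)
        if np.sum(u**2) <= 1.0:
            return centre + u * semi


def _random_walk_centreline(
    rng: np.random.Generator,
    centre: np.ndarray,
    semi: np.ndarray,
    length_um: float,
    exclusions: Sequence[tuple[np.ndarray, float]] = (),
    step_um: float = 0.1,
    max_turn_deg: float = 25.0,
) -> Optional[np.ndarray]:
    """Centreline points inside the (already shrunk) ellipsoid, or None.

    ``exclusions`` is a list of (centre_um, radius_um) keep-out spheres
    (the chromatin mass) that no centreline point may enter.
    """

    def _ok(p: np.ndarray) -> bool:
        if _point_q(p, centre, semi) > 1.0:
            return False
        return all(
            np.linalg.norm(p - c) > r for c, r in exclusions
        )

    for _ in range(20):
        start = _sample_point_in_ellipsoid(rng, centre, semi)
        if _ok(start):
            break
    else:
        return None
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    pts = [start]
    n_steps = max(1, int(round(length_um / step_um)))
    for _ in range(n_steps):
        # bounded-curvature turn: blend direction with a random perturbation
        ang = math.radians(rng.uniform(0, max_turn_deg))
        perp = rng.normal(size=3)
        perp -= perp.dot(d) * d
        nrm = np.linalg.norm(perp)
        if nrm > 0:
            perp /= nrm
            d = math.cos(ang) * d + math.sin(ang) * perp
            d /= np.linalg.norm(d)
        nxt = pts[-1] + d * step_um
        if not _ok(nxt):
            return None
        pts.append(nxt)
    return np.asarray(pts)


def _voxelise_capsule(
    spec: SceneSpec, coords, pts: np.ndarray, radius_um: float, edge_um: float = 0.05
):
    """Distance-to-polyline voxelisation within the capsule's bounding box.

    Returns hard (centre inside) indices and soft-occupancy indices/values;
    the soft occupancy ramps linearly across ``edge_um`` so that summed
    occupancy approximates the analytic capsule volume.
    """
    zc, yc, xc = coords
    lo = pts.min(axis=0) - (radius_um + 2 * edge_um)
    hi = pts.max(axis=0) + (radius_um + 2 * edge_um)
    sl = []
    for axis, (c, a, b) in enumerate(zip((zc, yc, xc), lo, hi)):
        i0 = int(np.searchsorted(c, a))
        i1 = int(np.searchsorted(c, b, side="right"))
        if i1 <= i0:
            return None
        sl.append((i0, i1))
    bz = zc[sl[0][0] : sl[0][1]]
    by = yc[sl[1][0] : sl[1][1]]
    bx = xc[sl[2][0] : sl[2][1]]
    P = np.stack(
        np.meshgrid(bz, by, bx, indexing="ij"), axis=-1
    )  # (nz, ny, nx, 3)
    dmin = np.full(P.shape[:3], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab.dot(ab))
        ap = P - a
        t = np.clip(np.tensordot(ap, ab, axes=([3], [0])) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d = np.linalg.norm(P - closest, axis=-1)
        np.minimum(dmin, d, out=dmin)
    occ = np.clip((radius_um - dmin) / edge_um + 0.5, 0.0, 1.0)
    hard = dmin <= radius_um
    off = np.array([sl[0][0], sl[1][0], sl[2][0]])
    hz, hy, hx = np.nonzero(hard)
    oz, oy, ox = np.nonzero(occ > 0)
    return (
        (hz + off[0], hy + off[1], hx + off[2]),
        (oz + off[0], oy + off[1], ox + off[2]),
        occ[oz, oy, ox],
    )


def _membrane_and_chromatin(spec: SceneSpec, coords, cells: list[_CellBody]) -> np.ndarray:
    """Red-channel emission: Gaussian membrane shell(s) plus chromatin blob(s)."""
    red = np.zeros(spec.fov_shape, dtype=np.float64)
    for cell in cells:
        q = _ellipsoid_q(coords, cell.centre_um, cell.semi_axes_um)
        geo_mean = float(np.prod(cell.semi_axes_um)) ** (1.0 / 3.0)
        sigma_q = spec.membrane_thickness / (2.0 * geo_mean)
        red += spec.amplitude_red * np.exp(-0.5 * ((q - 1.0) / sigma_q) ** 2)
    # chromatin blob(s): one per cell, scaled to the cell's volume share
    n = len(cells)
    for cell in cells:
        c_um = np.asarray(spec.chromatin_centre)[::-1] + cell.centre_um \
            if n > 1 else np.asarray(spec.chromatin_centre)[::-1]
        radius = spec.chromatin_radius / (n ** (1.0 / 3.0))
        qc = _ellipsoid_q(coords, c_um, np.full(3, radius))
        red += spec.amplitude_red * np.clip((1.0 - qc) / 0.1 + 0.5, 0.0, 1.0)
    return red


def generate_scene(
    spec: SceneSpec, rng: Optional[np.random.Generator] = None
) -> Scene:
    """Render a single-cell scene: red membrane+chromatin, green capsules.

    Mitochondria are capsules (cylinders with hemispherical caps) swept
    along bounded-curvature random walks; each is placed entirely inside
    the cell ellipsoid, with up to 200 rejection attempts per capsule.

    Raises
    ------
    SceneGenerationError
        If a capsule cannot be placed (message reports the rng seed).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    coords = _grid_coords_um(spec)
    semi = np.asarray(spec.semi_axes_zyx)
    cell = _CellBody(centre_um=np.zeros(3), semi_axes_um=semi)

    green = np.zeros(spec.fov_shape, dtype=np.float64)
    labels = np.zeros(spec.fov_shape, dtype=np.int32)
    capsules: list[_Capsule] = []

    for i in range(spec.n_mitochondria):
        diameter = rng.uniform(*spec.mito_diameter_range)
        length = rng.uniform(*spec.mito_length_range)
        radius = diameter / 2.0
        chrom_centre = np.asarray(spec.chromatin_centre)[::-1]
        chrom_r = spec.chromatin_radius + radius + spec.chromatin_standoff
        placed = False
        for _ in range(200):
            shrunk = semi - (radius + spec.membrane_standoff)
            if np.any(shrunk <= 0):
                break
            pts = _random_walk_centreline(
                rng, cell.centre_um, shrunk, length,
                exclusions=[(chrom_centre, chrom_r)],
            )
            if pts is None:
                continue
            vox = _voxelise_capsule(spec, coords, pts, radius)
            if vox is None or len(vox[0][0]) == 0:
                continue
            hard, occ_idx, occ_val = vox
            if np.any(labels[hard] != 0):   # no overlapping capsules
                continue
            labels[hard] = i + 1
            np.add.at(green, occ_idx, spec.amplitude_green * occ_val)
            capsules.append(
                _Capsule(
                    label=i + 1,
                    radius_um=radius,
                    length_um=length,
                    voxels=hard,
                    occ_voxels=occ_idx,
                    occ_values=occ_val,
                )
            )
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not place mitochondrion {i + 1}/{spec.n_mitochondria} "
                f"inside the cell after 200 attempts (seed {spec.rng_seed})"
            )

    red = _membrane_and_chromatin(spec, coords, [cell])
    return Scene(
        spec=spec, cells=[cell], green=green, red=red, labels=labels, capsules=capsules
    )


def divide_scene(
    scene: Scene,
    rng: Optional[np.random.Generator] = None,
    daughter_axis_scale: tuple[float, float, float] = (0.93, 0.90, 0.53),
    separation_frac: float = 0.47,
) -> Scene:
    """Post-cytokinesis version of a scene: two daughters, conserved cargo.

    Each capsule is assigned to a daughter and its voxel set is translated
    by an integer number of voxels so that it lies inside the daughter
    ellipsoid; integer shifts keep the voxelisation (and therefore the
    total foreground voxel count and total green emission) exactly equal
    to the mother scene's.  Daughters sit side by side along x.

    daughter_axis_scale scales the mother's (z, y, x) semi-axes.
    """
    if rng is None:
        rng = np.random.default_rng(scene.spec.rng_seed + 1)
    spec = scene.spec
    coords = _grid_coords_um(spec)
    semi = np.asarray(spec.semi_axes_zyx)
    d_semi = semi * np.asarray(daughter_axis_scale)
    offset_x = separation_frac * semi[2]
    daughters = [
        _CellBody(centre_um=np.array([0.0, 0.0, -offset_x]), semi_axes_um=d_semi.copy()),
        _CellBody(centre_um=np.array([0.0, 0.0, +offset_x]), semi_axes_um=d_semi.copy()),
    ]

    voxel = np.asarray(spec.voxel_size)
    green = np.zeros(spec.fov_shape, dtype=np.float64)
    labels = np.zeros(spec.fov_shape, dtype=np.int32)
    new_capsules: list[_Capsule] = []

    for cap in scene.capsules:
        hz, hy, hx = cap.voxels
        centroid = np.array(
            [coords[0][hz].mean(), coords[1][hy].mean(), coords[2][hx].mean()]
        )
        # cargo partitions by position: each mother half feeds one daughter,
        # and capsules keep their relative arrangement within the half
        side = 1 if centroid[2] >= 0 else 0
        daughter = daughters[side]
        # along x a mother *half* maps onto a whole daughter
        axis_scale = daughter.semi_axes_um / (semi * np.array([1.0, 1.0, 0.5]))
        preferred = daughter.centre_um + (centroid - daughter.centre_um) * axis_scale
        placed = False
        for attempt in range(2000):
            # phase 1: stay near the mapped position (structure-preserving);
            # phase 2: search the whole daughter, relaxing the standoffs
            if attempt < 800:
                standoff = spec.membrane_standoff * (1.0 - 0.5 * attempt / 800.0)
                chrom_standoff = spec.chromatin_standoff
                scatter = 0.05 + 0.35 * attempt / 800.0
                target = preferred + rng.normal(0.0, scatter, 3)
            else:
                relax = (attempt - 800) / 1200.0
                standoff = spec.membrane_standoff * 0.5 * (1.0 - relax)
                chrom_standoff = spec.chromatin_standoff * (1.0 - relax)
                target = _sample_point_in_ellipsoid(
                    rng, daughter.centre_um, daughter.semi_axes_um * 0.85
                )
            shift_vox = np.rint((target - centroid) / voxel).astype(int)
            nz, ny, nx = hz + shift_vox[0], hy + shift_vox[1], hx + shift_vox[2]
            if nz.min() < 0 or ny.min() < 0 or nx.min() < 0:
                continue
            if (
                nz.max() >= spec.fov_shape[0]
                or ny.max() >= spec.fov_shape[1]
                or nx.max() >= spec.fov_shape[2]
            ):
                continue
            pos = np.stack(
                [coords[0][nz], coords[1][ny], coords[2][nx]], axis=-1
            )
            inner_semi = daughter.semi_axes_um - standoff
            q = np.sqrt(
                np.sum(((pos - daughter.centre_um) / inner_semi) ** 2, axis=-1)
            )
            if q.max() > 1.0:
                continue
            chrom_c = np.asarray(spec.chromatin_centre)[::-1] + daughter.centre_um
            chrom_r = spec.chromatin_radius / (2.0 ** (1.0 / 3.0)) + chrom_standoff
            if np.min(np.linalg.norm(pos - chrom_c, axis=-1)) < chrom_r:
                continue
            if np.any(labels[nz, ny, nx] != 0):
                continue
            oz, oy, ox = cap.occ_voxels
            oz2, oy2, ox2 = oz + shift_vox[0], oy + shift_vox[1], ox + shift_vox[2]
            keep = (
                (oz2 >= 0)
                & (oz2 < spec.fov_shape[0])
                & (oy2 >= 0)
                & (oy2 < spec.fov_shape[1])
                & (ox2 >= 0)
                & (ox2 < spec.fov_shape[2])
            )
            labels[nz, ny, nx] = cap.label
            np.add.at(
                green,
                (oz2[keep], oy2[keep], ox2[keep]),
                spec.amplitude_green * cap.occ_values[keep],
            )
            new_capsules.append(
                replace(
                    cap,
                    voxels=(nz, ny, nx),
                    occ_voxels=(oz2[keep], oy2[keep], ox2[keep]),
                    occ_values=cap.occ_values[keep],
                )
            )
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not relocate mitochondrion {cap.label} into a daughter "
                f"cell after 2000 attempts (seed {spec.rng_seed})"
            )

    red = _membrane_and_chromatin(spec, coords, daughters)
    return Scene(
        spec=spec,
        cells=daughters,
        green=green,
        red=red,
        labels=labels,
        capsules=new_capsules,
    )


def _apply_slice_jitter(volume: np.ndarray, transforms: np.ndarray) -> np.ndarray:
    """Apply per-slice rigid transforms (rotation about centre + shift)."""
    out = np.empty_like(volume)
    centre = (np.asarray(volume.shape[1:]) - 1) / 2.0
    for z in range(volume.shape[0]):
        ang = math.radians(transforms[z, 0])
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        shift = transforms[z, 1:]
        # output pixel o maps to input rot^-1 @ (o - centre - shift) + centre
        inv = rot.T
        offset = centre - inv @ (centre + shift)
        out[z] = ndimage.affine_transform(
            volume[z], inv, offset=offset, order=1, mode="constant", cval=0.0
        )
    return out


def simulate_timeseries(
    scene: Union[Scene, Sequence[Scene]],
    schedule: BleachSchedule,
    psf: Optional[np.ndarray] = None,
    bleedthrough_fraction: float = 0.08,
    jitter: Optional[JitterModel] = None,
    noise: Optional[NoiseModel] = None,
    rng_seed: int = 0,
    red_schedule: Optional[BleachSchedule] = None,
    timepoints: Optional[Sequence[int]] = None,
) -> SimulationResult:
    """Simulate the acquired (t, c, z, y, x) stack for a scene or scene list.

    The expected green channel at event t is
    ``PSF * (m_green[t] * green0 + bleedthrough * m_red[t] * red0)``; the
    red channel is ``PSF * (m_red[t] * red0)``.  Per-slice rigid jitter is
    applied identically to both channels (the specimen moves, the optics do
    not), then shot/read noise.  With ``noise=None`` the stack is returned
    as float64 expected photons (no quantisation), which downstream
    linearity tests rely on.

    Parameters
    ----------
    scene : a single Scene, or one Scene per timepoint (e.g. mother before
        a division event, daughters after).
    timepoints : optional subset of event indices to materialise (bleach
        still accrues over all earlier events); frames keep this order.
    """
    if not (0.0 <= bleedthrough_fraction < 1.0):
        raise ValueError("bleedthrough_fraction must be in [0, 1)")
    if psf is not None:
        psf = np.asarray(psf, dtype=np.float64)
        if psf.min() < 0 or abs(psf.sum() - 1.0) > 1e-6:
            raise ValueError("psf must be non-negative and sum to 1")

    n_t = schedule.n_timepoints
    scenes: list[Scene] = list(scene) if isinstance(scene, (list, tuple)) else [scene] * n_t
    if len(scenes) != n_t:
        raise ValueError("need one scene per timepoint (or a single scene)")
    if red_schedule is None:
        red_schedule = replace(
            schedule, decay_rate_per_min=0.0413, n_timepoints=n_t
        )
    if red_schedule.n_timepoints != n_t:
        raise ValueError("red_schedule must cover the same number of timepoints")

    rng = np.random.default_rng(rng_seed)
    m_green = schedule.multipliers(rng)
    m_red = red_schedule.multipliers(rng)

    frames = list(range(n_t)) if timepoints is None else list(timepoints)
    if any(t < 0 or t >= n_t for t in frames):
        raise ValueError("timepoints outside the schedule range")

    shape3 = scenes[0].spec.fov_shape
    # blur each distinct scene once; per-timepoint frames are linear combos
    blurred: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for sc in scenes:
        key = id(sc)
        if key not in blurred:
            if psf is None:
                blurred[key] = (sc.green, sc.red)
            else:
                conv = FFTConvolver(psf, shape3)
                blurred[key] = (conv.convolve(sc.green), conv.convolve(sc.red))

    n_z = shape3[0]
    transforms = np.zeros((len(frames), n_z, 3))
    out_dtype = np.uint16 if noise is not None else np.float64
    data = np.empty((len(frames), 2, *shape3), dtype=out_dtype)
    labels_per_tp: list[np.ndarray] = []
    fg_per_tp: list[int] = []

    for k, t in enumerate(frames):
        sc = scenes[t]
        gb, rb = blurred[id(sc)]
        exp_red = m_red[t] * rb
        exp_green = m_green[t] * gb + bleedthrough_fraction * exp_red
        if jitter is not None:
            tr = jitter.draw(rng, n_z)
            transforms[k] = tr
            exp_red = _apply_slice_jitter(exp_red, tr)
            exp_green = _apply_slice_jitter(exp_green, tr)
        if noise is not None:
            data[k, 0] = noise.apply(exp_red, rng)
            data[k, 1] = noise.apply(exp_green, rng)
        else:
            data[k, 0] = exp_red
            data[k, 1] = exp_green
        labels_per_tp.append(sc.labels)
        fg_per_tp.append(sc.true_foreground_voxels)

    stack = ImageStack(
        data=data,
        voxel_size=scenes[0].spec.voxel_size,
        channel_names=["red", "green"],
    )
    gt = GroundTruth(
        labels_per_timepoint=labels_per_tp,
        true_foreground_voxels=fg_per_tp,
        transforms=transforms,
        multipliers_green=m_green[frames],
        multipliers_red=m_red[frames],
        rng_seed=rng_seed,
    )
    return SimulationResult(stack=stack, ground_truth=gt)


def cell_rois(scene: Scene, margin_um: float = 0.3, n_vertices: int = 48) -> ROISet:
    """Per-slice elliptical polygons tracing each cell body, with a margin."""
    spec = scene.spec
    coords = _grid_coords_um(spec)
    dz, dy, dx = spec.voxel_size
    n_z, n_y, n_x = spec.fov_shape
    polys: dict[int, list[np.ndarray]] = {}
    phi = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    for z in range(n_z):
        z_um = coords[0][z]
        slice_polys = []
        for cell in scene.cells:
            az, ay, ax = cell.semi_axes_um
            rel = (z_um - cell.centre_um[0]) / az
            if abs(rel) >= 1.0:
                continue
            scale = math.sqrt(1.0 - rel**2)
            ry = ay * scale + margin_um
            rx = ax * scale + margin_um
            cy = (cell.centre_um[1] / dy) + (n_y - 1) / 2.0
            cx = (cell.centre_um[2] / dx) + (n_x - 1) / 2.0
            rows = cy + (ry / dy) * np.sin(phi)
            cols = cx + (rx / dx) * np.cos(phi)
            slice_polys.append(
                np.clip(
                    np.stack([rows, cols], axis=1),
                    0,
                    [n_y - 1, n_x - 1],
                )
            )
        if slice_polys:
            polys[z] = slice_polys
    return ROISet(polygons=polys)


def save_ground_truth(gt: GroundTruth, stem: Union[str, Path]) -> tuple[Path, Path]:
    """Persist ground truth as sidecar JSON plus a label TIFF."""
    import tifffile

    stem = Path(stem)
    labels = np.stack(gt.labels_per_timepoint).astype(np.int32)
    tif_path = stem.with_suffix(".labels.tif")
    tifffile.imwrite(tif_path, labels)
    payload = {
        "true_foreground_voxels": gt.true_foreground_voxels,
        "transforms": gt.transforms.tolist(),
        "multipliers_green": gt.multipliers_green.tolist(),
        "multipliers_red": gt.multipliers_red.tolist(),
        "rng_seed": gt.rng_seed,
    }
    json_path = stem.with_suffix(".groundtruth.json")
    json_path.write_text(json.dumps(payload))
    return json_path, tif_path
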