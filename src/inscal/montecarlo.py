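"""Voxel-based Monte Carlo transport of 1875 nm light in layered tissue.

Models the stimulation geometry: a multimode fiber (200 μm core, NA 0.37)
resting on the cover glass at ~45° to the horizontal, launching photons
through a three-layer stack (ACSF / cover glass / cortex) discretised on a
Cartesian voxel grid (default 4×4×4 mm at 10 μm pitch).  Transport is the
standard weighted-photon random walk: exponential step lengths in optical
depth, partial-weight absorption μa/μt per interaction, Henyey–Greenstein
scattering, unpolarised Fresnel reflection/refraction where the refractive
index changes across a voxel face, and Russian-roulette termination of
low-weight photons.

The deposited-energy map defines the *illuminated region* at a given imaging
depth, used to bin neurons into illuminated vs weakly illuminated cohorts.

Optical properties at 1875 nm are configuration, not measurement: the
defaults are literature-typical placeholders (water-dominated absorption
~3 mm⁻¹, modest cortical scattering) and should be overridden when better
values are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "OpticalProperties",
    "Layer",
    "TissueModel",
    "FiberSpec",
    "FluenceMap",
    "build_tissue",
    "default_layers",
    "launch_photons",
    "run_monte_carlo",
    "illuminated_region",
    "cone_mask",
    "bin_neurons",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption μa (mm⁻¹), scattering μs (mm⁻¹), anisotropy g, index n."""

    mu_a: float
    mu_s: float
    g: float = 0.0
    n: float = 1.33

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be >= 0")
        if not -1 <= self.g <= 1:
            raise ValueError("g must lie in [-1, 1]")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class Layer:
    name: str
    thickness_mm: float
    properties: OpticalProperties

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be > 0")


def default_layers() -> list[Layer]:
    """ACSF / cover glass / cortex stack with placeholder 1875 nm properties."""
    return [
        Layer("acsf", 0.50, OpticalProperties(mu_a=3.0, mu_s=0.0, g=0.0, n=1.33)),
        Layer("glass", 0.17, OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0, n=1.52)),
        Layer("cortex", 3.33, OpticalProperties(mu_a=3.0, mu_s=5.0, g=0.9, n=1.36)),
    ]


@dataclass
class TissueModel:
    """Voxelised layered tissue cube.

    ``label_grid[ix, iy, iz]`` holds the layer index of each voxel (z is
    depth, origin at the top corner of the cube); per-layer property arrays
    are indexed by that label.  The grid may be edited voxel-wise for
    non-planar geometries.
    """

    extent_mm: float
    voxel_pitch_mm: float
    layers: list[Layer]
    label_grid: np.ndarray

    @property
    def voxels_per_axis(self) -> int:
        return self.label_grid.shape[0]

    @property
    def mu_a(self) -> np.ndarray:
        return np.array([l.properties.mu_a for l in self.layers])

    @property
    def mu_s(self) -> np.ndarray:
        return np.array([l.properties.mu_s for l in self.layers])

    @property
    def g(self) -> np.ndarray:
        return np.array([l.properties.g for l in self.layers])

    @property
    def n(self) -> np.ndarray:
        return np.array([l.properties.n for l in self.layers])

    def layer_top_mm(self, name: str) -> float:
        """Depth (mm) of the top surface of the named layer."""
        z = 0.0
        for layer in self.layers:
            if layer.name == name:
                return z
            z += layer.thickness_mm
        raise KeyError(f"no layer named {name!r}")


def build_tissue(
    layers: list[Layer] | None = None,
    extent_mm: float = 4.0,
    voxel_pitch_mm: float = 0.010,
) -> TissueModel:
    """Discretise a layer stack onto a cubic voxel grid.

    The extent must be an integer multiple of the pitch (default 4 mm / 10 μm
    = 400 voxels per axis).  Depth beyond the listed layers is assigned to
    the last layer.
    """
    layers = default_layers() if layers is None else list(layers)
    if not layers:
        raise ValueError("at least one layer is required")
    ratio = extent_mm / voxel_pitch_mm
    nv = int(round(ratio))
    if abs(ratio - nv) > 1e-9 or nv < 1:
        raise ValueError(f"extent {extent_mm} mm is not an integer multiple of pitch {voxel_pitch_mm} mm")
    if sum(l.thickness_mm for l in layers) > extent_mm + 1e-9:
        raise ValueError("layer thicknesses exceed the cube depth")
    if len(layers) > 255:
        raise ValueError("too many layers for a uint8 label grid")

    z_centers = (np.arange(nv) + 0.5) * voxel_pitch_mm
    labels_z = np.full(nv, len(layers) - 1, dtype=np.uint8)
    z0 = 0.0
    for i, layer in enumerate(layers):
        z1 = z0 + layer.thickness_mm
        labels_z[(z_centers >= z0) & (z_centers < z1)] = i
        z0 = z1
    label_grid = np.broadcast_to(labels_z[None, None, :], (nv, nv, nv)).copy()
    return TissueModel(extent_mm, voxel_pitch_mm, layers, label_grid)


@dataclass(frozen=True)
class FiberSpec:
    """Multimode stimulation fiber: geometry and launch optics.

    ``tilt_deg`` is the angle of the fiber axis to the horizontal plane, with
    the tilt lying in the x–z plane (the beam advances along +x while going
    down +z).  ``tip_position_mm`` is the centre of the fiber face in grid
    coordinates; by default it sits on the top surface of the cover glass.
    ``glass_transmission`` is a scalar radiant-exposure correction applied as
    the initial photon weight.
    """

    core_diameter_um: float = 200.0
    numerical_aperture: float = 0.37
    tilt_deg: float = 45.0
    tip_position_mm: tuple[float, float, float] = (1.5, 2.0, 0.5)
    wavelength_nm: float = 1875.0
    glass_transmission: float = 1.0

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0:
            raise ValueError("core diameter must be > 0")
        if not 0 < self.numerical_aperture < 1.33:
            raise ValueError("numerical aperture must lie in (0, n_launch_medium)")
        if not 0 < self.glass_transmission <= 1:
            raise ValueError("glass_transmission must lie in (0, 1]")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the fiber axis (into the tissue)."""
        th = math.radians(self.tilt_deg)
        return np.array([math.cos(th), 0.0, math.sin(th)])


def launch_photons(
    fiber: FiberSpec,
    n_photons: int,
    rng: np.random.Generator,
    n_medium: float = 1.33,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample launch positions, directions and weights for ``n_photons``.

    Positions are uniform over the tilted fiber face (disc of the core
    diameter); directions deviate from the fiber axis by a polar angle θ with
    sin θ uniform on [0, NA/n_medium] and uniform azimuth, the standard
    far-field cone of a multimode fiber.  Initial weight is the glass
    transmission factor.
    """
    axis = fiber.axis
    th = math.radians(fiber.tilt_deg)
    e1 = np.array([-math.sin(th), 0.0, math.cos(th)])
    e2 = np.array([0.0, 1.0, 0.0])

    r = 0.5 * fiber.core_diameter_um * 1e-3 * np.sqrt(rng.random(n_photons))
    phi = 2 * np.pi * rng.random(n_photons)
    pos = (
        np.asarray(fiber.tip_position_mm)[None, :]
        + r[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )

    sin_t = rng.random(n_photons) * (fiber.numerical_aperture / n_medium)
    cos_t = np.sqrt(1.0 - sin_t**2)
    psi = 2 * np.pi * rng.random(n_photons)
    dirs = (
        cos_t[:, None] * axis
        + (sin_t * np.cos(psi))[:, None] * e1
        + (sin_t * np.sin(psi))[:, None] * e2
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    weights = np.full(n_photons, fiber.glass_transmission)
    return pos, dirs, weights


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@njit(cache=True)
def _transport(
    label,
    mua,
    mus,
    g_arr,
    n_arr,
    pitch,
    pos,
    dirs,
    weights,
    absorbed,
    rr_threshold,
    rr_survival,
    seed,
):
    """Weighted-photon random walk; returns (absorbed, escaped, roulette_net)."""
    np.random.seed(seed)
    nx, ny, nz = label.shape
    absorbed_total = 0.0
    escaped_total = 0.0
    roulette_net = 0.0
    eps = 1e-7 * pitch

    for p in range(pos.shape[0]):
        x, y, z = pos[p, 0], pos[p, 1], pos[p, 2]
        ux, uy, uz = dirs[p, 0], dirs[p, 1], dirs[p, 2]
        w = weights[p]
        s = -math.log(np.random.random())
        while True:
            ix = int(math.floor(x / pitch))
            iy = int(math.floor(y / pitch))
            iz = int(math.floor(z / pitch))
            if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
                escaped_total += w
                break
            lab = label[ix, iy, iz]
            mt = mua[lab] + mus[lab]

            # distance to the nearest voxel face along the direction
            dbx = ((ix + 1) * pitch - x) / ux if ux > 0 else ((ix * pitch - x) / ux if ux < 0 else 1e30)
            dby = ((iy + 1) * pitch - y) / uy if uy > 0 else ((iy * pitch - y) / uy if uy < 0 else 1e30)
            dbz = ((iz + 1) * pitch - z) / uz if uz > 0 else ((iz * pitch - z) / uz if uz < 0 else 1e30)
            db = dbx
            axis = 0
            if dby < db:
                db = dby
                axis = 1
            if dbz < db:
                db = dbz
                axis = 2
            if db < 0.0:
                db = 0.0

            if mt * db < s:
                # traverse to the face; handle a refractive-index step there
                s -= mt * db
                x += ux * db
                y += uy * db
                z += uz * db
                jx, jy, jz = ix, iy, iz
                if axis == 0:
                    jx += 1 if ux > 0 else -1
                elif axis == 1:
                    jy += 1 if uy > 0 else -1
                else:
                    jz += 1 if uz > 0 else -1
                if jx < 0 or jy < 0 or jz < 0 or jx >= nx or jy >= ny or jz >= nz:
                    escaped_total += w
                    break
                lab2 = label[jx, jy, jz]
                n1 = n_arr[lab]
                n2 = n_arr[lab2]
                if n1 != n2:
                    if axis == 0:
                        ua = ux
                    elif axis == 1:
                        ua = uy
                    else:
                        ua = uz
                    ci = abs(ua)
                    sin_t2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
                    reflect = False
                    if sin_t2 >= 1.0:
                        reflect = True  # total internal reflection
                    else:
                        ct = math.sqrt(1.0 - sin_t2)
                        rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
                        rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
                        refl = 0.5 * (rs * rs + rp * rp)
                        if np.random.random() < refl:
                            reflect = True
                    if reflect:
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                    else:
                        scale = n1 / n2
                        sign = 1.0 if ua > 0 else -1.0
                        if axis == 0:
                            uy *= scale
                            uz *= scale
                            ux = sign * ct
                        elif axis == 1:
                            ux *= scale
                            uz *= scale
                            uy = sign * ct
                        else:
                            ux *= scale
                            uy *= scale
                            uz = sign * ct
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                # nudge off the face so the next voxel lookup is unambiguous
                x += ux * eps
                y += uy * eps
                z += uz * eps
            else:
                # interaction inside this voxel
                if mt > 0.0:
                    d = s / mt
                    x += ux * d
                    y += uy * d
                    z += uz * d
                    dep = w * mua[lab] / mt
                    absorbed[ix, iy, iz] += dep
                    absorbed_total += dep
                    w -= dep
                    if w <= 0.0:
                        break
                    gg = g_arr[lab]
                    ct = _hg_cos(gg, np.random.random())
                    st = math.sqrt(max(0.0, 1.0 - ct * ct))
                    phi = 2.0 * math.pi * np.random.random()
                    cp = math.cos(phi)
                    sp = math.sin(phi)
                    if abs(uz) > 0.99999:
                        ux = st * cp
                        uy = st * sp
                        uz = ct if uz > 0 else -ct
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                        nuz = -st * cp * den + uz * ct
                        ux, uy, uz = nux, nuy, nuz
                    s = -math.log(np.random.random())
                    if w < rr_threshold:
                        if np.random.random() < rr_survival:
                            roulette_net += w * (1.0 / rr_survival - 1.0)
                            w /= rr_survival
                        else:
                            roulette_net -= w
                            break
    return absorbed_total, escaped_total, roulette_net


@dataclass
class FluenceMap:
    """Deposited-weight map and conservation ledger of one Monte Carlo run.

    ``absorbed`` holds the weight fraction deposited per voxel.  ``totals``
    books every unit of weight: launched photon weight, absorbed and escaped
    totals, and the net weight created/destroyed by Russian roulette, so that
    ``launched + roulette_net == absorbed + escaped`` to float precision
    (with roulette disabled, ``launched == absorbed + escaped`` exactly).
    """

    absorbed: np.ndarray
    tissue: TissueModel
    totals: dict
    seed: int
    n_photons: int

    def fluence(self) -> np.ndarray:
        """Per-voxel fluence-like quantity: absorbed weight / μa (zero where
        the medium does not absorb)."""
        mua_vox = self.tissue.mu_a[self.tissue.label_grid]
        out = np.zeros_like(self.absorbed)
        np.divide(self.absorbed, mua_vox, out=out, where=mua_vox > 0)
        return out

    def conservation_error(self) -> float:
        """Relative weight-balance error of the run ledger."""
        t = self.totals
        return abs(t["launched"] + t["roulette_net"] - t["absorbed"] - t["escaped"]) / t["launched"]


def run_monte_carlo(
    tissue: TissueModel,
    fiber: FiberSpec,
    n_photons: int,
    seed: int,
    rr_threshold: float = 1e-4,
    rr_survival: float = 0.1,
) -> FluenceMap:
    """Run the voxel Monte Carlo transport; deterministic per seed.

    Set ``rr_threshold=0`` to disable Russian roulette (exact per-run weight
    conservation at the cost of longer low-weight histories).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    ss = np.random.SeedSequence(seed)
    launch_ss, walk_ss = ss.spawn(2)
    rng = np.random.default_rng(launch_ss)
    n_launch = tissue.layers[0].properties.n
    pos, dirs, weights = launch_photons(fiber, n_photons, rng, n_medium=n_launch)
    # photons on a grid face (tip on a surface) must start inside their voxel
    pos = pos + dirs * (1e-6 * tissue.voxel_pitch_mm)

    absorbed = np.zeros(tissue.label_grid.shape, dtype=np.float64)
    walk_seed = int(walk_ss.generate_state(1)[0] % (2**31 - 1))
    absorbed_total, escaped_total, roulette_net = _transport(
        tissue.label_grid,
        tissue.mu_a,
        tissue.mu_s,
        tissue.g,
        tissue.n,
        tissue.voxel_pitch_mm,
        pos,
        dirs,
        weights,
        absorbed,
        rr_threshold,
        rr_survival,
        walk_seed,
    )
    totals = {
        "launched": float(weights.sum()),
        "absorbed": float(absorbed_total),
        "escaped": float(escaped_total),
        "roulette_net": float(roulette_net),
    }
    return FluenceMap(
        absorbed=absorbed,
        tissue=tissue,
        totals=totals,
        seed=seed,
        n_photons=n_photons,
    )


def illuminated_region(
    fmap: FluenceMap,
    depth_um: float,
    threshold_fraction: float = 0.1,
) -> np.ndarray:
    """Boolean (x, y) mask of the illuminated region at an imaging depth.

    ``depth_um`` is measured from the top of the last (cortex) layer.  A
    voxel belongs to the illuminated region when its fluence reaches
    ``threshold_fraction`` of the plane maximum.  For a purely geometric
    definition see :func:`cone_mask`.
    """
    tissue = fmap.tissue
    z0 = tissue.layer_top_mm(tissue.layers[-1].name)
    iz = int((z0 + depth_um * 1e-3) / tissue.voxel_pitch_mm)
    nz = tissue.label_grid.shape[2]
    if not 0 <= iz < nz:
        raise ValueError(f"imaging depth {depth_um} μm is outside the grid")
    plane = fmap.fluence()[:, :, iz]
    peak = plane.max()
    if peak <= 0:
        raise ValueError("no deposited energy at the requested plane")
    return plane >= threshold_fraction * peak


def cone_mask(
    tissue: TissueModel,
    fiber: FiberSpec,
    depth_um: float,
) -> np.ndarray:
    """Geometric illuminated-region fallback: the fiber's divergence cone.

    The fiber axis is refracted at each layer interface (Snell, z normal);
    the illuminated disc at the imaging plane is centred on the refracted
    axis with radius ``core_radius + path × tan(asin(NA / n_cortex))``.
    """
    n_layers = [l.properties.n for l in tissue.layers]
    z_edges = np.cumsum([0.0] + [l.thickness_mm for l in tissue.layers])
    z0 = tissue.layer_top_mm(tissue.layers[-1].name)
    z_plane = z0 + depth_um * 1e-3

    pos = np.asarray(fiber.tip_position_mm, dtype=float)
    d = fiber.axis.copy()
    path = 0.0
    # walk the axis ray down through the interfaces to the imaging plane
    for i in range(len(n_layers)):
        z_bot = min(z_edges[i + 1], z_plane) if i + 1 < len(z_edges) else z_plane
        z_bot = max(z_bot, pos[2])
        if d[2] <= 0:
            raise ValueError("fiber axis does not point into the tissue")
        if pos[2] < z_bot:
            t = (z_bot - pos[2]) / d[2]
            pos = pos + t * d
            path += t
        if pos[2] >= z_plane - 1e-12:
            break
        n1, n2 = n_layers[i], n_layers[min(i + 1, len(n_layers) - 1)]
        if n1 != n2:
            sin_i = math.sqrt(d[0] ** 2 + d[1] ** 2)
            sin_t = sin_i * n1 / n2
            if sin_t >= 1:
                raise ValueError("fiber axis undergoes total internal reflection")
            if sin_i > 0:
                cos_t = math.sqrt(1 - sin_t**2)
                horiz = d[:2] / sin_i
                d = np.array([horiz[0] * sin_t, horiz[1] * sin_t, cos_t])

    half_angle = math.asin(fiber.numerical_aperture / n_layers[-1])
    radius_mm = 0.5 * fiber.core_diameter_um * 1e-3 + path * math.tan(half_angle)

    nv = tissue.voxels_per_axis
    pitch = tissue.voxel_pitch_mm
    xs = (np.arange(nv) + 0.5) * pitch
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    return (gx - pos[0]) ** 2 + (gy - pos[1]) ** 2 <= radius_mm**2


def bin_neurons(
    positions_um: np.ndarray,
    mask: np.ndarray,
    voxel_pitch_um: float,
) -> list[str]:
    """Label neurons "illuminated" / "weakly_illuminated" via the region mask.

    ``positions_um`` is (N, 2) or (N, 3) with x, y (and optionally depth) in
    the grid frame; the mask should have been computed at the neurons'
    imaging depth.  Out-of-grid neurons are labelled weakly illuminated with
    a warning.
    """
    positions_um = np.atleast_2d(np.asarray(positions_um, dtype=float))
    labels = []
    for p in positions_um:
        ix = int(p[0] // voxel_pitch_um)
        iy = int(p[1] // voxel_pitch_um)
        if not (0 <= ix < mask.shape[0] and 0 <= iy < mask.shape[1]):
            warnings.warn(f"neuron at {tuple(p)} μm lies outside the simulation grid")
            labels.append("weakly_illuminated")
        else:
            labels.append("illuminated" if mask[ix, iy] else "weakly_illuminated")
    return labels
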