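"""Seeded ground-truth specimens with sub-voxel geometry.

Phantoms emulate the biological samples used to demonstrate tri-exciton
imaging: microtubule-like filaments (25 nm diameter, far below the voxel),
solid virus-like microvesicles (50-250 nm), hollow vesicles (0.7-0.9 um)
labeled only at their periphery, and a deterministic "blobs"-style test
pattern with close pairs and hidden substructure.

Sub-voxel structures are rendered analytically: every primitive's sharp
indicator function is convolved with an isotropic Gaussian of sigma = half
the smallest voxel size.  Because convolution with a unit-mass kernel
preserves the integral exactly, the total emitter count of each primitive
equals its labeled volume times the density amplitude regardless of
orientation or grid phase — a property the tests rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rice

__all__ = ["Phantom", "make_filaments", "make_vesicles", "make_test_pattern"]


class PackingError(RuntimeError):
    """Raised when primitives cannot be placed at the requested separation."""


@dataclass
class Phantom:
    """Ground-truth specimen: per-label emitter density plus exact geometry.

    ``density`` maps a label (channel) name to a 3D array indexed [z, y, x]
    in emitters per um^3; ``geometry`` records every primitive with its exact
    continuous-coordinate parameters (nm) so ground truth survives rendering.
    """

    density: dict[str, np.ndarray]
    dx: float
    dy: float
    dz: float
    geometry: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.density.values()}
        if len(shapes) > 1:
            raise ValueError("all density channels must share one shape")
        for name, arr in self.density.items():
            if np.any(arr < 0):
                raise ValueError(f"negative density in channel {name!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.density.values())).shape

    @property
    def label_names(self) -> list[str]:
        return list(self.density)

    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz * 1e-9

    def geometry_json(self) -> str:
        return json.dumps({"dx": self.dx, "dy": self.dy, "dz": self.dz,
                           "geometry": self.geometry}, indent=2)

    @staticmethod
    def geometry_from_json(text: str) -> list[dict]:
        return json.loads(text)["geometry"]


def _voxel_grids(shape, dx, dy, dz):
    nz, ny, nx = shape
    z = np.arange(nz) * dz
    y = np.arange(ny) * dy
    x = np.arange(nx) * dx
    return z, y, x


def _smoothed_ball(r: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Radial profile of a unit ball convolved with an isotropic 3D Gaussian.

    Exact closed form; integrates to (4/3) pi radius^3 over all space.
    """
    r = np.maximum(r, 1e-9)
    a, b = (radius - r) / sigma, (-radius - r) / sigma
    gauss_term = (sigma / (r * np.sqrt(2.0 * np.pi))) * (
        np.exp(-0.5 * ((r + radius) / sigma) ** 2)
        - np.exp(-0.5 * ((r - radius) / sigma) ** 2)
    )
    return norm.cdf(a) - norm.cdf(b) + gauss_term


def _smoothed_disk(d: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Cross-section profile of a cylinder convolved with a 2D Gaussian.

    The disk-Gaussian convolution at perpendicular distance d equals the Rice
    CDF P(|Z + d| <= radius), Z ~ 2D normal(sigma); integrates to pi radius^2.
    """
    b = np.maximum(d, 1e-9) / sigma
    return rice.cdf(radius / sigma, b)


def _z_subsamples(z: np.ndarray, zi: slice, dz: float, sigma: float) -> tuple[np.ndarray, int]:
    """Supersampled z positions for voxels in ``zi``.

    The smoothing scale sigma is set by the (smaller) lateral voxel, so the
    profile varies faster than the axial step; averaging k sub-planes per
    z-voxel keeps the discrete sum an accurate quadrature of the integral.
    """
    # midpoint-rule error for a Gaussian is ~2 exp(-2 pi^2 sigma^2 / h^2);
    # h <= 1.5 sigma keeps it well below 0.1%
    k = max(1, int(np.ceil(dz / (1.5 * sigma))))
    offs = ((np.arange(k) + 0.5) / k - 0.5) * dz
    return (z[zi][:, None] + offs[None, :]).ravel(), k


def _deposit_sphere(density, center, radius, sigma, amplitude, shell_inner,
                    voxels, dz):
    z, y, x = voxels
    cz, cy, cx = center
    margin = radius + 4 * sigma + dz
    zi = slice(*np.searchsorted(z, [cz - margin, cz + margin]))
    yi = slice(*np.searchsorted(y, [cy - margin, cy + margin]))
    xi = slice(*np.searchsorted(x, [cx - margin, cx + margin]))
    zs, k = _z_subsamples(z, zi, dz, sigma)
    r = np.sqrt(
        (zs[:, None, None] - cz) ** 2
        + (y[None, yi, None] - cy) ** 2
        + (x[None, None, xi] - cx) ** 2
    )
    prof = _smoothed_ball(r, radius, sigma)
    if shell_inner is not None:
        prof = prof - _smoothed_ball(r, shell_inner, sigma)
    prof = prof.reshape(-1, k, *prof.shape[1:]).mean(axis=1)
    density[zi, yi, xi] += amplitude * np.clip(prof, 0.0, None)


def _segment_distance(pz, py, px, a, b):
    """Distance from points (pz, py, px broadcastable) to segment a->b (nm)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    t_num = (pz - a[0]) * ab[0] + (py - a[1]) * ab[1] + (px - a[2]) * ab[2]
    t = np.clip(t_num / denom, 0.0, 1.0) if denom > 0 else 0.0
    qz = a[0] + t * ab[0]
    qy = a[1] + t * ab[1]
    qx = a[2] + t * ab[2]
    return np.sqrt((pz - qz) ** 2 + (py - qy) ** 2 + (px - qx) ** 2)


def _deposit_polyline(density, points, radius, sigma, amplitude, voxels, dz):
    """Render a polyline tube; amplitude in emitters/um^3 inside the tube."""
    z, y, x = voxels
    pts = np.asarray(points, float)
    margin = radius + 4 * sigma + dz
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    zi = slice(*np.searchsorted(z, [lo[0], hi[0]]))
    yi = slice(*np.searchsorted(y, [lo[1], hi[1]]))
    xi = slice(*np.searchsorted(x, [lo[2], hi[2]]))
    zs, k = _z_subsamples(z, zi, dz, sigma)
    pz = zs[:, None, None]
    py = y[None, yi, None]
    px = x[None, None, xi]
    dmin = None
    for a, b in zip(pts[:-1], pts[1:]):
        d = _segment_distance(pz, py, px, a, b)
        dmin = d if dmin is None else np.minimum(dmin, d)
    prof = _smoothed_disk(dmin, radius, sigma)
    prof = prof.reshape(-1, k, *prof.shape[1:]).mean(axis=1)
    density[zi, yi, xi] += amplitude * prof


def _bounds_nm(shape, dx, dy, dz):
    nz, ny, nx = shape
    return (nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx


def make_filaments(
    n: int,
    diameter: float = 25.0,
    min_separation: float = 500.0,
    shape: tuple[int, int, int] = (33, 256, 256),
    dx: float = 50.0,
    dy: float = 50.0,
    dz: float = 150.0,
    seed: int | None = 0,
    pair_spacing: float | None = None,
    wiggle: float = 0.0,
    fragmented: bool = False,
    emitters_per_um: float = 2000.0,
    label: str = "QD655",
    angle_spread: float = 0.0,
) -> Phantom:
    """Seeded microtubule-like filament phantom.

    Filaments are straight (optionally gently bent) tubes of the stated
    ``diameter`` (nm) spanning the field of view in-plane.  They share a
    random base direction (plus up to ``angle_spread`` radians of per-filament
    jitter) and are laid out at jittered perpendicular offsets at least
    ``min_separation`` apart, so profiles across one filament are not
    contaminated by its neighbours.  With ``pair_spacing`` set, every
    filament becomes a parallel pair at that center-to-center spacing — the
    classic two-line resolution probe.  ``wiggle`` (nm) adds a sinusoidal
    bend; ``fragmented`` breaks each filament into short segments with gaps,
    mimicking depolymerizing intermediate filaments.
    """
    rng = np.random.default_rng(seed)
    ez, ey, ex = _bounds_nm(shape, dx, dy, dz)
    radius = diameter / 2.0
    sigma = 0.5 * min(dx, dy, dz)
    density = np.zeros(shape)
    geometry: list[dict] = []
    voxels = _voxel_grids(shape, dx, dy, dz)
    border = 4 * sigma + radius + (pair_spacing or 0.0)
    amplitude = emitters_per_um / (np.pi * (radius * 1e-3) ** 2)  # per um^3

    base_angle = rng.uniform(0.0, np.pi)
    half_span = 0.35 * min(ey, ex)
    extra = pair_spacing or 0.0
    if n > 1 and (n - 1) * (min_separation + extra) > 2 * half_span:
        raise PackingError(
            f"cannot fit {n} filaments at min_separation={min_separation} nm "
            f"in a {ey:.0f}x{ex:.0f} nm field"
        )
    if n == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-half_span, half_span, n)
        slack = (offsets[1] - offsets[0]) - (min_separation + extra)
        offsets = offsets + rng.uniform(-slack / 2, slack / 2, size=n)

    cy0, cx0 = ey / 2.0, ex / 2.0
    for k in range(n):
        angle = base_angle + rng.uniform(-angle_spread, angle_spread)
        uy, ux = np.sin(angle), np.cos(angle)
        nyv, nxv = ux, -uy  # in-plane unit normal
        cz = rng.uniform(0.35 * ez, 0.65 * ez) if ez > 0 else 0.0
        ay = cy0 + offsets[k] * nyv
        ax = cx0 + offsets[k] * nxv

        # clip the line to the bordered in-plane box
        ts: list[float] = []
        for comp, anchor, low, high in ((uy, ay, border, ey - border),
                                        (ux, ax, border, ex - border)):
            if abs(comp) > 1e-12:
                ts.append(tuple(sorted([(low - anchor) / comp,
                                        (high - anchor) / comp])))
        t0 = max(lo for lo, _ in ts)
        t1 = min(hi for _, hi in ts)
        if t1 <= t0:
            raise PackingError("filament clipped to zero length; volume too small")
        length = t1 - t0

        pair_offsets = ([0.0] if pair_spacing is None
                        else [-pair_spacing / 2.0, pair_spacing / 2.0])
        for poff in pair_offsets:
            t = np.linspace(t0, t1, 33)
            bend = (wiggle * np.sin(2 * np.pi * (t - t0) / length)
                    if wiggle else np.zeros_like(t))
            off = poff + bend
            py = ay + t * uy + off * nyv
            px = ax + t * ux + off * nxv
            pts = np.column_stack([np.full_like(t, cz), py, px])
            if fragmented:
                keep = rng.random(len(t) - 1) > 0.35
                for i in np.nonzero(keep)[0]:
                    _deposit_polyline(density, pts[i:i + 2], radius, sigma,
                                      amplitude, voxels, dz)
            else:
                _deposit_polyline(density, pts, radius, sigma, amplitude,
                                  voxels, dz)
            tm = 0.5 * (t0 + t1)
            geometry.append({
                "type": "filament",
                "diameter_nm": diameter,
                "z_nm": float(cz),
                "anchor_nm": [float(ay + poff * nyv), float(ax + poff * nxv)],
                "midpoint_nm": [float(ay + tm * uy + poff * nyv),
                                float(ax + tm * ux + poff * nxv)],
                "angle_rad": float(angle),
                "length_nm": float(length),
                "pair_spacing_nm": pair_spacing,
                "fragmented": fragmented,
            })

    return Phantom({label: density}, dx, dy, dz, geometry)


def make_vesicles(
    n_small: int = 20,
    small_range: tuple[float, float] = (50.0, 250.0),
    n_hollow: int = 3,
    hollow_range: tuple[float, float] = (700.0, 900.0),
    shell_thickness: float = 50.0,
    shape: tuple[int, int, int] = (33, 256, 256),
    dx: float = 50.0,
    dy: float = 50.0,
    dz: float = 150.0,
    seed: int | None = 0,
    emitters_per_um3: float = 5000.0,
    label: str = "QD655",
    max_tries: int = 500,
) -> Phantom:
    """Virus-like vesicle phantom.

    Small vesicles are uniformly labeled solid spheres with diameters drawn
    from ``small_range`` (nm); hollow vesicles carry label only in a
    peripheral shell of ``shell_thickness`` (their interior is dark), with
    outer diameters from ``hollow_range``.  Placement is uniform without
    overlap.
    """
    if min(*small_range, *hollow_range) <= 0:
        raise ValueError("diameter ranges must be positive")
    if n_hollow > 0 and shell_thickness >= hollow_range[0] / 2.0:
        raise ValueError("shell_thickness must be smaller than the hollow radius")
    rng = np.random.default_rng(seed)
    ez, ey, ex = _bounds_nm(shape, dx, dy, dz)
    sigma = 0.5 * min(dx, dy, dz)
    density = np.zeros(shape)
    geometry: list[dict] = []
    voxels = _voxel_grids(shape, dx, dy, dz)
    placed: list[tuple[np.ndarray, float]] = []

    specs = [("hollow", rng.uniform(*hollow_range) / 2.0) for _ in range(n_hollow)]
    specs += [("solid", rng.uniform(*small_range) / 2.0) for _ in range(n_small)]

    for kind, radius in specs:
        margin = radius + 4 * sigma
        for attempt in range(max_tries):
            c = np.array([
                rng.uniform(margin, ez - margin) if ez > 2 * margin else ez / 2,
                rng.uniform(margin, ey - margin),
                rng.uniform(margin, ex - margin),
            ])
            if all(np.linalg.norm(c - pc) > radius + pr + 2 * sigma
                   for pc, pr in placed):
                break
        else:
            raise PackingError(
                f"could not place {kind} vesicle r={radius:.0f} nm "
                f"after {max_tries} tries"
            )
        placed.append((c, radius))
        inner = radius - shell_thickness if kind == "hollow" else None
        _deposit_sphere(density, c, radius, sigma, emitters_per_um3, inner,
                        voxels, dz)
        geometry.append({
            "type": f"{kind}_vesicle",
            "diameter_nm": 2.0 * radius,
            "center_nm": c.tolist(),
            "shell_thickness_nm": shell_thickness if kind == "hollow" else None,
        })

    return Phantom({label: density}, dx, dy, dz, geometry)


def make_test_pattern(
    pair_spacings: tuple[float, ...] = (150.0, 250.0, 400.0),
    blob_diameter: float = 600.0,
    substructure_spacing: float = 300.0,
    shape: tuple[int, int, int] = (9, 192, 192),
    dx: float = 50.0,
    dy: float = 50.0,
    dz: float = 150.0,
    label: str = "QD655",
) -> Phantom:
    """Deterministic resolution test pattern (a "blobs"-style target).

    One row of large blobs, each hiding a pair of bright point-like cores at
    ``substructure_spacing``, and one row of small-blob pairs at each entry
    of ``pair_spacings`` — separation and substructure probes for comparing
    PSF models.  No randomness: two calls are bit-identical.
    """
    ez, ey, ex = _bounds_nm(shape, dx, dy, dz)
    sigma = 0.5 * min(dx, dy, dz)
    density = np.zeros(shape)
    geometry: list[dict] = []
    voxels = _voxel_grids(shape, dx, dy, dz)
    cz = ez / 2.0
    n_cols = max(len(pair_spacings), 2)
    xs = np.linspace(0.2 * ex, 0.8 * ex, n_cols)

    # row 1: blobs with hidden two-core substructure
    y1 = 0.3 * ey
    for cx in xs:
        _deposit_sphere(density, (cz, y1, cx), blob_diameter / 2.0, sigma,
                        1e-6, None, voxels, dz)
        for s in (-0.5, 0.5):
            _deposit_sphere(density, (cz, y1, cx + s * substructure_spacing),
                            60.0, sigma, 2e-5, None, voxels, dz)
        geometry.append({"type": "blob_with_cores", "center_nm": [cz, y1, cx],
                         "diameter_nm": blob_diameter,
                         "core_spacing_nm": substructure_spacing})

    # row 2: close pairs at the requested spacings
    y2 = 0.7 * ey
    for cx, spacing in zip(xs, pair_spacings):
        for s in (-0.5, 0.5):
            _deposit_sphere(density, (cz, y2, cx + s * spacing), 80.0, sigma,
                            2e-5, None, voxels, dz)
        geometry.append({"type": "pair_probe", "center_nm": [cz, y2, cx],
                         "spacing_nm": spacing})

    return Phantom({label: density}, dx, dy, dz, geometry)
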