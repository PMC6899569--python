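"""Ground-truthed cortical-bone phantom: hollow cylinder with lacunae and canals.

The phantom emulates a sub-micron CT window of mouse tibial cortex: a
cylindrical annulus of "bone" intensity containing three pore populations —
ellipsoidal osteocyte lacunae (log-normal volumes, optionally bimodal),
elongated near-axial vascular canals modelled as capsules, and sub-resolution
specks that end up in the "noise" class downstream. Pores are placed by
rejection sampling and kept mutually non-adjacent (no shared faces, edges or
corners) so 26-connected labelling of the recovered porosity reproduces the
generator's pore list one-to-one.

When a ``target_composition`` is requested, the canal population is sized from
the *rasterised* lacunar voxel count (the last canal's length is tuned voxel
by voxel) and the speck count from the resulting totals, so the ground-truth
volume partition lands on the requested lacuna/canal/noise percentages to
within a fraction of a percentage point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..volumes import BinaryMask, VolumeImage

__all__ = [
    "LacunaPopulation",
    "CanalPopulation",
    "SpeckPopulation",
    "OsteoidHalo",
    "IntensityModel",
    "TargetComposition",
    "CortexPhantomSpec",
    "GroundTruth",
    "generate_cortex_volume",
]

_ADJ = np.ones((3, 3, 3), dtype=bool)  # 26-neighbourhood


class PlacementError(RuntimeError):
    """Raised when a pore population cannot be placed without overlap."""


@dataclass
class LacunaPopulation:
    """Ellipsoidal lacunae with truncated log-normal volumes (µm³).

    ``log10_volume_mean``/``sd`` parameterise the primary mode on the
    log10-volume scale; an optional second mode makes the population bimodal.
    ``max_elongation`` bounds the long/short semi-axis ratio so that lacunae
    stay below any sensible canal shape criterion.
    """

    count: int = 0
    log10_volume_mean: float = 2.4
    log10_volume_sd: float = 0.18
    min_volume_um3: float = 50.0
    max_volume_um3: float = 1500.0
    max_elongation: float = 2.5
    second_mode_weight: float = 0.0
    second_mode_log10_mean: float = 1.7
    second_mode_log10_sd: float = 0.15


@dataclass
class CanalPopulation:
    """Capsule-shaped (cylinder + hemispherical caps) vascular canals.

    Radius and length are drawn uniformly from the given ranges; orientation
    is predominantly axial with a random tilt up to ``max_tilt_deg``.
    ``count`` is used only when the phantom spec has no target composition.
    """

    count: int = 0
    radius_um: tuple[float, float] = (3.5, 5.0)
    length_um: tuple[float, float] = (90.0, 180.0)
    max_tilt_deg: float = 12.0
    min_trim_length_um: float = 60.0


@dataclass
class SpeckPopulation:
    """Sub-resolution debris pores (fixed 2x2x1 voxel blocks)."""

    count: int = 0
    size_voxels: int = 4


@dataclass
class OsteoidHalo:
    """Optional low-intensity shell of unmineralised matrix around pores."""

    enabled: bool = False
    thickness_um: float = 2.0
    intensity_fraction: float = 0.6


@dataclass
class IntensityModel:
    bone_mean: float = 180.0
    background_mean: float = 30.0
    noise_sigma: float = 5.0
    bit_depth: int = 8


@dataclass
class TargetComposition:
    """Requested ground-truth partition of total pore volume (percent)."""

    lacuna_pct: float
    canal_pct: float
    noise_pct: float

    def __post_init__(self) -> None:
        total = self.lacuna_pct + self.canal_pct + self.noise_pct
        if not (99.0 <= total <= 101.0):
            raise ValueError(f"composition percentages sum to {total}, not ~100")


@dataclass
class CortexPhantomSpec:
    outer_radius_um: float = 120.0
    inner_radius_um: float = 71.0
    length_slices: int = 300
    voxel_size_um: float = 0.65
    lacunae: LacunaPopulation = field(default_factory=LacunaPopulation)
    canals: CanalPopulation = field(default_factory=CanalPopulation)
    specks: SpeckPopulation = field(default_factory=SpeckPopulation)
    osteoid_halo: OsteoidHalo = field(default_factory=OsteoidHalo)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    target_composition: TargetComposition | None = None
    margin_voxels: int = 2
    max_tries_per_pore: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inner_radius_um < self.outer_radius_um:
            raise ValueError("inner_radius_um must be < outer_radius_um")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.length_slices < 1:
            raise ValueError("length_slices must be >= 1")
        if self.intensity.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name, cnt in (("lacunae", self.lacunae.count),
                          ("canals", self.canals.count),
                          ("specks", self.specks.count)):
            if cnt < 0:
                raise ValueError(f"{name}.count must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side truth for one phantom.

    ``pores`` has one row per inserted pore: pore_id, pore_class
    (lacuna/canal/noise), volume_um3 (rasterised voxel count x voxel volume),
    n_voxels and centroid in volume coordinates (µm). ``cortex_mask`` is the
    solid annulus (pores filled); bone = cortex_mask & ~pore voxels.
    """

    pores: pd.DataFrame
    cortex_mask: BinaryMask
    pore_mask: BinaryMask
    voxel_size_um: float

    def class_volume_um3(self, pore_class: str) -> float:
        sub = self.pores[self.pores.pore_class == pore_class]
        return float(sub.volume_um3.sum())

    def composition_pct(self) -> dict[str, float]:
        total = float(self.pores.volume_um3.sum())
        if total == 0:
            return {"lacuna": float("nan"), "canal": float("nan"), "noise": float("nan")}
        return {c: 100.0 * self.class_volume_um3(c) / total
                for c in ("lacuna", "canal", "noise")}


# ---------------------------------------------------------------------------
# geometry helpers

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _ellipsoid_mask(semi_axes_vox: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Boolean mask of a rotated ellipsoid rasterised on its bounding box."""
    half = np.abs(rot * semi_axes_vox).sum(axis=1)  # projection extents
    half = np.ceil(half).astype(int) + 1
    zz, yy, xx = np.mgrid[-half[0]:half[0] + 1,
                          -half[1]:half[1] + 1,
                          -half[2]:half[2] + 1]
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    local = pts @ rot  # rotate into principal frame
    q = (local / semi_axes_vox) ** 2
    return q.sum(axis=-1) <= 1.0


def _capsule_mask(radius_vox: float, length_vox: float,
                  direction: np.ndarray) -> np.ndarray:
    """Capsule (segment of given length, hemispherical caps) on its bbox."""
    d = direction / np.linalg.norm(direction)
    half_seg = 0.5 * length_vox * d
    half = np.ceil(np.abs(half_seg) + radius_vox).astype(int) + 1
    zz, yy, xx = np.mgrid[-half[0]:half[0] + 1,
                          -half[1]:half[1] + 1,
                          -half[2]:half[2] + 1]
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    t = np.clip((pts @ d) / (0.5 * length_vox * 2) * 2, -1.0, 1.0) if length_vox > 0 \
        else np.zeros(pts.shape[:-1])
    closest = t[..., None] * half_seg
    dist = np.linalg.norm(pts - closest, axis=-1)
    return dist <= radius_vox


def _axial_direction(rng: np.random.Generator, max_tilt_deg: float) -> np.ndarray:
    tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
    azim = rng.uniform(0.0, 2 * np.pi)
    return np.array([np.cos(tilt),
                     np.sin(tilt) * np.cos(azim),
                     np.sin(tilt) * np.sin(azim)])


# ---------------------------------------------------------------------------
# placement machinery

class _Placer:
    """Tracks occupied voxels and places pore masks without 26-adjacency."""

    def __init__(self, spec: CortexPhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        vs = spec.voxel_size_um
        self.nz = spec.length_slices
        r_out_vox = spec.outer_radius_um / vs
        self.nxy = int(np.ceil(2 * r_out_vox)) + 8
        self.center = (self.nxy - 1) / 2.0
        yy, xx = np.mgrid[0:self.nxy, 0:self.nxy]
        self.rho_um = np.hypot(yy - self.center, xx - self.center) * vs
        self.annulus2d = (self.rho_um <= spec.outer_radius_um) & \
                         (self.rho_um >= spec.inner_radius_um)
        # radial band where pore voxels may live (margin inside both surfaces)
        m = spec.margin_voxels * vs
        self.safe2d = (self.rho_um <= spec.outer_radius_um - m) & \
                      (self.rho_um >= spec.inner_radius_um + m)
        self.pore_mask = np.zeros((self.nz, self.nxy, self.nxy), dtype=bool)
        self.records: list[dict] = []

    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.nxy, self.nxy)

    def try_place(self, local: np.ndarray, pore_class: str) -> bool:
        """Attempt to place a local pore mask at a random valid location."""
        spec, rng = self.spec, self.rng
        dz, dy, dx = local.shape
        zmargin = spec.margin_voxels
        if dz > self.nz - 2 * zmargin or dy > self.nxy or dx > self.nxy:
            return False
        z0 = rng.integers(zmargin, self.nz - zmargin - dz + 1)
        y0 = rng.integers(0, self.nxy - dy + 1)
        x0 = rng.integers(0, self.nxy - dx + 1)
        sl = (slice(z0, z0 + dz), slice(y0, y0 + dy), slice(x0, x0 + dx))
        # all pore voxels must sit in the safe annulus band
        if not self.safe2d[sl[1], sl[2]][local.any(axis=0)].all():
            return False
        # no 26-adjacency with existing pores: dilate candidate by one voxel
        grown = ndimage.binary_dilation(np.pad(local, 1), structure=_ADJ)
        gz0, gy0, gx0 = max(z0 - 1, 0), max(y0 - 1, 0), max(x0 - 1, 0)
        gz1 = min(z0 + dz + 1, self.nz)
        gy1 = min(y0 + dy + 1, self.nxy)
        gx1 = min(x0 + dx + 1, self.nxy)
        gsl = (slice(gz0, gz1), slice(gy0, gy1), slice(gx0, gx1))
        glocal = grown[gz0 - (z0 - 1):gz0 - (z0 - 1) + (gz1 - gz0),
                       gy0 - (y0 - 1):gy0 - (y0 - 1) + (gy1 - gy0),
                       gx0 - (x0 - 1):gx0 - (x0 - 1) + (gx1 - gx0)]
        if (self.pore_mask[gsl] & glocal).any():
            return False
        self.pore_mask[sl] |= local
        n_vox = int(local.sum())
        zc, yc, xc = ndimage.center_of_mass(local)
        vs = self.spec.voxel_size_um
        self.records.append({
            "pore_id": len(self.records) + 1,
            "pore_class": pore_class,
            "n_voxels": n_vox,
            "volume_um3": n_vox * vs ** 3,
            "centroid_z_um": (z0 + zc) * vs,
            "centroid_y_um": (y0 + yc) * vs,
            "centroid_x_um": (x0 + xc) * vs,
        })
        return True

    def place_or_fail(self, local: np.ndarray, pore_class: str, what: str) -> None:
        for _ in range(self.spec.max_tries_per_pore):
            if self.try_place(local, pore_class):
                return
        raise PlacementError(
            f"could not place a {what} after {self.spec.max_tries_per_pore} tries; "
            f"the {what} population is too dense for this cortex")


# ---------------------------------------------------------------------------
# population sampling

def _sample_lacuna_volume(pop: LacunaPopulation, rng: np.random.Generator) -> float:
    for _ in range(1000):
        if pop.second_mode_weight > 0 and rng.uniform() < pop.second_mode_weight:
            v = 10 ** rng.normal(pop.second_mode_log10_mean, pop.second_mode_log10_sd)
        else:
            v = 10 ** rng.normal(pop.log10_volume_mean, pop.log10_volume_sd)
        if pop.min_volume_um3 <= v <= pop.max_volume_um3:
            return float(v)
    raise ValueError("lacuna volume truncation bounds reject all draws")


def _lacuna_mask(pop: LacunaPopulation, vs: float,
                 rng: np.random.Generator) -> np.ndarray:
    v = _sample_lacuna_volume(pop, rng)
    r1 = rng.uniform(1.0, pop.max_elongation)          # a/c
    r2 = rng.uniform(1.0, r1)                          # b/c
    c = (3.0 * v / (4.0 * np.pi * r1 * r2)) ** (1.0 / 3.0)
    semi_um = np.array([r1 * c, r2 * c, c])
    return _ellipsoid_mask(semi_um / vs, _random_rotation(rng))


def _canal_mask(radius_um: float, length_um: float, pop: CanalPopulation,
                vs: float, rng: np.random.Generator) -> np.ndarray:
    d = _axial_direction(rng, pop.max_tilt_deg)
    return _capsule_mask(radius_um / vs, length_um / vs, d)


def _speck_mask(size_voxels: int) -> np.ndarray:
    # small compact block; 4 voxels -> 1x2x2
    if size_voxels == 4:
        return np.ones((1, 2, 2), dtype=bool)
    side = max(1, int(round(size_voxels ** (1 / 3))))
    m = np.ones((side, side, side), dtype=bool)
    return m


def _place_canals_to_target(placer: _Placer, target_vox: int) -> None:
    """Add canals until their rasterised voxel total hits ``target_vox``.

    All canals but the last are drawn from the population ranges; the last
    canal's length is tuned (at the minimum radius) so the accumulated count
    lands within about half a cross-section of the target.
    """
    spec, rng = placer.spec, placer.rng
    pop = spec.canals
    vs = spec.voxel_size_um
    vox_um3 = vs ** 3
    zspan_um = (placer.nz - 2 * spec.margin_voxels) * vs

    def canal_vox_estimate(r_um: float, l_um: float) -> float:
        return (np.pi * r_um ** 2 * l_um + 4.0 / 3.0 * np.pi * r_um ** 3) / vox_um3

    def max_len(r_um: float) -> float:
        # longest segment that still fits axially (with caps and slack)
        return max(pop.min_trim_length_um, 0.9 * zspan_um - 2.0 * r_um)

    min_r = pop.radius_um[0]
    acc = 0
    while target_vox - acc > 0:
        remaining = target_vox - acc
        r = rng.uniform(*pop.radius_um)
        l = min(rng.uniform(*pop.length_um), max_len(r))
        finishing = False
        if canal_vox_estimate(r, l) > remaining:
            # last canal: tune length at the minimum radius
            r = min_r
            l_ideal = (remaining * vox_um3
                       - 4.0 / 3.0 * np.pi * r ** 3) / (np.pi * r ** 2)
            l = float(np.clip(l_ideal, pop.min_trim_length_um, max_len(r)))
            finishing = l_ideal <= max_len(r)
        before = int(placer.pore_mask.sum())
        if finishing:
            d = _axial_direction(rng, pop.max_tilt_deg)
            best, best_err = None, None
            for dl_um in np.arange(-4.0, 4.5, 1.0) * vs:
                li = float(np.clip(l + dl_um, pop.min_trim_length_um, max_len(r)))
                m = _capsule_mask(r / vs, li / vs, d)
                err = abs(int(m.sum()) - remaining)
                if best_err is None or err < best_err:
                    best, best_err = m, err
            placer.place_or_fail(best, "canal", "canal")
        else:
            placer.place_or_fail(_canal_mask(r, l, pop, vs, rng),
                                 "canal", "canal")
        acc += int(placer.pore_mask.sum()) - before
        if finishing:
            return


def _top_up_lacunae(placer: _Placer, deficit_vox: int) -> None:
    """Add lacunae totalling ``deficit_vox`` voxels.

    Used after canal placement to restore the requested lacuna/canal volume
    ratio. Top-ups are drawn from the same lacuna population (so the volume
    distribution is not distorted); the final one is sized to the remaining
    deficit, giving granularity of half the population minimum.
    """
    spec, rng = placer.spec, placer.rng
    pop = spec.lacunae
    vs = spec.voxel_size_um
    vox_um3 = vs ** 3
    min_vox = pop.min_volume_um3 / vox_um3
    while deficit_vox > 0.5 * min_vox:
        v = _sample_lacuna_volume(pop, rng)
        if v / vox_um3 > deficit_vox:
            v = max(pop.min_volume_um3, deficit_vox * vox_um3)
        ratio = rng.uniform(1.0, min(1.5, pop.max_elongation))
        c = (3.0 * v / (4.0 * np.pi * ratio)) ** (1.0 / 3.0)
        local = _ellipsoid_mask(np.array([ratio * c, c, c]) / vs,
                                _random_rotation(rng))
        before = int(placer.pore_mask.sum())
        placer.place_or_fail(local, "lacuna", "lacuna")
        deficit_vox -= int(placer.pore_mask.sum()) - before


# ---------------------------------------------------------------------------

def generate_cortex_volume(spec: CortexPhantomSpec) -> tuple[VolumeImage, GroundTruth]:
    """Rasterise a cortex phantom and return the image plus its ground truth.

    Identical specs (including seed) yield bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_um
    placer = _Placer(spec, rng)

    for _ in range(spec.lacunae.count):
        placer.place_or_fail(_lacuna_mask(spec.lacunae, vs, rng), "lacuna", "lacuna")

    if spec.target_composition is not None:
        tc = spec.target_composition
        lac_vox = int(placer.pore_mask.sum())
        if tc.lacuna_pct > 0 and tc.canal_pct > 0:
            target_canal_vox = int(round(lac_vox * tc.canal_pct / tc.lacuna_pct))
            _place_canals_to_target(placer, target_canal_vox)
            canal_vox = int(placer.pore_mask.sum()) - lac_vox
            # canals are coarse and may overshoot; top up lacunae to restore
            # the requested volume ratio exactly
            lac_target = int(round(canal_vox * tc.lacuna_pct / tc.canal_pct))
            _top_up_lacunae(placer, lac_target - lac_vox)
            lac_vox = int(placer.pore_mask.sum()) - canal_vox
        canal_vox = int(placer.pore_mask.sum()) - lac_vox
        if tc.noise_pct > 0:
            known_pct = tc.lacuna_pct + tc.canal_pct
            total_vox = (lac_vox + canal_vox) / (known_pct / 100.0)
            speck_vox = total_vox * tc.noise_pct / 100.0
            local = _speck_mask(spec.specks.size_voxels)
            n_specks = int(round(speck_vox / local.sum()))
            for _ in range(n_specks):
                placer.place_or_fail(local, "noise", "speck")
    else:
        for _ in range(spec.canals.count):
            r = rng.uniform(*spec.canals.radius_um)
            l = rng.uniform(*spec.canals.length_um)
            placer.place_or_fail(_canal_mask(r, l, spec.canals, vs, rng),
                                 "canal", "canal")
        local = _speck_mask(spec.specks.size_voxels)
        for _ in range(spec.specks.count):
            placer.place_or_fail(local, "noise", "speck")

    # --- intensity model ------------------------------------------------
    cortex3d = np.broadcast_to(placer.annulus2d,
                               placer.shape()).copy()
    bone = cortex3d & ~placer.pore_mask
    inten = spec.intensity
    img = np.full(placer.shape(), inten.background_mean, dtype=np.float64)
    img[bone] = inten.bone_mean
    if spec.osteoid_halo.enabled and placer.pore_mask.any():
        halo_r = max(1, int(round(spec.osteoid_halo.thickness_um / vs)))
        halo = ndimage.binary_dilation(placer.pore_mask, structure=_ADJ,
                                       iterations=halo_r) & bone
        img[halo] = spec.osteoid_halo.intensity_fraction * inten.bone_mean
    if inten.noise_sigma > 0:
        img += rng.normal(0.0, inten.noise_sigma, size=img.shape)
    top = 2 ** inten.bit_depth - 1
    dtype = np.uint8 if inten.bit_depth == 8 else np.uint16
    img = np.clip(np.rint(img), 0, top).astype(dtype)

    pores = pd.DataFrame(placer.records,
                         columns=["pore_id", "pore_class", "n_voxels",
                                  "volume_um3", "centroid_z_um",
                                  "centroid_y_um", "centroid_x_um"])
    truth = GroundTruth(
        pores=pores,
        cortex_mask=BinaryMask(cortex3d, vs, label="cortex_solid"),
        pore_mask=BinaryMask(placer.pore_mask, vs, label="porosity"),
        voxel_size_um=vs,
    )
    return VolumeImage(img, vs), truth
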