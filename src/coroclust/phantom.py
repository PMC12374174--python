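"""Synthetic coronary vessel phantoms.

Generates contrast-enhanced CT volumes with a tapering tubular vessel,
a binary "segmentation" mask, ground-truth lesion annotations, and a
surrogate fractional-flow-reserve (FFR) record per lesion, so every
pipeline stage can be exercised and scored without patient data.

What the phantom emulates
-------------------------
* a single coronary branch whose caliber decreases proximal → distal;
  the baseline taper is terraced (smooth plateaus joined by smoothstep
  ramps), mimicking the discrete caliber drops at branch ostia and
  giving the width-graded cluster structure real arteries show;
* contrast-enhanced lumen (default 350 ± 40 HU) against soft tissue
  background (40 ± 20 HU);
* calcified plaque as a high-attenuation shell (700 ± 100 HU) between
  the narrowed lumen and the healthy vessel wall — included in the
  vessel mask, since a lumen segmentation captures bright calcium;
* soft (lipid/fibrotic) plaque as a low-attenuation annulus
  (100 ± 30 HU) — painted in the CT but *excluded* from the mask, so the
  segmented vessel narrows at soft lesions exactly the way a real
  lumen segmentation does;
* stenoses of at least 30% diameter reduction (the clinical inclusion
  threshold), applied as a cosine-tapered notch in the radius profile;
* a surrogate FFR per lesion, ``clamp(1 - 0.45 s^2, 0.30, 1.00) +
  N(0, 0.02)`` with ``s`` the diameter-stenosis fraction, tuned so the
  0.80 significance threshold is crossed near s ≈ 0.67.  The mapping is
  a stand-in for invasive pressure measurements and exists only to
  exercise the hemodynamic-concordance evaluation path.

Everything is deterministic given ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .volume_io import CTVolume, VesselMask

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "TruthLesion",
    "LesionAnnotation",
    "FFRRecord",
    "PhantomCase",
    "RadiusProfile",
    "make_radius_profile",
    "generate_phantom",
    "ffr_surrogate",
    "default_healthy_spec",
    "default_diseased_spec",
    "default_adjacent_lesion_spec",
]

LESION_TYPES = ("calcified", "soft", "mixed")

DEFAULT_HU_PARAMS = {
    "lumen": (350.0, 40.0),       # contrast-enhanced blood
    "background": (40.0, 20.0),   # soft tissue
    "calcified": (900.0, 150.0),  # dense calcium
    "soft": (100.0, 30.0),        # lipid/fibrotic plaque
}


@dataclass
class LesionSpec:
    """One planted lesion along the vessel centerline."""

    type: str
    center_fraction: float
    length_mm: float
    diameter_stenosis_fraction: float
    calcified_fraction: float = 0.5  # used for mixed lesions only

    def __post_init__(self) -> None:
        if self.type not in LESION_TYPES:
            raise ValueError(f"lesion type must be one of {LESION_TYPES}")
        if not 0.0 < self.center_fraction < 1.0:
            raise ValueError("center_fraction must be in (0, 1)")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be > 0")
        if not 0.3 <= self.diameter_stenosis_fraction <= 0.9:
            raise ValueError(
                "diameter_stenosis_fraction must be in [0.3, 0.9] "
                "(>=30% stenosis is the inclusion criterion)"
            )
        if not 0.0 < self.calcified_fraction < 1.0:
            raise ValueError("calcified_fraction must be in (0, 1)")


def _default_control_points(grid_shape, spacing) -> list[tuple[float, float, float]]:
    """A gently curved centerline through the grid along z (in mm)."""
    nx, ny, nz = grid_shape
    sx, sy, sz = spacing
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    # span the full z extent: the artery crosses the field of view, so the
    # distance transform sees a lateral wall (not an end cap) everywhere
    zs = np.linspace(0.0, nz - 1, 5) * sz
    amp = min(3.0, 0.1 * nx * sx)
    xs = cx + amp * np.sin(np.linspace(0.0, np.pi, 5))
    return [(float(x), float(cy), float(z)) for x, z in zip(xs, zs)]


@dataclass
class PhantomSpec:
    """Full description of a synthetic vessel case."""

    grid_shape: tuple[int, int, int] = (96, 96, 160)
    spacing: tuple[float, float, float] = (0.43, 0.43, 0.5)
    centerline_control_points: list | None = None
    radius_proximal: float = 2.0
    radius_distal: float = 1.0
    n_width_zones: int = 3
    lesions: list[LesionSpec] = field(default_factory=list)
    hu_params: dict = field(default_factory=lambda: dict(DEFAULT_HU_PARAMS))
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_distal <= 0 or self.radius_proximal < self.radius_distal:
            raise ValueError("need radius_proximal >= radius_distal > 0")
        if self.noise_sd < 0 or any(sd < 0 for _, sd in self.hu_params.values()):
            raise ValueError("standard deviations must be >= 0")
        if self.n_width_zones < 1:
            raise ValueError("n_width_zones must be >= 1")
        if self.centerline_control_points is None:
            self.centerline_control_points = _default_control_points(
                self.grid_shape, self.spacing
            )


@dataclass
class TruthLesion:
    id: int
    type: str
    voxels: np.ndarray          # (n, 3) int voxel coordinates
    interval_mm: tuple[float, float]  # centerline arc-length interval


@dataclass
class LesionAnnotation:
    lesions: list[TruthLesion]
    centerline_length_mm: float

    def __post_init__(self) -> None:
        seen: set[tuple[int, int, int]] = set()
        for les in self.lesions:
            vox = {tuple(v) for v in np.asarray(les.voxels)}
            if vox & seen:
                raise ValueError("truth lesion voxel sets must be pairwise disjoint")
            seen |= vox


@dataclass
class FFRRecord:
    lesion_id: int
    ffr: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ffr <= 1.0:
            raise ValueError("FFR must be in (0, 1]")


@dataclass
class PhantomCase:
    ct: CTVolume
    mask: VesselMask
    truth: LesionAnnotation
    ffr: list[FFRRecord]
    ideal_radius_profile: "RadiusProfile"
    proximal_point_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


class RadiusProfile:
    """Lumen radius as a function of centerline arc length (mm).

    ``baseline(s)`` is the healthy caliber; ``lumen(s)`` additionally
    applies the cosine-tapered stenosis notch of every lesion.
    """

    def __init__(self, length_mm: float, r_prox: float, r_dist: float,
                 n_zones: int, lesions: list[LesionSpec]):
        self.length_mm = float(length_mm)
        self.r_prox = float(r_prox)
        self.r_dist = float(r_dist)
        self.n_zones = int(n_zones)
        self.lesions = list(lesions)
        windows = []
        for les in lesions:
            c = les.center_fraction * length_mm
            windows.append((c - les.length_mm / 2.0, c + les.length_mm / 2.0, les))
        windows.sort(key=lambda w: w[0])
        for (a0, b0, _), (a1, b1, _) in zip(windows, windows[1:]):
            if b0 > a1:
                raise ValueError(
                    f"lesion windows overlap: [{a0:.1f},{b0:.1f}] and "
                    f"[{a1:.1f},{b1:.1f}] mm"
                )
        self.windows = windows

    def baseline(self, s) -> np.ndarray:
        """Terraced smooth monotone nonincreasing caliber."""
        s = np.asarray(s, dtype=np.float64)
        f = np.clip(s / self.length_mm, 0.0, 1.0)
        if self.n_zones == 1:
            frac = f
        else:
            # zone i plateaus at frac = i/(n-1); a smoothstep ramp in the
            # zone's last 30% climbs to the next plateau
            n = self.n_zones
            zone = np.minimum((f * n).astype(int), n - 1)
            local = f * n - zone            # position within the zone in [0,1)
            ramp = 0.3
            t = np.clip((local - (1.0 - ramp)) / ramp, 0.0, 1.0)
            frac = np.clip((zone + _smoothstep(t)) / (n - 1), 0.0, 1.0)
        return self.r_prox + (self.r_dist - self.r_prox) * frac

    def stenosis_factor(self, s) -> np.ndarray:
        """Multiplicative diameter factor from all lesion notches."""
        s = np.asarray(s, dtype=np.float64)
        factor = np.ones_like(s)
        for a, b, les in self.windows:
            inside = (s >= a) & (s <= b)
            if not np.any(inside):
                continue
            # raised-cosine taper: full stenosis at window centre, 0 at edges
            u = (s[inside] - a) / (b - a)
            taper = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
            factor[inside] = np.minimum(
                factor[inside], 1.0 - les.diameter_stenosis_fraction * taper
            )
        return factor

    def lumen(self, s) -> np.ndarray:
        return self.baseline(s) * self.stenosis_factor(s)

    def lesion_at(self, s: np.ndarray) -> np.ndarray:
        """Index of the lesion window covering each arc length (-1 = none)."""
        s = np.asarray(s, dtype=np.float64)
        out = np.full(s.shape, -1, dtype=np.int32)
        for i, (a, b, _) in enumerate(self.windows):
            out[(s >= a) & (s <= b)] = i
        return out


def _centerline_samples(spec: PhantomSpec, step_mm: float = 0.2):
    """Dense arc-length-parameterized samples of the centerline spline."""
    pts = np.asarray(spec.centerline_control_points, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 centerline control points")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spline = CubicSpline(chord, pts, axis=0)
    # oversample, then reparameterize by arc length
    tt = np.linspace(0.0, chord[-1], max(1000, int(chord[-1] / 0.05)))
    xyz = spline(tt)
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    s_out = np.arange(0.0, total + step_mm / 2.0, step_mm)
    samples = np.column_stack([np.interp(s_out, arc, xyz[:, k]) for k in range(3)])
    return samples, s_out, total


def make_radius_profile(spec: PhantomSpec) -> RadiusProfile:
    """Build the (baseline + lesion notch) radius profile for a spec."""
    _, _, total = _centerline_samples(spec)
    return RadiusProfile(
        length_mm=total,
        r_prox=spec.radius_proximal,
        r_dist=spec.radius_distal,
        n_zones=spec.n_width_zones,
        lesions=spec.lesions,
    )


def ffr_surrogate(stenosis_fraction: float, rng: np.random.Generator | None = None) -> float:
    """Surrogate FFR for a lesion of diameter-stenosis fraction ``s``.

    Noise-free value ``clamp(1 - 0.45 s^2, 0.30, 1.00)``; crosses the
    0.80 significance threshold between s = 0.65 and s = 0.70.
    """
    base = float(np.clip(1.0 - 0.45 * stenosis_fraction ** 2, 0.30, 1.00))
    if rng is not None:
        base += float(rng.normal(0.0, 0.02))
    return float(np.clip(base, 1e-6, 1.0))


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize the vessel tube and produce CT + mask + truth + FFR."""
    rng = np.random.default_rng(spec.seed)
    samples, s_arc, total = _centerline_samples(spec)
    profile = RadiusProfile(total, spec.radius_proximal, spec.radius_distal,
                            spec.n_width_zones, spec.lesions)

    spacing = np.asarray(spec.spacing, dtype=np.float64)
    shape = tuple(int(n) for n in spec.grid_shape)
    extent = (np.asarray(shape) - 0.5) * spacing

    # radial containment is checked in x/y only: the vessel is allowed to
    # reach the first/last z slice, like an artery crossing the field of view
    r_base_samples = profile.baseline(s_arc)
    lo = samples[:, :2] - r_base_samples[:, None]
    hi = samples[:, :2] + r_base_samples[:, None]
    out_z = (samples[:, 2] < -0.5 * spacing[2]) | (samples[:, 2] > extent[2])
    bad_pt = ((lo < -0.5 * spacing[None, :2])
              | (hi > extent[None, :2] + 0.5 * spacing[None, :2])).any(axis=1) | out_z
    if bad_pt.any():
        bad = int(np.argmax(bad_pt))
        raise ValueError(
            f"tube exits the grid near centerline point {tuple(samples[bad])} mm"
        )

    # distance of every voxel center to the nearest centerline sample
    grid = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    vox_mm = grid.reshape(-1, 3) * spacing
    tree = cKDTree(samples)
    d_perp, nearest = tree.query(vox_mm, k=1, workers=-1)
    s_vox = s_arc[nearest]

    r_lumen = profile.lumen(s_vox)
    r_outer = profile.baseline(s_vox)
    lesion_idx = profile.lesion_at(s_vox)

    lumen = d_perp <= r_lumen
    annulus = (~lumen) & (d_perp <= r_outer) & (lesion_idx >= 0)

    # split annulus voxels into calcified / soft tissue per lesion
    calc_annulus = np.zeros_like(annulus)
    soft_annulus = np.zeros_like(annulus)
    for i, (a, b, les) in enumerate(profile.windows):
        in_lesion = annulus & (lesion_idx == i)
        if les.type == "calcified":
            calc_annulus |= in_lesion
        elif les.type == "soft":
            soft_annulus |= in_lesion
        else:  # mixed: proximal calcified_fraction of the window is calcium
            split = a + les.calcified_fraction * (b - a)
            calc_annulus |= in_lesion & (s_vox <= split)
            soft_annulus |= in_lesion & (s_vox > split)

    hu = spec.hu_params
    ct_flat = rng.normal(hu["background"][0], hu["background"][1], size=vox_mm.shape[0])
    for tissue, sel in (("lumen", lumen), ("calcified", calc_annulus),
                        ("soft", soft_annulus)):
        n = int(sel.sum())
        if n:
            ct_flat[sel] = rng.normal(hu[tissue][0], hu[tissue][1], size=n)
    if spec.noise_sd > 0:
        ct_flat += rng.normal(0.0, spec.noise_sd, size=ct_flat.shape)

    # the mask emulates a lumen segmentation: bright calcium is captured,
    # low-attenuation soft plaque is not, so the vessel narrows there
    mask_flat = lumen | calc_annulus

    ct = CTVolume(data=ct_flat.reshape(shape), spacing=spec.spacing)
    mask = VesselMask(data=mask_flat.reshape(shape).astype(np.uint8),
                      spacing=spec.spacing)

    # truth annotation; soft truth voxels trimmed to within 1 voxel of mask
    mask_dilated = ndimage.binary_dilation(
        mask.data.astype(bool), structure=np.ones((3, 3, 3), bool)
    ).reshape(-1)
    lesions: list[TruthLesion] = []
    ffr_records: list[FFRRecord] = []
    for i, (a, b, les) in enumerate(profile.windows):
        in_lesion = lesion_idx == i
        vox_sel = (calc_annulus & in_lesion) | (
            soft_annulus & in_lesion & mask_dilated
        )
        coords = grid.reshape(-1, 3)[vox_sel]
        lesions.append(TruthLesion(id=i, type=les.type, voxels=coords,
                                   interval_mm=(float(a), float(b))))
        ffr_records.append(FFRRecord(
            lesion_id=i,
            ffr=ffr_surrogate(les.diameter_stenosis_fraction, rng),
        ))

    truth = LesionAnnotation(lesions=lesions, centerline_length_mm=float(total))
    return PhantomCase(
        ct=ct, mask=mask, truth=truth, ffr=ffr_records,
        ideal_radius_profile=profile,
        proximal_point_mm=tuple(float(v) for v in samples[0]),
    )


# ---------------------------------------------------------------------------
# Canonical desk-scale study specs
# ---------------------------------------------------------------------------

def default_healthy_spec(seed: int = 0) -> PhantomSpec:
    """Tapering vessel with no lesions."""
    return PhantomSpec(seed=seed)


def default_diseased_spec(seed: int = 0) -> PhantomSpec:
    """One calcified and one (distant) soft lesion — the two-lesion study case.

    The calcified lesion sits on the proximal (2.0 mm) plateau with a
    moderate 45% stenosis; the soft lesion sits on the middle (1.5 mm)
    plateau with a 60% stenosis, strong enough to produce the width
    deviation a lumen segmentation shows at lipid plaque.
    """
    return PhantomSpec(
        seed=seed,
        lesions=[
            LesionSpec("calcified", center_fraction=0.18, length_mm=8.0,
                       diameter_stenosis_fraction=0.45),
            LesionSpec("soft", center_fraction=0.50, length_mm=8.0,
                       diameter_stenosis_fraction=0.60),
        ],
    )


def default_adjacent_lesion_spec(seed: int = 0) -> PhantomSpec:
    """A mixed lesion: calcified and soft components back to back.

    Diffuse mixed plaques are commonly this long; the 16 mm window with a
    60% stenosis gives the soft component enough narrowed centerline for
    its own candidate, which then merges with the calcified component.
    """
    return PhantomSpec(
        seed=seed,
        lesions=[
            LesionSpec("mixed", center_fraction=0.30, length_mm=16.0,
                       diameter_stenosis_fraction=0.60, calcified_fraction=0.4),
        ],
    )
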