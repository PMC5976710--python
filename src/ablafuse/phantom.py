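"""Synthetic paired CECT / CE-CBCT phantom with full ground truth.

No patient volumes are available for this kind of intraprocedural study, so
every registration and assessment claim is exercised against a digital
liver phantom: an ellipsoidal liver (arterial-phase parenchyma ~100 HU)
containing a branching vessel tree (~180 HU, with landmarkable
bifurcations) and an enhancing tumor sphere (~160 HU) on a ~-100 HU
background.  The CBCT half applies a known deformation (rigid + affine +
smooth B-spline field), inserts a hypodense coagulation zone (~40 HU),
resamples to a coarser tumor-centred field of view and degrades the image
(multiplicative shading, heavier noise) -- mimicking the lower resolution,
truncated FOV and non-uniform intensity of intraprocedural cone-beam CT.

Default geometry is a scaled-down liver: the CT grid keeps the clinical
slice spacing (2.5 mm) with twice the clinical mean in-plane pixel
(2 x 0.68 = 1.36 mm) and the CBCT grid twice its clinical mean in-plane
pixel (2 x 1.18 = 2.36 mm), preserving the CBCT/CT resolution ratio while
keeping registration experiments at ~96^3 tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import Mask
from .registration import LandmarkPairSet
from .transforms import (AffineTransform, BSplineTransform, RigidTransform,
                         TransformChain, invert_chain_at_points)
from .volume import GridSpec, Volume

__all__ = ["PhantomConfig", "PhantomGroundTruth", "Scenario", "make_phantom",
           "degrade_to_cbct", "scenario_suite"]


@dataclass
class PhantomConfig:
    # CT (moving) grid
    ct_shape: tuple = (96, 96, 52)
    ct_spacing: tuple = (1.36, 1.36, 2.5)
    # CBCT (fixed) grid, tumor-centred
    cbct_shape: tuple = (48, 48, 48)
    cbct_spacing: tuple = (2.36, 2.36, 2.36)
    # anatomy (world mm; liver centred at the origin)
    liver_radii_mm: tuple = (55.0, 45.0, 50.0)
    tumor_center_mm: tuple = (18.0, -18.0, -5.0)
    tumor_radius_mm: float = 8.0
    ablation_radius_mm: float = 13.0
    ablation_offset_mm: tuple = (0.0, 0.0, 0.0)
    #: when set, the ablation centre is slid along +x until the ground-truth
    #: residual fraction best matches this value (overrides the offset)
    ablation_target_residual_fraction: float | None = None
    vessel_radius_mm: float = 3.0
    # intensities (HU); only the ordering vessel > tumor > parenchyma >
    # necrosis > background matters to the algorithms.  Contrasts follow
    # arterial-phase enhancement (opacified vessels well above parenchyma).
    hu_background: float = -100.0
    hu_parenchyma: float = 100.0
    hu_tumor: float = 170.0
    hu_vessel: float = 250.0
    hu_ablation: float = 40.0
    # smooth parenchymal heterogeneity carried along with the anatomy (real
    # livers are not uniform; this texture is what intensity metrics lock
    # onto between vessels)
    texture_amplitude_hu: float = 25.0
    texture_scale_mm: float = 18.0
    # true deformation (fixed -> moving): ~5 mm translation, ~5 deg rotation
    rigid_translation_mm: tuple = (4.0, -2.0, 2.3)
    rigid_rotation_deg: tuple = (3.0, -3.0, 2.0)
    affine_scale: float = 1.03
    nonrigid_amplitude_mm: float = 8.0
    nonrigid_scale_mm: float = 45.0
    # degradation
    ct_noise_sd: float = 10.0
    cbct_noise_sd: float = 25.0
    shading_amplitude: float = 0.15
    seed: int = 0

    @classmethod
    def coarse(cls, **overrides) -> "PhantomConfig":
        """Smaller, faster variant used by the end-to-end scenario suite."""
        base = cls(
            ct_shape=(64, 64, 40), ct_spacing=(2.0, 2.0, 3.0),
            cbct_shape=(40, 40, 36), cbct_spacing=(3.2, 3.2, 3.2),
            rigid_translation_mm=(3.0, -2.0, 2.0),
            rigid_rotation_deg=(2.0, -2.0, 2.0),
            affine_scale=1.02,
            nonrigid_amplitude_mm=5.0,
        )
        return replace(base, **overrides)

    def validate(self):
        if min(self.ct_spacing) <= 0 or min(self.cbct_spacing) <= 0:
            raise ValueError("spacings must be strictly positive")
        if self.nonrigid_amplitude_mm < 0:
            raise ValueError("nonrigid amplitude must be >= 0")


@dataclass
class PhantomGroundTruth:
    """Everything a recovery experiment needs: the exact fixed->moving
    chain, masks in both spaces, paired landmarks (the first
    ``n_bifurcations`` lie at vessel bifurcations and seed the rigid step;
    the rest are held out for target-registration-error scoring)."""

    config: PhantomConfig
    chain: TransformChain = None
    masks: dict = field(default_factory=dict)
    landmarks: LandmarkPairSet = None
    landmarks_moving: np.ndarray = None
    n_bifurcations: int = 0
    tumor_center_moving: np.ndarray = None
    tumor_center_fixed: np.ndarray = None
    ablation_center_fixed: np.ndarray = None

    def evaluation_grid(self, spacing_mm: float = 1.18) -> "GridSpec":
        """Fine isotropic grid (default: the clinical CBCT in-plane pixel)
        centred on the fixed-space tumor, for digitization-free overlap
        scoring."""
        extent = (np.asarray(self.config.cbct_shape) - 1) * np.asarray(self.config.cbct_spacing)
        n = tuple(int(np.ceil(e / spacing_mm)) + 1 for e in extent)
        origin = self.tumor_center_fixed - (np.asarray(n) - 1) * spacing_mm / 2.0
        return GridSpec(n, np.full(3, spacing_mm), origin)

    def warped_tumor_mask(self, chain: TransformChain, grid: "GridSpec") -> Mask:
        """Rasterize the image of the analytic tumor sphere under ``chain``
        on ``grid`` (exact; no interpolation of a voxelized mask)."""
        pts = grid.world_points()
        inside = np.linalg.norm(chain.apply(pts) - self.tumor_center_moving,
                                axis=1) <= self.config.tumor_radius_mm
        return Mask(inside.reshape(grid.shape).astype(np.uint8), grid.spacing,
                    grid.origin, grid.direction)

    def tumor_fixed_mask(self, grid: "GridSpec") -> Mask:
        """The true fixed-space tumor on an arbitrary grid."""
        return self.warped_tumor_mask(self.chain, grid)


# -- analytic anatomy -------------------------------------------------------

_VESSEL_NODES = {
    # three generations of a portal-like tree, all inside the liver ellipsoid
    "p0": (-5.0, -30.0, -35.0), "p1": (0.0, -10.0, -10.0),
    "p2": (20.0, 10.0, 10.0), "p3": (-20.0, 5.0, 15.0),
    "p4": (30.0, 22.0, 18.0), "p5": (10.0, 25.0, 25.0),
    "p6": (-32.0, 18.0, 22.0), "p7": (-12.0, -8.0, 28.0),
    "p8": (38.0, 28.0, 10.0), "p9": (25.0, 8.0, 30.0),
    "q1": (22.0, -35.0, -8.0),
    "l1": (40.0, -28.0, 6.0), "l2": (14.0, -38.0, -18.0),
    "l3": (4.0, 34.0, 28.0), "l4": (16.0, 30.0, 30.0),
    "l5": (-38.0, 22.0, 24.0), "l6": (-36.0, 8.0, 30.0),
    "l7": (-6.0, -20.0, 36.0), "l8": (-22.0, -14.0, 34.0),
    "l9": (32.0, 0.0, 36.0),
}
_VESSEL_SEGMENTS = [("p0", "p1"), ("p1", "p2"), ("p1", "p3"), ("p2", "p4"),
                    ("p2", "p5"), ("p3", "p6"), ("p3", "p7"), ("p4", "p8"),
                    ("p4", "p9"), ("p0", "q1"), ("q1", "l1"), ("q1", "l2"),
                    ("p5", "l3"), ("p5", "l4"), ("p6", "l5"), ("p6", "l6"),
                    ("p7", "l7"), ("p7", "l8"), ("p9", "l9")]
# landmark pairs live at vessel bifurcations (intrahepatic vessels deform
# less than the liver contour); the first few seed the rigid step, the rest
# are held out for TRE
_BIFURCATIONS = ["p1", "p2", "p3", "p4"]
_HELD_OUT = ["q1", "p5", "p6", "p7", "p9"]


def _ellipsoid_value(pts: np.ndarray, radii) -> np.ndarray:
    r = np.asarray(radii, dtype=float)
    return ((pts / r) ** 2).sum(axis=-1)


def _segment_distance(pts: np.ndarray, a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    d = np.asarray(b, dtype=float) - a
    t = np.clip(((pts - a) @ d) / (d @ d), 0.0, 1.0)
    return np.linalg.norm(pts - (a + t[:, None] * d), axis=1)


def _vessel_distance(pts: np.ndarray) -> np.ndarray:
    dist = np.full(pts.shape[0], np.inf)
    for na, nb in _VESSEL_SEGMENTS:
        dist = np.minimum(dist, _segment_distance(pts, _VESSEL_NODES[na], _VESSEL_NODES[nb]))
    return dist


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _texture(pts: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Smooth anatomical texture at moving-space points: a cubic-B-spline
    interpolated random field, fixed by the config seed, so CT and CBCT see
    the *same* (deformed) heterogeneity."""
    from scipy.ndimage import map_coordinates

    if cfg.texture_amplitude_hu <= 0:
        return np.zeros(pts.shape[0])
    rng = np.random.default_rng([int(cfg.seed), 777])
    half = float(max(cfg.liver_radii_mm)) + 40.0
    spacing = float(cfg.texture_scale_mm)
    n = int(np.ceil(2 * half / spacing)) + 4
    grid = rng.normal(size=(n, n, n))
    coords = ((pts + half) / spacing + 1.0).T
    vals = map_coordinates(grid, coords, order=3, mode="nearest")
    return cfg.texture_amplitude_hu * vals


def _clean_intensity(pts: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Noise-free phantom intensity at moving-space world points."""
    e = _ellipsoid_value(pts, cfg.liver_radii_mm)
    w_liver = _smoothstep((1.0 - e) / 0.06 + 0.5)
    out = cfg.hu_background + (cfg.hu_parenchyma - cfg.hu_background) * w_liver
    out += _texture(pts, cfg) * w_liver
    edge = 1.0  # mm blending width of vessel/tumor boundaries
    w_vessel = _smoothstep((cfg.vessel_radius_mm - _vessel_distance(pts)) / edge + 0.5) * w_liver
    out += (cfg.hu_vessel - cfg.hu_parenchyma) * w_vessel
    dt = np.linalg.norm(pts - np.asarray(cfg.tumor_center_mm), axis=1)
    w_tumor = _smoothstep((cfg.tumor_radius_mm - dt) / edge + 0.5) * w_liver * (1 - w_vessel)
    out += (cfg.hu_tumor - cfg.hu_parenchyma) * w_tumor
    return out


def _ct_grid(cfg: PhantomConfig) -> GridSpec:
    shape = np.asarray(cfg.ct_shape)
    spacing = np.asarray(cfg.ct_spacing, dtype=float)
    origin = -(shape - 1) * spacing / 2.0  # liver centred at the world origin
    return GridSpec(tuple(int(s) for s in shape), spacing, origin)


def make_phantom(cfg: PhantomConfig | None = None):
    """Build the pre-ablation CECT and the moving-space half of the truth.

    Deterministic given ``cfg.seed``.  Raises if the tumor sphere does not
    fit inside the liver.
    """
    cfg = cfg or PhantomConfig()
    cfg.validate()

    # tumor must fit inside the liver: probe its surface
    rng_dirs = np.random.default_rng(12345)  # fixed probe directions, not data noise
    dirs = rng_dirs.normal(size=(200, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    surface = np.asarray(cfg.tumor_center_mm) + cfg.tumor_radius_mm * dirs
    if np.any(_ellipsoid_value(surface, cfg.liver_radii_mm) > 1.0):
        raise ValueError("geometry error: tumor sphere does not fit inside the liver")

    grid = _ct_grid(cfg)
    pts = grid.world_points()
    clean = _clean_intensity(pts, cfg)
    rng = np.random.default_rng(cfg.seed)
    data = clean + rng.normal(0.0, cfg.ct_noise_sd, size=clean.shape)
    cect = Volume(data.reshape(grid.shape), grid.spacing, grid.origin, grid.direction)

    e = _ellipsoid_value(pts, cfg.liver_radii_mm)
    liver = (e <= 1.0).reshape(grid.shape).astype(np.uint8)
    dtum = np.linalg.norm(pts - np.asarray(cfg.tumor_center_mm), axis=1)
    tumor = (dtum <= cfg.tumor_radius_mm).reshape(grid.shape).astype(np.uint8)
    vessel = ((_vessel_distance(pts) <= cfg.vessel_radius_mm) & (e <= 1.0)).reshape(
        grid.shape).astype(np.uint8)

    truth = PhantomGroundTruth(config=cfg)
    truth.masks["liver_moving"] = Mask.from_volume(cect, liver)
    truth.masks["tumor_moving"] = Mask.from_volume(cect, tumor)
    truth.masks["vessel_moving"] = Mask.from_volume(cect, vessel)
    truth.landmarks_moving = np.asarray(
        [_VESSEL_NODES[k] for k in _BIFURCATIONS + _HELD_OUT], dtype=float)
    truth.n_bifurcations = len(_BIFURCATIONS)
    truth.tumor_center_moving = np.asarray(cfg.tumor_center_mm, dtype=float)
    return cect, truth


# -- true deformation -------------------------------------------------------


def _rotation_matrix(deg_xyz) -> np.ndarray:
    rx, ry, rz = np.deg2rad(np.asarray(deg_xyz, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _true_chain(cfg: PhantomConfig, ct_grid: GridSpec, rng: np.random.Generator) -> TransformChain:
    rigid = RigidTransform(_rotation_matrix(cfg.rigid_rotation_deg),
                           np.asarray(cfg.rigid_translation_mm, dtype=float))
    affine = AffineTransform(np.eye(3) * cfg.affine_scale, np.zeros(3), np.zeros(3))

    gs = float(cfg.nonrigid_scale_mm)
    lo = ct_grid.index_to_world(np.zeros(3)) - 2.5 * gs
    hi = ct_grid.index_to_world(np.asarray(ct_grid.shape) - 1.0) + 2.5 * gs
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / gs)) + 4 for a in range(3))
    coeffs = rng.normal(size=shape + (3,))
    bspline = BSplineTransform(lo, np.full(3, gs), coeffs)
    if cfg.nonrigid_amplitude_mm > 0:
        probe = ct_grid.world_points()[::7]
        maxdisp = np.max(np.linalg.norm(bspline.displacement(probe), axis=1))
        coeffs *= cfg.nonrigid_amplitude_mm / maxdisp
    else:
        coeffs[:] = 0.0
    bspline = BSplineTransform(lo, np.full(3, gs), coeffs)
    return TransformChain([rigid, affine, bspline])


def _pullback_ball_mask(chain: TransformChain, center_fixed: np.ndarray, radius: float,
                        grid: GridSpec) -> np.ndarray:
    """Rasterize the moving-space image of a fixed-space ball: a moving
    voxel p is inside iff chain^{-1}(p) lies in the ball."""
    pts = grid.world_points()
    approx_center = chain.apply(center_fixed[None, :])[0]
    near = np.linalg.norm(pts - approx_center, axis=1) <= radius + 25.0
    out = np.zeros(pts.shape[0], dtype=np.uint8)
    if near.any():
        x = invert_chain_at_points(chain, pts[near], tol=1e-9, max_iter=30)
        out[near] = (np.linalg.norm(x - center_fixed, axis=1) <= radius).astype(np.uint8)
    return out.reshape(grid.shape)


def degrade_to_cbct(cect: Volume, truth: PhantomGroundTruth,
                    cfg: PhantomConfig | None = None):
    """Apply the true deformation, insert the ablation zone, resample to the
    coarser tumor-centred CBCT grid and degrade (shading + noise).

    Completes ``truth`` with the exact chain, fixed-space masks and paired
    landmarks, and returns ``(cbct, truth)``.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    ct_grid = _ct_grid(cfg)
    chain = _true_chain(cfg, ct_grid, rng)
    truth.chain = chain

    c_m = np.asarray(cfg.tumor_center_mm, dtype=float)
    c_f = invert_chain_at_points(chain, c_m[None, :], tol=1e-12)[0]
    truth.tumor_center_fixed = c_f

    shape = np.asarray(cfg.cbct_shape)
    spacing = np.asarray(cfg.cbct_spacing, dtype=float)
    origin = c_f - (shape - 1) * spacing / 2.0
    grid = GridSpec(tuple(int(s) for s in shape), spacing, origin)
    pts = grid.world_points()
    mapped = chain.apply(pts)

    clean = _clean_intensity(mapped, cfg)  # analytic: no interpolation blur

    # ablation zone in fixed space
    abl_center = c_f + np.asarray(cfg.ablation_offset_mm, dtype=float)
    dtum_fixed = np.linalg.norm(mapped - c_m, axis=1)
    tumor_fixed = dtum_fixed <= cfg.tumor_radius_mm
    if cfg.ablation_target_residual_fraction is not None:
        frac = float(cfg.ablation_target_residual_fraction)
        best_d, best_err = 0.0, np.inf
        for d in np.linspace(0.0, cfg.tumor_radius_mm + cfg.ablation_radius_mm, 321):
            cand = c_f + np.array([d, 0.0, 0.0])
            abl = np.linalg.norm(pts - cand, axis=1) <= cfg.ablation_radius_mm
            n_t = tumor_fixed.sum()
            res = (tumor_fixed & ~abl).sum() / n_t
            if abs(res - frac) < best_err:
                best_err, best_d = abs(res - frac), d
        abl_center = c_f + np.array([best_d, 0.0, 0.0])
    truth.ablation_center_fixed = abl_center

    dabl = np.linalg.norm(pts - abl_center, axis=1)
    w_abl = _smoothstep((cfg.ablation_radius_mm - dabl) / 1.0 + 0.5)
    # necrosis replaces tissue but not the extrahepatic background
    e_fixed = _ellipsoid_value(mapped, cfg.liver_radii_mm)
    w_abl = w_abl * _smoothstep((1.0 - e_fixed) / 0.06 + 0.5)
    data = clean + (cfg.hu_ablation - clean) * w_abl

    # CBCT-like degradation: smooth multiplicative shading + heavier noise
    if cfg.shading_amplitude > 0:
        coarse = rng.normal(size=(4, 4, 4))
        from scipy.ndimage import zoom

        fieldv = zoom(coarse, np.asarray(grid.shape) / 4.0, order=3)
        fieldv = fieldv[: grid.shape[0], : grid.shape[1], : grid.shape[2]]
        fieldv /= np.max(np.abs(fieldv))
        shade = 1.0 + cfg.shading_amplitude * fieldv.reshape(-1)
        data = (data + 1000.0) * shade - 1000.0
    data = data + rng.normal(0.0, cfg.cbct_noise_sd, size=data.shape)

    cbct = Volume(data.reshape(grid.shape), grid.spacing, grid.origin, grid.direction)

    # exact fixed-space masks (analytic shapes composed with the true chain)
    tumor_fixed_m = tumor_fixed.reshape(grid.shape).astype(np.uint8)
    if not tumor_fixed_m.any():
        raise ValueError("FOV error: deformation pushed the tumor outside the CBCT grid")
    border = np.zeros(grid.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    if (tumor_fixed_m.astype(bool) & border).any():
        raise ValueError("FOV error: tumor touches the CBCT field-of-view boundary")
    truth.masks["tumor_fixed"] = Mask.from_volume(cbct, tumor_fixed_m)
    truth.masks["liver_fixed"] = Mask.from_volume(
        cbct, (e_fixed <= 1.0).reshape(grid.shape).astype(np.uint8))
    truth.masks["ablation_fixed"] = Mask.from_volume(
        cbct, (dabl <= cfg.ablation_radius_mm).reshape(grid.shape).astype(np.uint8))
    truth.masks["ablation_moving"] = Mask(
        _pullback_ball_mask(chain, abl_center, cfg.ablation_radius_mm, ct_grid),
        ct_grid.spacing, ct_grid.origin, ct_grid.direction)

    # landmark pairs: moving positions are known; fixed ones are the exact
    # chain preimages (Newton inversion, verified to 1e-9 mm)
    moving_lm = truth.landmarks_moving
    fixed_lm = invert_chain_at_points(chain, moving_lm, tol=1e-12)
    resid = np.linalg.norm(chain.apply(fixed_lm) - moving_lm, axis=1)
    if np.max(resid) > 1e-9:
        raise RuntimeError("landmark inversion failed to converge below 1e-9 mm")
    truth.landmarks = LandmarkPairSet(fixed_lm, moving_lm)
    return cbct, truth


# -- canonical outcome scenarios -------------------------------------------


@dataclass
class Scenario:
    name: str
    cect: Volume
    cbct: Volume
    truth: PhantomGroundTruth
    expected_classification: str


def scenario_suite(seed: int = 0, partial_fraction: float = 0.25):
    """Canonical outcome cases on the coarse phantom: complete ablation,
    partial ablation (configurable residual fraction) and missed target.
    Reproducible under a fixed seed."""
    specs = [
        ("complete", dict(ablation_radius_mm=13.0, ablation_offset_mm=(0.0, 0.0, 0.0)),
         "complete"),
        ("partial_%d" % round(100 * partial_fraction),
         dict(ablation_radius_mm=11.0,
              ablation_target_residual_fraction=partial_fraction), "partial"),
        ("missed", dict(ablation_radius_mm=11.0,
                        ablation_offset_mm=(31.0, 0.0, 0.0)), "missed"),
    ]
    out = []
    for i, (name, overrides, expected) in enumerate(specs):
        cfg = PhantomConfig.coarse(seed=seed + 101 * i, **overrides)
        cect, truth = make_phantom(cfg)
        cbct, truth = degrade_to_cbct(cect, truth, cfg)
        out.append(Scenario(name, cect, cbct, truth, expected))
    return out
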