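"""Four-step CECT -> CE-CBCT registration.

The intraprocedural CE-CBCT is the fixed (template) image and the
pre-ablation CECT the moving image throughout.  The pipeline runs

1. CECT resampling at CBCT resolution,
2. semiautomatic rigid initialisation from three (or more) paired vessel
   landmarks (least-squares Kabsch fit),
3. automatic affine then cubic-B-spline free-form registration driven by
   normalized mutual information (Studholme form) on a multiresolution
   pyramid,
4. warping of the CECT (and its segmented tumor) onto the CBCT grid.

All transforms map fixed-space world points to moving-space world points
(see :mod:`ablafuse.transforms`).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .preprocess import Mask
from .transforms import (AffineTransform, BSplineTransform, RigidTransform,
                         TransformChain, bspline_weights_1d)
from .volume import GridSpec, Volume, sample_at_world

__all__ = [
    "LandmarkPairSet",
    "JointHistogram",
    "RegistrationResult",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "landmark_rigid",
    "joint_histogram",
    "nmi",
    "register_affine",
    "register_bspline",
    "warp",
    "register_pipeline",
    "default_registration_config",
]


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkPairSet:
    """Paired world-mm points: ``fixed_points`` in CBCT space and
    ``moving_points`` in CECT space (n >= 3, fixed points not collinear)."""

    fixed_points: np.ndarray
    moving_points: np.ndarray

    def __post_init__(self):
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        if self.fixed_points.shape != self.moving_points.shape:
            raise ValueError("fixed and moving landmark counts differ")
        if self.fixed_points.shape[0] < 3 or self.fixed_points.shape[1] != 3:
            raise ValueError("need >= 3 paired 3D landmarks")
        centered = self.fixed_points - self.fixed_points.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise ValueError("fixed landmarks are collinear; rigid fit is degenerate")

    def __len__(self):
        return self.fixed_points.shape[0]

    def subset(self, idx) -> "LandmarkPairSet":
        return LandmarkPairSet(self.fixed_points[idx], self.moving_points[idx])


_LM_HEADER = ["fixed_x", "fixed_y", "fixed_z", "moving_x", "moving_y", "moving_z"]


def read_landmarks_csv(path) -> LandmarkPairSet:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such landmark file: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_LM_HEADER) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
        fixed, moving = [], []
        for row in reader:
            fixed.append([float(row[k]) for k in _LM_HEADER[:3]])
            moving.append([float(row[k]) for k in _LM_HEADER[3:]])
    return LandmarkPairSet(np.asarray(fixed), np.asarray(moving))


def write_landmarks_csv(pairs: LandmarkPairSet, path) -> None:
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LM_HEADER)
        for f, m in zip(pairs.fixed_points, pairs.moving_points):
            writer.writerow([repr(float(x)) for x in (*f, *m)])


def landmark_rigid(pairs: LandmarkPairSet, allow_scale: bool = False) -> RigidTransform:
    """Least-squares rigid transform mapping the fixed landmarks onto the
    moving landmarks (Kabsch/Umeyama: SVD of the cross-covariance with the
    standard reflection correction; no scaling unless ``allow_scale``)."""
    f = pairs.fixed_points
    m = pairs.moving_points
    fc = f.mean(axis=0)
    mc = m.mean(axis=0)
    H = (f - fc).T @ (m - mc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        var = np.sum((f - fc) ** 2)
        scale = float(np.sum(S * np.diag(D)) / var)
        M = scale * R  # similarity, returned as a centered affine
        return AffineTransform(M, mc - M @ fc, np.zeros(3))
    return RigidTransform(R, mc - R @ fc)


# ---------------------------------------------------------------------------
# joint histogram & normalized mutual information
# ---------------------------------------------------------------------------


@dataclass
class JointHistogram:
    """Partial-volume joint histogram of fixed vs mapped-moving intensity.

    ``counts`` is (bins_fixed, bins_moving); bin k spans the value range
    around the centre ``lo + k * (hi - lo) / (bins - 1)`` so that integer
    images binned at their value set land exactly on single bins.
    """

    counts: np.ndarray
    fixed_range: tuple
    moving_range: tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def edges(self, which: str = "fixed") -> np.ndarray:
        lo, hi = self.fixed_range if which == "fixed" else self.moving_range
        bins = self.counts.shape[0 if which == "fixed" else 1]
        w = (hi - lo) / (bins - 1) if bins > 1 and hi > lo else 1.0
        return lo + (np.arange(bins + 1) - 0.5) * w


def _bin_coords(values: np.ndarray, lo: float, hi: float, bins: int):
    """Linear (partial-volume) bin assignment: lower bin index and weight of
    the upper bin for each value."""
    if hi <= lo:
        u = np.zeros_like(values)
    else:
        u = (values - lo) / (hi - lo) * (bins - 1)
    u = np.clip(u, 0.0, bins - 1.0)
    i0 = np.minimum(u.astype(np.int64), bins - 2)
    return i0, u - i0


def _pv_accumulate(fvals, mvals, bins, f_range=None, m_range=None):
    flo, fhi = f_range if f_range is not None else (fvals.min(), fvals.max())
    mlo, mhi = m_range if m_range is not None else (mvals.min(), mvals.max())
    fi, ft = _bin_coords(fvals, flo, fhi, bins)
    mi, mt = _bin_coords(mvals, mlo, mhi, bins)
    counts = np.zeros((bins, bins))
    flatidx = fi * bins + mi
    cflat = counts.reshape(-1)
    np.add.at(cflat, flatidx, (1 - ft) * (1 - mt))
    np.add.at(cflat, flatidx + 1, (1 - ft) * mt)
    np.add.at(cflat, flatidx + bins, ft * (1 - mt))
    np.add.at(cflat, flatidx + bins + 1, ft * mt)
    return counts, (float(flo), float(fhi)), (float(mlo), float(mhi)), (fi, ft, mi, mt)


def joint_histogram(fixed: Volume, moving: Volume, chain: TransformChain | None = None,
                    bins: int = 32, mask: Mask | None = None,
                    samples: int | None = None, seed: int = 0) -> JointHistogram:
    """Joint histogram of fixed-grid voxels against the chain-mapped moving
    image, accumulated with linear partial-volume weighting.

    Samples either every fixed voxel or a seeded uniform random subset of
    ``samples`` voxels; voxels outside ``mask`` or whose mapped point falls
    outside the moving extent do not contribute.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if samples is not None and samples < 1000:
        raise ValueError("when sampling, use >= 1000 samples")
    chain = chain or TransformChain()
    grid = fixed.grid
    pts = grid.world_points()
    fvals = np.asarray(fixed.data, dtype=float).reshape(-1)
    if mask is not None:
        keep = np.asarray(mask.labels, dtype=bool).reshape(-1)
        pts, fvals = pts[keep], fvals[keep]
    if samples is not None and samples < pts.shape[0]:
        rng = np.random.default_rng(seed)
        sel = rng.choice(pts.shape[0], size=samples, replace=False)
        pts, fvals = pts[sel], fvals[sel]
    mapped = chain.apply(pts)
    idx = moving.world_to_index(mapped)
    shape = np.asarray(moving.data.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    if not inside.any():
        raise ValueError("empty overlap: no fixed sample maps inside the moving image")
    mvals = sample_at_world(moving, mapped[inside], interp="linear", fill=0.0)
    counts, frange, mrange, _ = _pv_accumulate(fvals[inside], mvals, bins)
    return JointHistogram(counts, frange, mrange)


def _entropies_bits(counts: np.ndarray):
    total = counts.sum()
    p = counts / total
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)

    def H(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    return H(pf), H(pm), H(p.reshape(-1))


def nmi(h: JointHistogram) -> float:
    """Studholme normalized mutual information (H_f + H_m) / H_joint, in
    bits; 0*log(0) is taken as 0.  Equals 2 for identical images and 1 under
    independence (or a constant marginal)."""
    if h.total <= 0:
        raise ValueError("empty joint histogram")
    hf, hm, hj = _entropies_bits(h.counts)
    if hj == 0.0:
        return 2.0 if (hf > 0 or hm > 0) else 1.0
    return (hf + hm) / hj


# ---------------------------------------------------------------------------
# metric evaluation helpers
# ---------------------------------------------------------------------------


def _gaussian_downsample(v: Volume, factor: int) -> Volume:
    from scipy.ndimage import gaussian_filter

    if factor == 1:
        return v
    data = gaussian_filter(np.asarray(v.data, dtype=float), sigma=factor / 2.0)
    sl = tuple(slice(None, None, factor) for _ in range(3))
    data = data[sl]
    return Volume(data, v.spacing * factor, v.origin.copy(), v.direction.copy())


@dataclass
class _MetricSamples:
    """Fixed-image samples reused across metric evaluations of one level."""

    points: np.ndarray      # (S, 3) fixed-space world coordinates
    intensities: np.ndarray  # (S,)

    @classmethod
    def from_volume(cls, fixed: Volume, body_threshold, samples, seed):
        pts = fixed.grid.world_points()
        fvals = np.asarray(fixed.data, dtype=float).reshape(-1)
        if body_threshold is not None:
            keep = fvals > body_threshold
            if keep.sum() >= 1000:  # fall back to whole volume on tiny masks
                pts, fvals = pts[keep], fvals[keep]
        if samples is not None and samples < pts.shape[0]:
            rng = np.random.default_rng(seed)
            sel = rng.choice(pts.shape[0], size=int(samples), replace=False)
            pts, fvals = pts[sel], fvals[sel]
        return cls(pts, fvals)


def _metric_nmi(samples: _MetricSamples, moving: Volume, chain: TransformChain,
                bins: int) -> float:
    """NMI over the fixed samples with out-of-extent moving points taking
    the moving minimum (air/background).

    Keeping the sample set constant (rather than dropping non-overlapping
    samples, as the reporting histogram does) removes the overlap-shrinkage
    pathology of mutual information, where pushing difficult boundary
    samples out of the moving field of view spuriously raises the score.
    """
    mapped = chain.apply(samples.points)
    idx = moving.world_to_index(mapped)
    shape = np.asarray(moving.data.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    if inside.sum() < 100:
        raise ValueError("empty overlap while evaluating the metric")
    mvals = sample_at_world(moving, mapped, interp="linear")
    counts, _, _, _ = _pv_accumulate(samples.intensities, mvals, bins)
    return nmi(JointHistogram(counts, (0, 1), (0, 1)))


# ---------------------------------------------------------------------------
# affine stage (derivative-free NMI ascent)
# ---------------------------------------------------------------------------

_AFFINE_DEFAULTS = {
    "bins": 32,
    "pyramid": (4, 2, 1),
    "samples": 150000,
    "maxiter": (6, 4, 2),       # Powell outer iterations per level
    "xtol": 1e-3,
    # optional HU threshold restricting the metric to fixed voxels above it
    # (useful when air dominates a large fixed FOV); None = whole volume
    "body_threshold": None,
    "seed": 0,
    "matrix_scale": 0.02,       # initial search step for matrix entries
    "translation_scale": 2.0,   # mm
    # homomorphic uniformity correction applied to both images before the
    # metric (CBCT shading biases NMI); None disables
    "uniformity_sigma_mm": 50.0,
    # trust region around the initialization: the landmark step has already
    # removed gross mismatch, and far from it NMI has spurious optima where
    # samples leave the moving field of view
    "max_translation_mm": 15.0,
    "max_matrix_dev": 0.15,
}


def register_affine(fixed: Volume, moving: Volume, init: TransformChain | None = None,
                    config: dict | None = None):
    """Maximise NMI over the 12 centered affine parameters by Powell search
    on a coarse-to-fine pyramid.  Returns ``(affine, trace)`` where the
    affine composes *after* ``init`` and ``trace`` is the per-level list of
    (initial NMI, final NMI)."""
    from scipy.optimize import minimize

    from .preprocess import _merge_config

    cfg = _merge_config(_AFFINE_DEFAULTS, config)
    init = init or TransformChain()
    if cfg["uniformity_sigma_mm"]:
        from .preprocess import shading_correction

        fixed = shading_correction(fixed, cfg["uniformity_sigma_mm"])
        moving = shading_correction(moving, cfg["uniformity_sigma_mm"])
    center = fixed.grid.center_world
    trace = []
    p = np.zeros(12)

    def make_affine(params):
        dM = params[:9].reshape(3, 3)
        return AffineTransform(np.eye(3) + dM, params[9:], center)

    for li, factor in enumerate(cfg["pyramid"]):
        fx = _gaussian_downsample(fixed, int(factor))
        mv = _gaussian_downsample(moving, int(factor))
        samples = _MetricSamples.from_volume(fx, cfg["body_threshold"],
                                             cfg["samples"], cfg["seed"] + li)

        def neg(params):
            chain = init.extended(make_affine(params))
            try:
                return -_metric_nmi(samples, mv, chain, cfg["bins"])
            except ValueError:
                return 0.0  # empty overlap: worst possible score

        start = -neg(p)
        final = start
        maxiter = cfg["maxiter"][li] if np.iterable(cfg["maxiter"]) else cfg["maxiter"]
        # degrees of freedom are staged (translation, full affine, then a
        # translation re-polish): the 12-parameter search can trade matrix
        # terms against translation on a noisy metric, so the
        # well-conditioned subset brackets it
        for active in (slice(9, 12), slice(0, 12), slice(9, 12)):
            sub = np.arange(12)[active]

            def neg_sub(q, sub=sub):
                full = p.copy()
                full[sub] = q
                return neg(full)

            scales = np.concatenate([np.full(9, cfg["matrix_scale"]),
                                     np.full(3, cfg["translation_scale"])])[sub]
            bounds = ([(-cfg["max_matrix_dev"], cfg["max_matrix_dev"])] * 9 +
                      [(-cfg["max_translation_mm"], cfg["max_translation_mm"])] * 3)
            bounds = [bounds[i] for i in sub]
            res = minimize(neg_sub, p[sub], method="Powell", bounds=bounds,
                           options={"maxiter": int(maxiter), "xtol": cfg["xtol"],
                                    "ftol": 1e-7, "direc": np.diag(scales)})
            if -res.fun >= final:
                p[sub] = res.x
                final = -res.fun
        # sub-millimetre translation polish: bounded scalar search per axis
        from scipy.optimize import minimize_scalar

        for axis in (9, 10, 11):
            def neg_axis(v, axis=axis):
                q = p.copy()
                q[axis] = v
                return neg(q)

            r = minimize_scalar(neg_axis, bounds=(p[axis] - 2.0, p[axis] + 2.0),
                                method="bounded", options={"xatol": 0.01})
            if -r.fun >= final:
                p[axis] = r.x
                final = -r.fun
        trace.append((start, final))

    return make_affine(p), trace


# ---------------------------------------------------------------------------
# B-spline stage (analytic NMI gradient ascent)
# ---------------------------------------------------------------------------

_BSPLINE_DEFAULTS = {
    "grid_spacing": 20.0,       # mm, finest control-point spacing of the FFD
    # per-level multiplier of grid_spacing (coarse lattice first, refined by
    # exact dyadic subdivision); entries must halve or stay equal.  The
    # doubled mid-resolution level lets the coarse lattice settle before the
    # refinement adds local degrees of freedom
    "grid_schedule": (2, 2, 1, 1),
    "bins": 32,
    "pyramid": (4, 2, 2, 1),
    "samples": 150000,
    "maxiter": 100,             # L-BFGS iterations per level
    "regularization": 0.01,     # weight of the mean bending energy
    "body_threshold": None,
    "uniformity_sigma_mm": 50.0,
    "seed": 0,
}


def _nmi_and_bin_gradient(fvals, mvals, bins):
    """NMI plus dNMI/d(moving value) per sample, for partial-volume bins."""
    counts, frange, mrange, (fi, ft, mi, mt) = _pv_accumulate(fvals, mvals, bins)
    total = counts.sum()
    p = counts / total
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        logf = np.where(pf > 0, np.log2(np.where(pf > 0, pf, 1.0)), 0.0)
        logm = np.where(pm > 0, np.log2(np.where(pm > 0, pm, 1.0)), 0.0)
    hf = float(-(pf * logf).sum())
    hm = float(-(pm * logm).sum())
    hj = float(-(p * logp).sum())
    if hj <= 0:
        return 2.0, np.zeros_like(mvals), (frange, mrange)
    val = (hf + hm) / hj
    inv_ln2 = 1.0 / np.log(2.0)
    # dH/dc_ij = -(log2 p + 1/ln2)/N, zero at empty bins
    dhf = np.where(pf > 0, -(logf + inv_ln2) / total, 0.0)  # row-indexed
    dhm = np.where(pm > 0, -(logm + inv_ln2) / total, 0.0)  # col-indexed
    dhj = np.where(p > 0, -(logp + inv_ln2) / total, 0.0)
    G = (dhf[:, None] + dhm[None, :] - val * dhj) / hj  # dNMI/dc_ij
    mlo, mhi = mrange
    wbin = (mhi - mlo) / (bins - 1) if mhi > mlo else 1.0
    # moving sample contributes (1-mt) to column mi and mt to mi+1 in rows fi
    # and fi+1 with weights (1-ft), ft; d/dm moves mass from mi to mi+1
    dcol = (1 - ft) * (G[fi, mi + 1] - G[fi, mi]) \
        + ft * (G[fi + 1, mi + 1] - G[fi + 1, mi])
    return val, dcol / wbin, (frange, mrange)


def _refine_dyadic(coeffs: np.ndarray) -> np.ndarray:
    """Halve the control spacing of a cubic-B-spline coefficient lattice by
    knot insertion (subdivision masks [1,6,1]/8 and [4,4]/8), reproducing
    the same displacement field on the refined lattice (exactly, away from
    the lattice border)."""
    out = coeffs
    for axis in range(3):
        c = np.moveaxis(out, axis, 0)
        n = c.shape[0]
        even = np.empty_like(c)
        cm = np.concatenate([c[:1], c[:-1]], axis=0)
        cp = np.concatenate([c[1:], c[-1:]], axis=0)
        even = (cm + 6.0 * c + cp) / 8.0
        odd = (c[:-1] + c[1:]) / 2.0
        new = np.empty((2 * n - 1,) + c.shape[1:], dtype=c.dtype)
        new[0::2] = even
        new[1::2] = odd
        out = np.moveaxis(new, 0, axis)
    return out


def _moving_gradients_world(moving: Volume):
    """Per-axis world-space (mm^-1) intensity gradient volumes."""
    grads_idx = np.gradient(np.asarray(moving.data, dtype=float))
    # d/dworld = direction @ (d/didx / spacing); components stacked (3, ...)
    gidx = np.stack([g / s for g, s in zip(grads_idx, moving.spacing)])
    d = moving.direction
    return np.einsum("ab,b...->a...", np.linalg.inv(d.T), gidx)


def register_bspline(fixed: Volume, moving: Volume, init: TransformChain | None = None,
                     config: dict | None = None):
    """Maximise NMI over cubic-B-spline control-point displacements with a
    bending-energy penalty, by adaptive gradient ascent on a multiresolution
    pyramid (analytic metric gradient).  Returns ``(bspline, trace)``; the
    transform composes after ``init`` (its lattice lives in the space that
    ``init`` maps fixed points into)."""
    from scipy.ndimage import correlate1d

    from .preprocess import _merge_config

    cfg = _merge_config(_BSPLINE_DEFAULTS, config)
    init = init or TransformChain()
    if cfg["uniformity_sigma_mm"]:
        from .preprocess import shading_correction

        fixed = shading_correction(fixed, cfg["uniformity_sigma_mm"])
        moving = shading_correction(moving, cfg["uniformity_sigma_mm"])
    gs = float(cfg["grid_spacing"])
    if gs < 2.0 * float(np.max(fixed.spacing)):
        raise ValueError(
            f"over-parameterized: control spacing {gs} mm < 2 fixed voxels "
            f"({2.0 * float(np.max(fixed.spacing)):.2f} mm)")

    schedule = tuple(cfg["grid_schedule"])
    if len(schedule) != len(cfg["pyramid"]):
        raise ValueError("grid_schedule must have one entry per pyramid level")
    for a, b in zip(schedule, schedule[1:]):
        if b != a and 2 * b != a:
            raise ValueError("grid_schedule entries must stay equal or halve")

    # lattice covering the init-mapped fixed domain plus cubic support margin
    corners_idx = np.array([[i, j, k] for i in (0, fixed.shape[0] - 1)
                            for j in (0, fixed.shape[1] - 1)
                            for k in (0, fixed.shape[2] - 1)], dtype=float)
    corners = init.apply(fixed.grid.index_to_world(corners_idx))
    gs0 = gs * schedule[0]
    margin = 2.0 * gs0
    lo = corners.min(axis=0) - margin
    hi = corners.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / gs0)) + 4 for a in range(3))
    coeffs = np.zeros(shape + (3,))
    spacing3 = np.full(3, gs0)

    lam = float(cfg["regularization"])
    kernel = np.array([1.0, -2.0, 1.0])

    def bending(mu):
        # mean squared second difference (mm^2 per control point), so the
        # penalty weight is independent of lattice size
        n_ctrl = float(np.prod(mu.shape[:3]))
        e = 0.0
        g = np.zeros_like(mu)
        for axis in range(3):
            d2 = correlate1d(mu, kernel, axis=axis, mode="constant")
            e += float((d2**2).sum()) / n_ctrl
            g += 2.0 * correlate1d(d2, kernel, axis=axis, mode="constant") / n_ctrl
        return e, g

    trace = []
    for li, factor in enumerate(cfg["pyramid"]):
        if li > 0 and schedule[li] * 2 == schedule[li - 1]:
            coeffs = _refine_dyadic(coeffs)
            spacing3 = spacing3 / 2.0
            shape = coeffs.shape[:3]
        fx = _gaussian_downsample(fixed, int(factor))
        mv = _gaussian_downsample(moving, int(factor))
        samples = _MetricSamples.from_volume(fx, cfg["body_threshold"],
                                             cfg["samples"], cfg["seed"] + li)
        z = init.apply(samples.points)  # B-spline acts in the init-mapped space
        tf = BSplineTransform(lo, spacing3.copy(), coeffs)
        flat_idx, w = tf.support_indices_and_weights(z)
        lat_shape = coeffs.shape
        gradvols = _moving_gradients_world(mv)
        mshape = np.asarray(mv.data.shape)
        mdata = np.asarray(mv.data, dtype=float)
        fill = float(mdata.min())

        def objective(mu, with_grad):
            from scipy.ndimage import map_coordinates

            u = np.einsum("nk,nkd->nd", w, mu.reshape(-1, 3)[flat_idx])
            y = z + u
            idx = mv.world_to_index(y)
            inside = np.all((idx >= 0) & (idx <= mshape - 1), axis=1)
            if inside.sum() < 100:
                raise ValueError("empty overlap in B-spline stage")
            coords = idx[inside].T
            mvals = map_coordinates(mdata, coords, order=1, mode="constant",
                                    cval=fill, prefilter=False)
            val, dval_dm, _ = _nmi_and_bin_gradient(samples.intensities[inside],
                                                    mvals, cfg["bins"])
            pen, peng = (bending(mu) if lam else (0.0, None))
            if not with_grad:
                return val - lam * pen, None
            gm = np.stack([map_coordinates(gv, coords, order=1, mode="constant",
                                           cval=0.0, prefilter=False)
                           for gv in gradvols], axis=1)  # (S_in, 3)
            force = dval_dm[:, None] * gm
            grad = np.zeros((int(np.prod(lat_shape[:3])), 3))
            np.add.at(grad, flat_idx[inside].reshape(-1),
                      (w[inside][:, :, None] * force[:, None, :]).reshape(-1, 3))
            grad = grad.reshape(lat_shape)
            if lam:
                grad -= lam * peng
            return val - lam * pen, grad

        mu_level_start = coeffs.copy()
        value0, _ = objective(coeffs, False)
        pen0 = lam * bending(coeffs)[0] if lam else 0.0
        start_nmi = value0 + pen0
        lat_size = coeffs.size

        def neg(x):
            val, grad = objective(x.reshape(lat_shape), True)
            return -val, -grad.ravel()

        from scipy.optimize import minimize

        res = minimize(neg, coeffs.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": int(cfg["maxiter"]), "maxcor": 20})
        mu = res.x.reshape(lat_shape)
        value, _ = objective(mu, False)
        final_nmi = value + (lam * bending(mu)[0] if lam else 0.0)
        if final_nmi < start_nmi:
            # a level may not worsen the raw metric: discard its update
            mu, final_nmi = mu_level_start, start_nmi
        coeffs = mu
        trace.append((start_nmi, final_nmi))

    return BSplineTransform(lo, spacing3, coeffs), trace


# ---------------------------------------------------------------------------
# warping and full pipeline
# ---------------------------------------------------------------------------


def warp(moving, chain: TransformChain, grid: GridSpec, interp: str | None = None,
         fill: float | None = None):
    """Resample ``moving`` (Volume or Mask) onto ``grid`` through ``chain``:
    the value at fixed voxel x is the moving value at chain(x).  Masks use
    nearest interpolation and stay binary."""
    pts = chain.apply(grid.world_points())
    if isinstance(moving, Mask):
        vol = Volume(moving.labels.astype(float), moving.spacing, moving.origin,
                     moving.direction)
        vals = sample_at_world(vol, pts, interp="nearest", fill=0.0)
        return Mask(vals.reshape(grid.shape).astype(np.uint8), grid.spacing.copy(),
                    grid.origin.copy(), grid.direction.copy())
    vals = sample_at_world(moving, pts, interp=interp or "linear", fill=fill)
    return Volume(vals.reshape(grid.shape), grid.spacing.copy(), grid.origin.copy(),
                  grid.direction.copy())


@dataclass
class RegistrationResult:
    """Full chain plus the per-stage NMI traces and convergence flags."""

    chain: TransformChain
    stage_traces: dict = field(default_factory=dict)
    converged: dict = field(default_factory=dict)

    def stage_chain(self, upto: str) -> TransformChain:
        names = ["rigid", "affine", "bspline"]
        n = names.index(upto) + 1
        return TransformChain(self.chain.transforms[:n])


def default_registration_config() -> dict:
    return {
        "affine": {k: v for k, v in _AFFINE_DEFAULTS.items()},
        "bspline": {k: v for k, v in _BSPLINE_DEFAULTS.items()},
        "resample_moving": False,
    }


def register_pipeline(cbct: Volume, cect: Volume, landmarks: LandmarkPairSet,
                      config: dict | None = None) -> RegistrationResult:
    """Run the four-step scheme: resample CECT at CBCT resolution, landmark
    rigid, NMI affine, NMI B-spline.  CBCT is fixed, CECT moving."""
    from .preprocess import _merge_config

    cfg = _merge_config(default_registration_config(), config)

    moving = cect
    if cfg["resample_moving"]:
        # literal step-1 variant: degrade the CECT to CBCT voxel size before
        # the metric stages.  By default the full-resolution CECT drives the
        # metric and step 1 is realised by the final warp onto the CBCT grid
        # (the CECT content is in either case re-sampled at CBCT resolution)
        scale = cect.spacing / cbct.spacing
        new_shape = tuple(max(int(np.ceil(n * s)), 2)
                          for n, s in zip(cect.shape, scale))
        grid = GridSpec(new_shape, cbct.spacing.copy(), cect.origin.copy(),
                        cect.direction.copy())
        from .volume import resample_to_grid

        moving = resample_to_grid(cect, grid, interp="linear")

    rigid = landmark_rigid(landmarks)
    chain = TransformChain([rigid])

    affine, affine_trace = register_affine(cbct, moving, chain, cfg["affine"])
    chain = chain.extended(affine)

    bspline, bspline_trace = register_bspline(cbct, moving, chain, cfg["bspline"])
    chain = chain.extended(bspline)

    traces = {"affine": affine_trace, "bspline": bspline_trace}
    converged = {stage: bool(tr and tr[-1][1] >= tr[-1][0])
                 for stage, tr in traces.items()}
    return RegistrationResult(chain, traces, converged)
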