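"""Node time-series extraction from 4-D volumes.

Implements the resting-state ROI pipeline: a discrete-cosine basis spanning
the 0.0078-0.1 Hz band models the signal of interest; an F-contrast over
the basis locates resting-state activity inside the motor-cortex mask; a
6 mm sphere at that peak yields the M1 principal eigenvariate (adjusted for
motion and nuisance signals); 4 mm spheres in putamen and thalamus are
centred on the voxels whose (confound-residualized) series correlate most
strongly with the M1 eigenvariate; the subthalamic nucleus uses its whole
mask.  Head motion is summarized by Power-style framewise displacement.

Sphere membership is evaluated in world space (mm) through the volume
affine, so anisotropic voxels are handled correctly.  Voxel indices are
0-based; NIfTI files are interpreted in RAS orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .spectra import SubjectTimeSeries

logger = logging.getLogger(__name__)

#: Rotation-to-displacement conversion radius (mm) for framewise
#: displacement, the head-sphere radius of the cited motion metric.
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class VolumeSeries:
    """A 4-D functional acquisition (x, y, z, t)."""

    data: np.ndarray
    voxel_size_mm: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 64:
            raise ValueError("need at least 64 volumes")
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def n_time(self) -> int:
        return self.data.shape[3]


@dataclass
class RoiMask:
    """Boolean 3-D mask aligned to a companion volume grid."""

    name: str
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.sum() < 1:
            raise ValueError(f"mask {self.name!r} is empty")


@dataclass
class MotionParams:
    """Rigid-body realignment parameters: 6 x t (translations mm, then
    rotations in radians)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 6:
            raise ValueError("motion must be 6 x t")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite motion parameters")

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class Eigenvariate:
    """Principal component summary of an ROI's voxel time series."""

    series: np.ndarray
    variance_explained_pct: float
    sphere_centre: tuple | None = None

    def __post_init__(self):
        if not (0 < self.variance_explained_pct <= 100 + 1e-9):
            raise ValueError("variance explained must be in (0, 100]")


# ---------------------------------------------------------------------------
# DCT basis and GLM
# ---------------------------------------------------------------------------

def dct_basis(n_vol: int, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    """Orthonormal discrete-cosine columns restricted to a frequency band.

    Column j of the full (type-II) basis oscillates at f_j = j / (2 N tr);
    columns with f_lo <= f_j <= f_hi are retained.  The constant term
    (j = 0) is never included.  Returns an (n_vol, k) matrix with
    B'B = I.
    """
    nyq = 0.5 / tr
    if not (0 <= f_lo < f_hi <= nyq + 1e-12):
        raise ValueError("need 0 <= f_lo < f_hi <= Nyquist")
    j = np.arange(1, n_vol)
    f_j = j / (2.0 * n_vol * tr)
    keep = j[(f_j >= f_lo) & (f_j <= f_hi)]
    if keep.size == 0:
        raise ValueError("no DCT component falls inside the requested band")
    t = np.arange(n_vol)
    B = np.sqrt(2.0 / n_vol) * np.cos(np.pi * np.outer(2 * t + 1, keep) / (2.0 * n_vol))
    return B


def framewise_displacement(motion: MotionParams) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-volume framewise displacement and its (mean, cumulative) summary.

    FD_t = sum |delta translations| + R * sum |delta rotations| with
    R = 50 mm; the first volume has FD 0 and the mean is over volumes >= 2.
    Returns (fd series in mm, mean, running cumulative sum).
    """
    if motion.n_time < 2:
        raise ValueError("need at least 2 volumes")
    d = np.diff(motion.values, axis=1)
    fd = np.zeros(motion.n_time)
    fd[1:] = np.abs(d[:3]).sum(axis=0) + FD_ROTATION_RADIUS_MM * np.abs(d[3:]).sum(axis=0)
    return fd, float(fd[1:].mean()), np.cumsum(fd)


def peak_voxel(stat_map: np.ndarray, mask: RoiMask) -> tuple[int, int, int]:
    """Coordinate of the maximal statistic within a mask.

    Ties are broken by the lowest linear (C-order) index, with a logged
    warning; an all-NaN masked map is an error.
    """
    vals = np.where(mask.data, stat_map, -np.inf)
    vals = np.where(np.isnan(vals), -np.inf, vals)
    best = vals.max()
    if not np.isfinite(best):
        raise ValueError("statistic is NaN at every masked voxel")
    flat_hits = np.flatnonzero(vals.ravel() == best)
    if flat_hits.size > 1:
        logger.warning("peak_voxel: %d tied maxima; choosing lowest linear index",
                       flat_hits.size)
    return tuple(int(c) for c in np.unravel_index(flat_hits[0], stat_map.shape))


def dct_f_statistic(vol: VolumeSeries, design: np.ndarray, dct: np.ndarray,
                    mask: RoiMask | None = None) -> np.ndarray:
    """Per-voxel partial F statistic for the DCT block, controlling confounds.

    The full model is [confounds+intercept, DCT]; the statistic compares its
    residual sum of squares against the confound-only model.  Voxels outside
    ``mask`` (if given) are NaN.
    """
    t = vol.n_time
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != t or dct.shape[0] != t:
        raise ValueError("design/DCT row count must equal the number of volumes")
    X0 = np.column_stack([design, np.ones(t)])
    X1 = np.column_stack([X0, dct])
    for X, label in [(X0, "confounds"), (X1, "confounds+DCT")]:
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            raise ValueError(f"rank-deficient design ({label}): rank {r} < {X.shape[1]}")

    if mask is not None:
        Y = vol.data[mask.data].T  # (t, v)
    else:
        Y = vol.data.reshape(-1, t).T
    Q0, _ = np.linalg.qr(X0)
    Q1, _ = np.linalg.qr(X1)
    R0 = Y - Q0 @ (Q0.T @ Y)
    R1 = Y - Q1 @ (Q1.T @ Y)
    rss0 = np.sum(R0 ** 2, axis=0)
    rss1 = np.sum(R1 ** 2, axis=0)
    k = dct.shape[1]
    dof = t - X1.shape[1]
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / k) / (rss1 / dof)
    out = np.full(vol.data.shape[:3], np.nan)
    if mask is not None:
        out[mask.data] = F
    else:
        out[:] = F.reshape(vol.data.shape[:3])
    return out


# ---------------------------------------------------------------------------
# Eigenvariates
# ---------------------------------------------------------------------------

def _residualize(Y: np.ndarray, confounds: np.ndarray | None,
                 protect: np.ndarray | None = None) -> np.ndarray:
    """Remove the confound (plus intercept) contribution from Y (t x v).

    With ``protect`` (e.g. the in-band DCT basis), confound betas are
    estimated jointly with the protected regressors and only the confound
    part is subtracted — the signal of interest is modelled, not absorbed
    into the nuisance fit.  This mirrors eigenvariate adjustment for an
    effects-of-interest contrast in standard GLM practice.
    """
    t = Y.shape[0]
    if confounds is None or np.size(confounds) == 0:
        C = np.ones((t, 1))
    else:
        C = np.column_stack([np.atleast_2d(confounds), np.ones(t)])
    if protect is None or protect.size == 0:
        Q, _ = np.linalg.qr(C)
        return Y - Q @ (Q.T @ Y)
    X = np.column_stack([protect, C])
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - C @ beta[protect.shape[1]:]


def extract_eigenvariate(vol: VolumeSeries, voxels: np.ndarray,
                         confounds: np.ndarray | None = None,
                         centre: tuple | None = None,
                         protect: np.ndarray | None = None) -> Eigenvariate:
    """Principal eigenvariate of a voxel set, confound-adjusted.

    Each voxel's series is residualized against the confounds (with
    intercept); the first left singular vector of the residual matrix is
    scaled to unit variance, with its sign chosen so that it correlates
    positively with the mean voxel series.  variance_explained_pct is
    s1^2 / sum s^2 * 100.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or voxels.shape[0] == 0:
        raise ValueError("voxels must be a non-empty (v, 3) index array")
    Y = vol.data[voxels[:, 0], voxels[:, 1], voxels[:, 2], :].T  # (t, v)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    R = _residualize(Y, confounds, protect=protect)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    u = U[:, 0]
    mean_series = R.mean(axis=1)
    if np.dot(u, mean_series) < 0:
        u = -u
    sd = u.std()
    if sd == 0:
        raise ValueError("degenerate eigenvariate (zero variance)")
    ve = 100.0 * s[0] ** 2 / np.sum(s ** 2)
    return Eigenvariate(series=u / sd, variance_explained_pct=float(ve),
                        sphere_centre=centre)


def sphere_voxels(vol: VolumeSeries, centre_vox: tuple, radius_mm: float,
                  mask: RoiMask | None = None) -> np.ndarray:
    """Voxels within ``radius_mm`` (world-space distance via the affine) of
    a centre voxel's world coordinate, optionally intersected with a mask.

    A radius of 0 returns the centre voxel alone.  A sphere that exits the
    volume is clipped with a warning; an empty intersection is an error.
    """
    shape = vol.data.shape[:3]
    centre_world = (vol.affine @ np.array([*centre_vox, 1.0]))[:3]
    # bounding box in voxel units (conservative, using voxel sizes)
    half = np.ceil(radius_mm / vol.voxel_size_mm).astype(int) + 1
    lo = np.array(centre_vox) - half
    hi = np.array(centre_vox) + half
    clipped = np.any(lo < 0) or np.any(hi >= shape)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(shape) - 1)
    ranges = [np.arange(a, b + 1) for a, b in zip(lo, hi)]
    gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
    idx = np.column_stack([gi.ravel(), gj.ravel(), gk.ravel()])
    world = (vol.affine @ np.column_stack([idx, np.ones(len(idx))]).T)[:3].T
    keep = np.sum((world - centre_world) ** 2, axis=1) <= radius_mm ** 2 + 1e-9
    idx = idx[keep]
    if mask is not None:
        inmask = mask.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        idx = idx[inmask]
    if clipped:
        warnings.warn("sphere clipped to the volume bounds", stacklevel=2)
    if len(idx) == 0:
        raise ValueError("sphere does not intersect the mask/volume")
    return idx


def extract_all_nodes(vol: VolumeSeries, masks: dict, motion: MotionParams,
                      nuisance: np.ndarray | None = None,
                      f_lo: float = 1.0 / 128.0, f_hi: float = 0.1,
                      m1_radius_mm: float = 6.0, sub_radius_mm: float = 4.0,
                      subject_id: str = "subject"
                      ) -> tuple[SubjectTimeSeries, dict]:
    """Run the full four-node extraction and return (time series, report).

    M1: 6 mm-radius sphere at the peak of the DCT-band F statistic within
    the motor-cortex mask.  PUT and THAL: 4 mm-radius spheres centred on
    the masked voxel whose residualized series best correlates (Pearson)
    with the M1 eigenvariate.  STN: whole-mask eigenvariate.  All
    eigenvariates are adjusted for the 6 motion regressors plus nuisance
    series; the DCT band itself is preserved (it models the signal of
    interest and is not regressed out).
    """
    t = vol.n_time
    if motion.n_time != t:
        raise ValueError("motion parameter length must match the volume")
    conf = motion.values.T
    if nuisance is not None and np.asarray(nuisance).size:
        conf = np.column_stack([conf, np.asarray(nuisance)])
    dct = dct_basis(t, vol.tr, f_lo, f_hi)

    report = {"nodes": {}, "band_hz": [f_lo, f_hi], "n_dct": int(dct.shape[1])}

    # M1: peak of the in-band F statistic inside its mask
    fmap = dct_f_statistic(vol, conf, dct, mask=masks["M1"])
    m1_centre = peak_voxel(fmap, masks["M1"])
    m1_vox = sphere_voxels(vol, m1_centre, m1_radius_mm, masks["M1"])
    ev_m1 = extract_eigenvariate(vol, m1_vox, conf, centre=m1_centre)

    series = {"M1": ev_m1}
    for name in ("PUT", "THAL"):
        mask = masks[name]
        idx = np.column_stack(np.nonzero(mask.data))
        Y = _residualize(vol.data[idx[:, 0], idx[:, 1], idx[:, 2], :].T, conf)
        Yc = Y - Y.mean(axis=0)
        m1c = ev_m1.series - ev_m1.series.mean()
        denom = np.sqrt(np.sum(Yc ** 2, axis=0) * np.sum(m1c ** 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Yc.T @ m1c) / denom
        rmap = np.full(vol.data.shape[:3], np.nan)
        rmap[idx[:, 0], idx[:, 1], idx[:, 2]] = r
        centre = peak_voxel(rmap, mask)
        vox = sphere_voxels(vol, centre, sub_radius_mm, mask)
        series[name] = extract_eigenvariate(vol, vox, conf, centre=centre)

    stn_idx = np.column_stack(np.nonzero(masks["STN"].data))
    series["STN"] = extract_eigenvariate(vol, stn_idx, conf, centre=None)

    fd, fd_mean, fd_cum = framewise_displacement(motion)
    order = ("M1", "PUT", "STN", "THAL")
    mat = np.vstack([series[k].series for k in order])
    for k in order:
        report["nodes"][k] = {
            "variance_explained_pct": series[k].variance_explained_pct,
            "sphere_centre": (list(series[k].sphere_centre)
                              if series[k].sphere_centre is not None else None),
        }
    report["fd_mean_mm"] = fd_mean
    report["fd_cumulative_mm"] = float(fd_cum[-1])
    ts = SubjectTimeSeries(node_series=mat, tr=vol.tr, subject_id=subject_id,
                           node_labels=order)
    return ts, report


# ---------------------------------------------------------------------------
# NIfTI / text I/O
# ---------------------------------------------------------------------------

def save_nifti_volume(vol: VolumeSeries, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header["pixdim"][4] = vol.tr
    nib.save(img, str(path))


def load_nifti_volume(path: str | Path, tr: float | None = None) -> VolumeSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    tr_file = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return VolumeSeries(data=data, voxel_size_mm=np.array(zooms[:3]),
                        affine=np.array(img.affine), tr=tr or tr_file or 1.0)


def save_nifti_mask(mask: RoiMask, vol: VolumeSeries, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), vol.affine), str(path))


def load_nifti_mask(path: str | Path, name: str | None = None) -> RoiMask:
    import nibabel as nib

    img = nib.load(str(path))
    return RoiMask(name=name or Path(path).stem,
                   data=np.asanyarray(img.dataobj) > 0.5)


def save_motion(motion: MotionParams, path: str | Path) -> None:
    np.savetxt(path, motion.values.T, fmt="%.8f")


def load_motion(path: str | Path) -> MotionParams:
    return MotionParams(values=np.loadtxt(path).T)
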