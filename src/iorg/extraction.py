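"""Cone reflectance signal extraction from registered AOSLO acquisitions.

An *acquisition* is a single registered video of the photoreceptor mosaic
(:class:`FrameStack`).  Given cone-center coordinates, each cone's
reflectance time course is obtained by projecting a cylindrical column
(a fixed disc of pixels) through the stack and averaging intensities per
frame.  Before extraction, frames are intensity-standardized so that
acquisitions from different sessions and subjects are comparable, and
coordinates may be refined to each acquisition's average image with a
greedy hill-climbing step.  Cones and acquisitions with too much missing
data around stimulus delivery are excluded, and the pre-stimulus mean is
subtracted from every retained signal so that downstream RMS summaries
measure stimulus-evoked deviation only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "FrameStack",
    "ConeSignalTable",
    "exclude_short_acquisitions",
    "correct_intraframe_distortion",
    "affine_register_frames",
    "standardize_frames",
    "refine_coordinates",
    "compute_column_radius",
    "extract_cone_signals",
    "apply_exclusion",
    "subtract_prestim_mean",
]


@dataclass(eq=False)
class FrameStack:
    """One registered acquisition: a T x H x W intensity stack.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Pixel intensities in arbitrary units (AU).
    valid : ndarray of bool, shape (T,)
        Per-frame validity (frames dropped by registration are invalid).
    frame_rate : float
        Frames per second.
    stimulus_frame : int
        Index of the first frame at or after stimulus delivery.
    image_region : ndarray of bool, shape (T, H, W), optional
        Per-frame mask of image-containing pixels.  When omitted, pixels
        with intensity > 0 are taken to contain image (registration fills
        empty canvas with zeros).
    """

    frames: np.ndarray
    valid: np.ndarray
    frame_rate: float
    stimulus_frame: int
    image_region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        T = self.frames.shape[0]
        if T < 2:
            raise ValueError("an acquisition needs at least 2 frames")
        if self.valid.shape != (T,):
            raise ValueError("valid must have one entry per frame")
        if not (0 <= self.stimulus_frame < T):
            raise ValueError("stimulus_frame outside [0, T)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame k at k / frame_rate)."""
        return np.arange(self.n_frames) / self.frame_rate

    def region_mask(self) -> np.ndarray:
        """Per-frame boolean mask of image-containing pixels."""
        if self.image_region is not None:
            return self.image_region
        return self.frames > 0


@dataclass(eq=False)
class ConeSignalTable:
    """Per-cone, per-frame reflectance values with a missing-data mask."""

    signal: np.ndarray  # (C, T) AU, possibly mean-subtracted
    missing: np.ndarray  # (C, T) bool
    cone_ids: np.ndarray  # (C,)
    stimulus_frame: int
    frame_rate: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.cone_ids = np.asarray(self.cone_ids)
        if self.signal.shape != self.missing.shape:
            raise ValueError("signal and missing must have congruent shapes")
        if self.signal.shape[0] != self.cone_ids.shape[0]:
            raise ValueError("one cone_id per signal row required")

    @property
    def n_cones(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def select(self, keep: np.ndarray) -> "ConeSignalTable":
        """Return a table restricted to the given cone-row mask/indices."""
        return ConeSignalTable(
            signal=self.signal[keep],
            missing=self.missing[keep],
            cone_ids=self.cone_ids[keep],
            stimulus_frame=self.stimulus_frame,
            frame_rate=self.frame_rate,
        )


def exclude_short_acquisitions(
    stacks: list[FrameStack], original_frame_count: int
) -> list[FrameStack]:
    """Drop registered acquisitions retaining less than half their frames.

    An acquisition is kept when its number of valid frames is at least
    ``original_frame_count / 2`` (exactly half is retained).
    """
    if original_frame_count <= 0:
        raise ValueError("original_frame_count must be positive")
    return [s for s in stacks if int(np.sum(s.valid)) >= original_frame_count / 2]


def _strip_translation(ref_strip: np.ndarray, mov_strip: np.ndarray) -> np.ndarray:
    """Best translation (dy, dx) aligning mov_strip to ref_strip."""
    if ref_strip.std() == 0 or mov_strip.std() == 0:
        return np.zeros(2)
    shift, _, _ = phase_cross_correlation(
        ref_strip, mov_strip, upsample_factor=10, normalization=None
    )
    return np.asarray(shift, dtype=float)


def correct_intraframe_distortion(
    stack: FrameStack, reference_frame: int, strip_height: int
) -> FrameStack:
    """Mitigate residual intra-frame (scan) distortion.

    For each horizontal strip of the reference frame, the translation
    aligning every frame's corresponding strip to it is estimated; the
    median translation over frames is taken as the distortion of that
    strip and its inverse applied to the strip in all frames.  The median
    makes the estimate robust to a minority of badly-registered frames.
    """
    if not (0 <= reference_frame < stack.n_frames) or not stack.valid[reference_frame]:
        raise ValueError("reference frame index invalid or marked invalid")
    if strip_height < 1:
        raise ValueError("strip_height must be >= 1")
    H = stack.shape[0]
    frames = stack.frames.copy()
    valid_idx = np.flatnonzero(stack.valid)
    for y0 in range(0, H, strip_height):
        y1 = min(y0 + strip_height, H)
        ref_strip = stack.frames[reference_frame, y0:y1]
        shifts = np.array(
            [_strip_translation(ref_strip, stack.frames[t, y0:y1]) for t in valid_idx]
        )
        med = np.median(shifts, axis=0)
        if np.allclose(med, 0):
            continue
        for t in range(stack.n_frames):
            # inverse of the median translation: shift the strip by +med
            frames[t, y0:y1] = ndimage.shift(
                stack.frames[t, y0:y1], med, order=1, mode="constant", cval=0.0
            )
    return replace(stack, frames=frames)


def _affine_matrix(params: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """3x3 pull-back matrix from the 6-parameter vector.

    The linear part acts about ``center`` (image center), which keeps
    rotation/scale parameters decoupled from translation during the
    search; the returned matrix is in absolute (corner-origin) pixel
    coordinates.
    """
    a, b, c, d, ty, tx = params
    lin = np.array([[1 + a, b], [c, 1 + d]])
    if center is None:
        center = np.zeros(2)
    off = center - lin @ center + np.array([ty, tx])
    return np.array(
        [[lin[0, 0], lin[0, 1], off[0]], [lin[1, 0], lin[1, 1], off[1]], [0, 0, 1]]
    )


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def affine_register_frames(
    stack: FrameStack,
    reference_frame: int,
    max_iter: int = 400,
    min_correlation: float = 0.2,
) -> tuple[FrameStack, list[np.ndarray]]:
    """Remove full-frame drift by affine registration to a reference frame.

    Each valid frame is mapped by the affine transform maximizing its
    correlation with the reference, found by a translation pre-alignment
    (phase correlation) followed by a direct search over the 6 affine
    parameters.  Frames whose registered correlation stays below
    ``min_correlation`` are flagged invalid.

    Returns the registered stack and the list of 3x3 transform matrices
    (identity for invalid frames).
    """
    if not (0 <= reference_frame < stack.n_frames) or not stack.valid[reference_frame]:
        raise ValueError("reference frame index invalid or marked invalid")
    ref = stack.frames[reference_frame]
    frames = stack.frames.copy()
    valid = stack.valid.copy()
    transforms: list[np.ndarray] = []

    for t in range(stack.n_frames):
        if not valid[t] or t == reference_frame:
            transforms.append(np.eye(3))
            continue
        mov = stack.frames[t]
        center = (np.asarray(mov.shape, dtype=float) - 1) / 2
        ones = np.ones_like(mov)
        init_shift = _strip_translation(ref, mov)
        x0 = np.array([0.0, 0.0, 0.0, 0.0, -init_shift[0], -init_shift[1]])

        def _warp(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            mat = _affine_matrix(p, center)
            warped = ndimage.affine_transform(
                mov, mat[:2, :2], offset=mat[:2, 2],
                order=1, mode="constant", cval=0.0,
            )
            support = ndimage.affine_transform(
                ones, mat[:2, :2], offset=mat[:2, 2],
                order=1, mode="constant", cval=0.0,
            ) > 0.99
            return warped, support

        def cost(p: np.ndarray) -> float:
            # correlation over the valid overlap only: canvas filled by
            # the warp must not drag the metric
            warped, support = _warp(p)
            if support.sum() < 0.25 * support.size:
                return 0.0
            return -_correlation(ref[support], warped[support])

        # direct search with steps scaled to each parameter's natural
        # magnitude (~1% for the linear part, ~0.3 px for translation)
        simplex = x0 + np.vstack(
            [np.zeros(6), np.diag([0.01, 0.01, 0.01, 0.01, 0.3, 0.3])]
        )
        res = optimize.minimize(
            cost, x0, method="Nelder-Mead",
            options={
                "maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-9,
                "initial_simplex": simplex,
            },
        )
        mat = _affine_matrix(res.x, center)
        warped, support = _warp(res.x)
        corr = _correlation(ref[support], warped[support]) if support.any() else 0.0
        if corr < min_correlation:
            warnings.warn(
                f"frame {t}: affine registration correlation {corr:.3f} below "
                f"{min_correlation}; frame flagged invalid"
            )
            valid[t] = False
            transforms.append(np.eye(3))
            continue
        frames[t] = warped
        transforms.append(mat)
    return replace(stack, frames=frames, valid=valid), transforms


def standardize_frames(
    stack: FrameStack, target_mean: float = 70.0, target_sd: float = 35.0
) -> FrameStack:
    """Standardize image-containing pixels of each frame to (mean, SD).

    Each frame's image-containing region is z-scored and rescaled to a
    mean of ``target_mean`` and SD of ``target_sd`` (defaults 70 / 35),
    removing image-wide intensity fluctuations between and within
    acquisitions while keeping values in image units.  Pixels outside the
    image region are untouched.  Frames whose region has zero variance
    are flagged invalid.
    """
    frames = stack.frames.copy()
    valid = stack.valid.copy()
    region = stack.region_mask()
    for t in range(stack.n_frames):
        if not valid[t]:
            continue
        m = region[t]
        px = frames[t][m]
        if px.size < 2 or px.std() == 0:
            valid[t] = False
            logger.warning("frame %d: zero-variance image region; flagged invalid", t)
            continue
        frames[t][m] = (px - px.mean()) / px.std() * target_sd + target_mean
    out = replace(stack, frames=frames, valid=valid)
    # region mask must survive standardization (values may now be <= 0)
    if stack.image_region is None:
        out.image_region = region
    return out


def refine_coordinates(
    avg_image: np.ndarray, coords: np.ndarray, max_radius: int = 2, max_steps: int = 10
) -> np.ndarray:
    """Refine cone centers to local maxima of an average image.

    Greedy 8-connected hill climbing from each (x, y) coordinate: move to
    the strictly brighter neighbor (ties broken in row-major order) until
    no neighbor is brighter, at most ``max_steps`` steps, never displacing
    a coordinate by more than ``max_radius`` pixels in Chebyshev distance.
    Coordinates on flat plateaus stay put.
    """
    if max_radius < 1:
        raise ValueError("max_radius must be >= 1")
    img = np.asarray(avg_image, dtype=float)
    H, W = img.shape
    out = np.array(coords, dtype=float)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for i, (x, y) in enumerate(np.rint(out).astype(int)):
        x0, y0 = x, y
        if not (0 <= y < H and 0 <= x < W):
            raise ValueError(f"coordinate {i} outside image")
        for _ in range(max_steps):
            best = img[y, x]
            bx, by = x, y
            for dy, dx in offsets:
                ny, nx = y + dy, x + dx
                if not (0 <= ny < H and 0 <= nx < W):
                    continue
                if max(abs(ny - y0), abs(nx - x0)) > max_radius:
                    continue
                if img[ny, nx] > best:
                    best = img[ny, nx]
                    bx, by = nx, ny
            if (bx, by) == (x, y):
                break
            x, y = bx, by
        out[i] = (x, y)
    return out


def compute_column_radius(
    coords: np.ndarray, fwhm_fraction: float = 0.6, min_radius: float = 1.0
) -> float:
    """Column radius from the mosaic's nearest-neighbor cone spacing.

    The column diameter covers the central full-width-half-max of a
    cone's reflectance profile, taken as ``fwhm_fraction`` of the median
    nearest-neighbor spacing; the radius is half that, floored at
    ``min_radius`` pixels.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("column radius needs >= 2 cone coordinates")
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    median_spacing = float(np.median(d[:, 1]))
    return max(min_radius, 0.5 * fwhm_fraction * median_spacing)


def extract_cone_signals(
    stack: FrameStack, coords: np.ndarray, radius: float
) -> ConeSignalTable:
    """Project a cylindrical column through the stack at each cone.

    ``signal[c, t]`` is the mean intensity over pixels whose centers lie
    within ``radius`` of cone *c* (the same disc in every frame — a
    cylinder), restricted to image-containing pixels.  Entries are
    missing when the frame is invalid or the column contains no image
    pixels in that frame.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 pixel")
    coords = np.asarray(coords, dtype=float)
    H, W = stack.shape
    region = stack.region_mask()
    T = stack.n_frames
    C = coords.shape[0]
    signal = np.zeros((C, T))
    missing = np.zeros((C, T), dtype=bool)
    flat_frames = stack.frames.reshape(T, -1)
    flat_region = region.reshape(T, -1)
    for c, (x, y) in enumerate(coords):
        y0, y1 = int(np.floor(y - radius)), int(np.ceil(y + radius)) + 1
        x0, x1 = int(np.floor(x - radius)), int(np.ceil(x + radius)) + 1
        yy, xx = np.mgrid[max(y0, 0):min(y1, H), max(x0, 0):min(x1, W)]
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= radius**2
        idx = (yy[disc] * W + xx[disc]).ravel()
        if idx.size == 0:
            missing[c] = True
            continue
        in_region = flat_region[:, idx]  # (T, n_px)
        n_px = in_region.sum(axis=1)
        vals = flat_frames[:, idx]
        full = n_px == idx.size
        sig_c = np.full(T, np.nan)
        if full.any():
            sig_c[full] = np.mean(vals[full], axis=1)
        for t in np.flatnonzero(~full & (n_px > 0)):
            sig_c[t] = np.mean(vals[t][in_region[t]])
        signal[c] = sig_c
        missing[c] = (~stack.valid) | (n_px == 0)
    signal[missing] = np.nan
    return ConeSignalTable(
        signal=signal,
        missing=missing,
        cone_ids=np.arange(C),
        stimulus_frame=stack.stimulus_frame,
        frame_rate=stack.frame_rate,
    )


def stimulus_window_frames(
    stimulus_frame: int, frame_rate: float, n_frames: int, window_s: float = 0.2
) -> np.ndarray:
    """Frame indices within ``window_s`` seconds after stimulus delivery.

    The window is [stimulus_frame, stimulus_frame + ceil(window_s * frame_rate)]
    inclusive, clipped to the acquisition.
    """
    last = stimulus_frame + int(np.ceil(window_s * frame_rate))
    return np.arange(stimulus_frame, min(last, n_frames - 1) + 1)


def apply_exclusion(
    table: ConeSignalTable,
    n_acquisitions_present: np.ndarray | None = None,
    n_acquisitions_total: int | None = None,
    stim_window_s: float = 0.2,
) -> tuple[ConeSignalTable, pd.DataFrame]:
    """Apply the per-cone missing-data exclusion rules.

    A cone is removed when any of the following holds:

    1. more than 50% of the frames within 0.2 s of stimulus delivery are
       missing (the cone may not have received the stimulus);
    2. 50% or more of the acquisition's frames are missing for the cone;
    3. the cone is present in less than 50% of the location's
       acquisitions (requires ``n_acquisitions_present``/``_total``).

    The rules are independent predicates, so their application order does
    not affect the retained set.  Returns the filtered table and a
    per-cone report with the reason(s) for exclusion.
    """
    C, T = table.signal.shape
    win = stimulus_window_frames(
        table.stimulus_frame, table.frame_rate, T, stim_window_s
    )
    frac_window_missing = table.missing[:, win].mean(axis=1)
    frac_all_missing = table.missing.mean(axis=1)
    rule_window = frac_window_missing > 0.5
    rule_whole = frac_all_missing >= 0.5
    if n_acquisitions_present is not None and n_acquisitions_total is not None:
        present = np.asarray(n_acquisitions_present, dtype=float)
        rule_acq = present < 0.5 * n_acquisitions_total
    else:
        rule_acq = np.zeros(C, dtype=bool)
    excluded = rule_window | rule_whole | rule_acq
    report = pd.DataFrame(
        {
            "cone_id": table.cone_ids,
            "excluded": excluded,
            "window_missing_gt_50pct": rule_window,
            "acquisition_missing_ge_50pct": rule_whole,
            "present_lt_50pct_acquisitions": rule_acq,
        }
    )
    return table.select(~excluded), report


def subtract_prestim_mean(
    table: ConeSignalTable,
) -> tuple[ConeSignalTable, np.ndarray]:
    """Subtract each cone's pre-stimulus mean from its whole signal.

    The pre-stimulus window is every frame strictly before the stimulus
    frame; the mean is over non-missing frames only.  Cones with no valid
    pre-stimulus frame cannot be zeroed and are excluded (their ids are
    returned alongside the new table).
    """
    pre = slice(0, table.stimulus_frame)
    sig = table.signal.copy()
    pre_missing = table.missing[:, pre]
    pre_sig = np.where(pre_missing, np.nan, sig[:, pre])
    n_pre = (~pre_missing).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(pre_sig, axis=1)
    no_prestim = n_pre == 0
    if np.any(no_prestim):
        logger.warning(
            "%d cone(s) had no valid pre-stimulus frames and were excluded",
            int(no_prestim.sum()),
        )
    sig = sig - mu[:, None]
    out = ConeSignalTable(
        signal=sig,
        missing=table.missing,
        cone_ids=table.cone_ids,
        stimulus_frame=table.stimulus_frame,
        frame_rate=table.frame_rate,
    ).select(~no_prestim)
    return out, table.cone_ids[no_prestim]
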