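"""Synthetic AOSLO acquisitions, cone mosaics, LRPs, and whole cohorts.

This module emulates the raw inputs the analysis pipeline consumes: a
1 x 1 degree field imaged at 29.4 Hz for 6 s, with a brief stimulus
delivered 2 s into each acquisition; trials of 10 acquisitions (one
no-stimulus control trial plus three stimulus trials per location); a
hexagonal-with-jitter cone mosaic; lognormally distributed per-cone
response amplitudes with a small fraction of non-responding
(S-cone-like) cells; pixel noise; frame dropout; and optional small
residual per-frame translations.  Ground truth (cone positions, true
amplitudes, dropped frames, applied transforms) is recorded in a
manifest so that pipeline output can be scored against it.

The post-stimulus reflectance fluctuation of a responding cone is a
zero-mean, fixed-magnitude random-sign process: at each post-stimulus
frame the cone's column-mean reflectance deviates from baseline by
exactly +/- its true amplitude.  The analysis only measures the RMS of
the deviation, so any zero-mean process with controlled RMS serves; the
fixed-magnitude form makes the mapping from programmed to extracted
amplitude exact, which is what lets recovery be validated to 1%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .extraction import FrameStack, compute_column_radius
from .lrp import LRP

__all__ = [
    "MosaicSpec",
    "ResponseSpec",
    "GroundTruthManifest",
    "generate_mosaic",
    "render_acquisition",
    "generate_lrp",
    "generate_cohort",
    "DEFAULT_FRAME_RATE",
    "DEFAULT_DURATION_S",
]

DEFAULT_FRAME_RATE = 29.4  # Hz
DEFAULT_DURATION_S = 6.0  # s per acquisition
BASELINE_AU = 100.0  # baseline column-mean reflectance of every cone
TIFF_SCALE = 64.0  # AU -> uint16 quantization for on-disk stacks


@dataclass
class MosaicSpec:
    """Geometry of a synthetic cone mosaic.

    spacing is the target center-to-center distance in µm; with
    ``jitter_sd = 0`` the lattice is exactly hexagonal with
    nearest-neighbor distance equal to ``spacing``.
    """

    spacing: float = 5.0  # µm
    jitter_sd: float = 0.3  # µm
    field_size: float = 1.0  # deg
    pixels_per_degree: float = 291.0  # px/deg (1 px per µm at 291 µm/deg)
    retinal_magnification: float = 291.0  # µm/deg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def px_per_um(self) -> float:
        return self.pixels_per_degree / self.retinal_magnification

    @property
    def field_px(self) -> float:
        return self.field_size * self.pixels_per_degree


@dataclass
class ResponseSpec:
    """Statistical structure of per-cone stimulus-evoked responses.

    Per-cone true amplitudes are 10**N(mean_log_amplitude,
    sd_log_amplitude) AU; a ``nonresponder_fraction`` of cones (putative
    S cones, which the stimulus barely excites) have amplitude 0.
    ``noise_sd`` is additive Gaussian pixel noise in AU.
    """

    mean_log_amplitude: float = 1.25  # log10 AU; population-RMS ~ 34 AU
    sd_log_amplitude: float = 0.35  # log10 AU; ~decade spread of cone amplitudes
    nonresponder_fraction: float = 0.05
    noise_sd: float = 15.0  # AU, per pixel
    dropout_fraction: float = 0.05
    stimulus_time: float = 2.0  # s into the acquisition
    response_duration: float = 1.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nonresponder_fraction", "dropout_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruthManifest:
    """Ground truth for one rendered acquisition."""

    cone_positions: list  # [(x_px, y_px), ...]
    cone_true_amplitude: list  # AU per cone
    excluded_frames: list  # dropped frame indices
    applied_affine: list  # per-frame 2x3 transforms (row-major lists)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_mosaic(spec: MosaicSpec) -> np.ndarray:
    """Generate cone-center coordinates (x_px, y_px) on a jittered hexagonal lattice.

    Rows are spaced ``spacing * sqrt(3)/2`` apart with alternate rows
    offset by half a spacing; positions are then perturbed by isotropic
    Gaussian jitter of SD ``jitter_sd``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    s_px = spec.spacing * spec.px_per_um
    jitter_px = spec.jitter_sd * spec.px_per_um
    row_h = s_px * np.sqrt(3) / 2
    extent = spec.field_px
    pts = []
    j = 0
    y = 0.0
    while y <= extent:
        x0 = (j % 2) * s_px / 2
        n_in_row = int(np.floor((extent - x0) / s_px)) + 1
        xs = x0 + s_px * np.arange(n_in_row)
        pts.append(np.column_stack([xs, np.full(n_in_row, y)]))
        j += 1
        y = j * row_h
    coords = np.vstack(pts)
    if jitter_px > 0:
        coords = coords + rng.normal(0.0, jitter_px, size=coords.shape)
        # keep jittered cones inside the field
        coords = np.clip(coords, 0.51, max(extent, 1.0))
    return coords


def _stimulus_frame_index(times: np.ndarray, stimulus_time: float) -> int:
    idx = int(np.searchsorted(times, stimulus_time, side="left"))
    if idx >= times.size:
        raise ValueError("stimulus_time beyond the end of the acquisition")
    return idx


def render_acquisition(
    coords: np.ndarray,
    resp: ResponseSpec,
    frame_rate: float = DEFAULT_FRAME_RATE,
    duration: float = DEFAULT_DURATION_S,
    amplitudes: np.ndarray | None = None,
    acquisition_index: int = 0,
    stimulated: bool = True,
    motion_sd_px: float = 0.0,
    fwhm_fraction: float = 0.6,
    shape: tuple[int, int] | None = None,
) -> tuple[FrameStack, GroundTruthManifest]:
    """Render one acquisition of the mosaic as a frame stack.

    Cones are drawn as isotropic Gaussians with FWHM equal to
    ``fwhm_fraction`` of the mosaic's median nearest-neighbor spacing.
    Each cone's Gaussian is scaled so that its *column mean* (over the
    disc an extraction with the same ``fwhm_fraction`` would use) equals
    the programmed baseline-plus-deviation reflectance — rendering and
    extraction are therefore calibrated to the same units.

    Per-cone true amplitudes are drawn from ``resp`` unless given
    explicitly (pass the same array to render repeated acquisitions of
    one retinal location).  ``acquisition_index`` decorrelates the noise,
    response-sign, dropout, and motion streams between acquisitions that
    share a seed.  A no-stimulus control acquisition is rendered with
    ``stimulated=False``.
    """
    coords = np.asarray(coords, dtype=float)
    T = int(round(duration * frame_rate))
    if T < 2:
        raise ValueError("duration * frame_rate must be >= 2 frames")
    times = np.arange(T) / frame_rate
    stim_frame = _stimulus_frame_index(times, resp.stimulus_time)

    spacing_px = _median_nn_spacing(coords)
    sigma = fwhm_fraction * spacing_px / (2 * np.sqrt(2 * np.log(2)))
    half = int(np.ceil(3 * sigma)) + 1
    if shape is None:
        H = W = int(np.ceil(coords.max() + half + 1))
    else:
        H, W = shape
    if np.any(coords < 0) or np.any(coords[:, 0] > W - 1) or np.any(coords[:, 1] > H - 1):
        raise ValueError("cone coordinates outside frame bounds")

    rng_amp = np.random.default_rng(resp.seed)
    C = coords.shape[0]
    if amplitudes is None:
        amplitudes = draw_cone_amplitudes(C, resp, rng_amp)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (C,):
        raise ValueError("one amplitude per cone required")

    rng_acq = np.random.default_rng((resp.seed, 1 + acquisition_index))

    # Per-cone stamps, plus the crosstalk matrix M where M[c, n] is the
    # mean of cone n's Gaussian over cone c's extraction disc (in-frame
    # pixels only).  Rendering peak amplitudes as M^-1 @ (programmed
    # column means) makes an extraction using the same fwhm_fraction
    # recover the programmed baseline and deviations exactly, neighbor
    # overlap included.
    radius = compute_column_radius(coords, fwhm_fraction=fwhm_fraction)
    stamps = []
    gains = np.empty(C)
    disc_px = []
    for c, (x, y) in enumerate(coords):
        cy, cx = int(round(y)), int(round(x))
        yy, xx = np.mgrid[cy - half:cy + half + 1, cx - half:cx + half + 1]
        prof = np.exp(-(((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)))
        disc = (
            ((yy - y) ** 2 + (xx - x) ** 2 <= radius**2)
            & (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        )
        gains[c] = prof[disc].mean()
        stamps.append((yy, xx, prof))
        disc_px.append(np.column_stack([xx[disc], yy[disc]]).astype(float))

    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import splu
    from scipy.spatial import cKDTree as _KDTree

    cutoff = 2 * (3 * sigma + radius)
    neighbor_tree = _KDTree(coords)
    M = lil_matrix((C, C))
    for c in range(C):
        px = disc_px[c]
        for n in neighbor_tree.query_ball_point(coords[c], cutoff):
            # evaluate neighbor n's *truncated* stamp over cone c's disc,
            # exactly as the rendered frames will contain it
            cy, cx = int(round(coords[n, 1])), int(round(coords[n, 0]))
            inside = (np.abs(px[:, 0] - cx) <= half) & (np.abs(px[:, 1] - cy) <= half)
            d2 = ((px - coords[n]) ** 2).sum(axis=1)
            overlap = float(np.mean(np.where(inside, np.exp(-d2 / (2 * sigma**2)), 0.0)))
            if overlap > 0:
                M[c, n] = overlap
    M_lu = splu(M.tocsc())

    # response deviations: +/- amplitude at each post-stimulus frame
    t_stim = times[stim_frame]
    active = (times > t_stim) & (times <= t_stim + resp.response_duration)
    dev = np.zeros((C, T))
    if stimulated:
        signs = rng_acq.choice([-1.0, 1.0], size=(C, int(active.sum())))
        dev[:, active] = amplitudes[:, None] * signs

    # frame dropout
    n_drop = int(np.floor(resp.dropout_fraction * T))
    dropped = np.sort(rng_acq.choice(T, size=n_drop, replace=False)) if n_drop else np.array([], dtype=int)
    valid = np.ones(T, dtype=bool)
    valid[dropped] = False

    # residual per-frame translation, recorded in the manifest
    if motion_sd_px > 0:
        shifts = rng_acq.normal(0.0, motion_sd_px, size=(T, 2))
    else:
        shifts = np.zeros((T, 2))

    frames = np.zeros((T, H, W))
    support = np.zeros((H, W), dtype=bool)
    clipped = []
    for c in range(C):
        yy, xx, prof = stamps[c]
        m = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        support[yy[m], xx[m]] = True
        clipped.append((yy[m], xx[m], prof[m], m))
    moving = motion_sd_px > 0
    if not moving:
        # static mosaic: render the crosstalk-calibrated baseline image
        # once, add per-frame response deltas only when cones deviate
        base_peaks = M_lu.solve(np.full(C, BASELINE_AU))
        base = np.zeros((H, W))
        for c in range(C):
            yy, xx, prof, _ = clipped[c]
            base[yy, xx] += base_peaks[c] * prof
    for t in range(T):
        dx, dy = shifts[t]
        if moving:
            # motion breaks the static calibration; render uncalibrated
            # Gaussians scaled by the per-cone disc gain instead
            f = frames[t]
            for c in range(C):
                yy, xx, prof = stamps[c]
                x, y = coords[c, 0] + dx, coords[c, 1] + dy
                prof = np.exp(-(((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)))
                m = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
                f[yy[m], xx[m]] += ((BASELINE_AU + dev[c, t]) / gains[c]) * prof[m]
        else:
            f = frames[t]
            f[:] = base
            if dev[:, t].any():
                delta_peaks = M_lu.solve(dev[:, t])
                for c in np.flatnonzero(delta_peaks):
                    yy, xx, prof, _ = clipped[c]
                    f[yy, xx] += delta_peaks[c] * prof
        if resp.noise_sd > 0:
            noise = rng_acq.normal(0.0, resp.noise_sd, size=(H, W))
            f[support] = np.maximum(f[support] + noise[support], 1.0 / TIFF_SCALE)

    stack = FrameStack(
        frames=frames,
        valid=valid,
        frame_rate=frame_rate,
        stimulus_frame=stim_frame,
        image_region=np.broadcast_to(support, frames.shape).copy(),
    )
    affines = [
        [[1.0, 0.0, float(shifts[t, 0])], [0.0, 1.0, float(shifts[t, 1])]]
        for t in range(T)
    ]
    manifest = GroundTruthManifest(
        cone_positions=[[float(x), float(y)] for x, y in coords],
        cone_true_amplitude=[float(a) for a in amplitudes],
        excluded_frames=[int(i) for i in dropped],
        applied_affine=affines,
    )
    return stack, manifest


def draw_cone_amplitudes(
    n_cones: int, resp: ResponseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-cone true amplitudes (AU): lognormal with S-cone-like zeros."""
    amps = 10.0 ** rng.normal(resp.mean_log_amplitude, resp.sd_log_amplitude, n_cones)
    amps[rng.random(n_cones) < resp.nonresponder_fraction] = 0.0
    return amps


def _median_nn_spacing(coords: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(coords).query(coords, k=2)
    return float(np.median(d[:, 1]))


def generate_lrp(
    os_length: float,
    peak_sd: float = 3.0,
    noise_sd: float = 0.0,
    depth_step: float = 0.5,
    seed: int = 0,
) -> LRP:
    """Synthesize a longitudinal reflectance profile with EZ and IZ peaks.

    Two unit-height Gaussian peaks (SD ``peak_sd`` µm) separated by
    ``os_length`` µm on a uniform depth grid, plus additive Gaussian
    noise of SD ``noise_sd`` (AU; peak height is 1).
    """
    if os_length <= 0 or depth_step <= 0:
        raise ValueError("os_length and depth_step must be positive")
    if os_length <= 2 * depth_step:
        raise ValueError("os_length <= 2 * depth_step: peaks unresolvable")
    rng = np.random.default_rng(seed)
    margin = max(5.0, 4.0 * peak_sd)
    depth = np.arange(0.0, os_length + 2 * margin + depth_step / 2, depth_step)
    ez, iz = margin, margin + os_length
    refl = np.exp(-((depth - ez) ** 2) / (2 * peak_sd**2)) + np.exp(
        -((depth - iz) ** 2) / (2 * peak_sd**2)
    )
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, depth.size)
    return LRP(depth=depth, reflectance=refl)


def write_stack_tiff(path: Path, stack: FrameStack) -> None:
    """Write a frame stack as a 16-bit multi-frame grayscale TIFF."""
    data = np.clip(np.round(stack.frames * TIFF_SCALE), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_stack_tiff(
    path: Path,
    frame_rate: float,
    stimulus_frame: int,
    valid: np.ndarray | None = None,
) -> FrameStack:
    """Read a 16-bit stack written by :func:`write_stack_tiff` back to AU."""
    data = tifffile.imread(str(path)).astype(float) / TIFF_SCALE
    if valid is None:
        valid = np.ones(data.shape[0], dtype=bool)
    return FrameStack(
        frames=data, valid=np.asarray(valid, bool),
        frame_rate=frame_rate, stimulus_frame=stimulus_frame,
    )


def generate_cohort(
    control_spec: ResponseSpec,
    disease_spec: ResponseSpec,
    eccentricities: list[float],
    n_subjects: int,
    seed: int,
    out_dir: str | Path,
    mosaic_spec: MosaicSpec | None = None,
    n_stim_trials: int = 3,
    n_acquisitions: int = 10,
    frame_rate: float = DEFAULT_FRAME_RATE,
    duration: float = DEFAULT_DURATION_S,
    ecc_amplitude_scale: dict | None = None,
    disease_spacing_factor: float = 1.3,
    write_tiffs: bool = True,
) -> dict:
    """Generate a synthetic two-arm cohort on disk.

    ``n_subjects`` subjects are split between arms (first half control,
    remainder disease).  For every subject x eccentricity, one
    no-stimulus control trial and ``n_stim_trials`` stimulus trials of
    ``n_acquisitions`` acquisitions each are rendered, along with cone
    coordinates, a synthetic LRP whose OS length follows the bundled
    normative eccentricity profile, and a ground-truth manifest.
    Response amplitude scales with eccentricity via
    ``ecc_amplitude_scale`` (default: the normative control amplitude
    profile, normalized to 1 degree); disease-arm mosaics are sparser by
    ``disease_spacing_factor``.

    Returns the cohort manifest (also written as
    ``cohort_manifest.json``); deterministic and byte-identical for a
    fixed seed.
    """
    from .datasets import load_normative_controls

    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    norm = load_normative_controls()
    if ecc_amplitude_scale is None:
        amp = norm[norm.metric == "iORG_amplitude"].set_index("eccentricity_deg")["mean"]
        base = amp.iloc[0]
        ecc_amplitude_scale = {
            e: float(np.interp(e, amp.index.to_numpy(), amp.to_numpy()) / base)
            for e in eccentricities
        }
    os_prof = norm[norm.metric == "OS_length"].set_index("eccentricity_deg")
    nnd_prof = norm[norm.metric == "NND"].set_index("eccentricity_deg")

    base_mosaic = mosaic_spec or MosaicSpec()
    n_control = (n_subjects + 1) // 2
    manifest: dict = {"seed": seed, "subjects": []}
    master = np.random.default_rng(seed)
    for s in range(n_subjects):
        arm = "control" if s < n_control else "disease"
        spec = control_spec if arm == "control" else disease_spec
        subj_id = f"{arm}{s:02d}"
        subj_seed = int(master.integers(2**31))
        subj_dir = out_dir / subj_id
        subj_rec: dict = {"subject_id": subj_id, "arm": arm, "seed": subj_seed, "locations": []}
        for e_i, ecc in enumerate(eccentricities):
            loc_dir = subj_dir / f"ecc_{ecc:g}"
            loc_dir.mkdir(parents=True, exist_ok=True)
            loc_seed = subj_seed + 1000 * e_i
            spacing = float(
                np.interp(ecc, nnd_prof.index.to_numpy(), nnd_prof["mean"].to_numpy())
            )
            if arm == "disease":
                spacing *= disease_spacing_factor
            mspec = MosaicSpec(
                spacing=spacing,
                jitter_sd=base_mosaic.jitter_sd,
                field_size=base_mosaic.field_size,
                pixels_per_degree=base_mosaic.pixels_per_degree,
                retinal_magnification=base_mosaic.retinal_magnification,
                seed=loc_seed,
            )
            coords = generate_mosaic(mspec)
            pd.DataFrame(coords, columns=["x_px", "y_px"]).to_csv(
                loc_dir / "coords.csv", index=False
            )
            scale = ecc_amplitude_scale.get(ecc, 1.0)
            loc_resp = ResponseSpec(
                mean_log_amplitude=spec.mean_log_amplitude + np.log10(scale),
                sd_log_amplitude=spec.sd_log_amplitude,
                nonresponder_fraction=spec.nonresponder_fraction,
                noise_sd=spec.noise_sd,
                dropout_fraction=spec.dropout_fraction,
                stimulus_time=spec.stimulus_time,
                response_duration=spec.response_duration,
                seed=loc_seed,
            )
            amps = draw_cone_amplitudes(
                coords.shape[0], loc_resp, np.random.default_rng(loc_seed)
            )
            trials = ["control"] + [f"stim{k + 1}" for k in range(n_stim_trials)]
            loc_rec = {
                "eccentricity_deg": ecc,
                "seed": loc_seed,
                "spacing_um": spacing,
                "trials": {},
                "cone_true_amplitude": [float(a) for a in amps],
            }
            acq_counter = 0
            for trial in trials:
                tdir = loc_dir / f"trial_{trial}"
                tdir.mkdir(exist_ok=True)
                acq_files = []
                for a in range(n_acquisitions):
                    stack, gt = render_acquisition(
                        coords,
                        loc_resp,
                        frame_rate=frame_rate,
                        duration=duration,
                        amplitudes=amps,
                        acquisition_index=acq_counter,
                        stimulated=(trial != "control"),
                    )
                    fname = f"acq_{a:02d}.tif"
                    if write_tiffs:
                        write_stack_tiff(tdir / fname, stack)
                    acq_files.append(
                        {
                            "file": fname,
                            "stimulus_frame": int(stack.stimulus_frame),
                            "excluded_frames": gt.excluded_frames,
                        }
                    )
                    acq_counter += 1
                loc_rec["trials"][trial] = acq_files
            # synthetic LRP for this location
            os_mu = float(np.interp(ecc, os_prof.index.to_numpy(), os_prof["mean"].to_numpy()))
            os_sd = float(np.interp(ecc, os_prof.index.to_numpy(), os_prof["sd"].to_numpy()))
            rng_os = np.random.default_rng(loc_seed + 7)
            os_true = max(os_mu + rng_os.normal(0, os_sd), 6.0)
            if arm == "disease":
                os_true = max(0.6 * os_true, 6.0)
            prof = generate_lrp(os_true, noise_sd=0.05, seed=loc_seed + 8)
            pd.DataFrame(
                {"depth_um": prof.depth, "reflectance": prof.reflectance}
            ).to_csv(loc_dir / "lrp.csv", index=False)
            loc_rec["os_length_true_um"] = float(os_true)
            subj_rec["locations"].append(loc_rec)
        manifest["subjects"].append(subj_rec)
    manifest["n_trials"] = n_subjects * len(eccentricities) * (1 + n_stim_trials)
    manifest["n_acquisitions"] = manifest["n_trials"] * n_acquisitions
    with open(out_dir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
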