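"""End-to-end orchestration: simulate -> extract -> summarize -> report.

`run_pipeline` drives a complete synthetic-cohort experiment through the
same analysis stages a real study uses: cohort generation, cone signal
extraction with exclusion rules, population- and individual-RMS
summaries and amplitudes, mosaic and outer-segment structural metrics
with normative z-scores, per-subject photometry, and cohort statistics
(structure-function regressions, Spearman correlation against retinal
sensitivity, healthy-cone fractions).  Every stage is seeded from the
run configuration, and a provenance manifest (config hash, package and
dependency versions) accompanies the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_normative_controls
from .extraction import (
    apply_exclusion,
    compute_column_radius,
    exclude_short_acquisitions,
    extract_cone_signals,
    refine_coordinates,
    standardize_frames,
    subtract_prestim_mean,
)
from .lrp import LRP, detect_os_length
from .mosaic import NormativeStats, bound_nnd, z_score
from .photometry import PhotometryParams, photon_density
from .rms import (
    NormativeDistribution,
    extract_amplitude,
    individual_rms_all,
    population_rms,
)
from .stats import linear_fit_with_pi, pair_sensitivity, spearman, SensitivityRecord
from .synthetic import (
    DEFAULT_DURATION_S,
    DEFAULT_FRAME_RATE,
    MosaicSpec,
    ResponseSpec,
    generate_cohort,
    read_stack_tiff,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort pipeline run.

    Defaults reproduce the study conditions: 6-s acquisitions at
    29.4 Hz with the stimulus 2 s in, trials of 10 acquisitions (one
    no-stimulus control trial plus three stimulus trials per location),
    and a 1 x 1 degree field.
    """

    seed: int = 0
    n_subjects: int = 2
    eccentricities: list = field(default_factory=lambda: [1.0, 4.0])
    frame_rate: float = DEFAULT_FRAME_RATE
    duration_s: float = DEFAULT_DURATION_S
    n_stim_trials: int = 3
    n_acquisitions: int = 10
    # demo-scale field by default; set {"field_size": 1.0} for full-field runs
    mosaic: dict = field(default_factory=lambda: {"field_size": 0.1, "jitter_sd": 0.3})
    control_response: dict = field(default_factory=dict)  # ResponseSpec overrides
    disease_response: dict = field(default_factory=lambda: {"mean_log_amplitude": 1.2})
    standardize: bool = True
    refine: bool = False
    fwhm_fraction: float = 0.6
    amplitude_window_s: float = 1.0
    summary_mode: str = "per_trial"  # or "pooled"
    photometry: dict = field(default_factory=dict)  # PhotometryParams overrides
    normative_table: str | None = None  # CSV path; bundled table when None

    def mosaic_spec(self, **extra) -> MosaicSpec:
        return MosaicSpec(**{"seed": self.seed, **self.mosaic, **extra})

    def response_spec(self, arm: str) -> ResponseSpec:
        overrides = self.control_response if arm == "control" else self.disease_response
        return ResponseSpec(**{"seed": self.seed, **overrides})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _extract_location(
    loc_dir: Path,
    loc_rec: dict,
    cfg: RunConfig,
) -> tuple[list, np.ndarray, float]:
    """Extraction stage for one subject x eccentricity location.

    Reads the stimulus-trial stacks, applies standardization and
    (optionally) coordinate refinement, projects cone columns, applies
    the missing-data exclusion rules, and subtracts pre-stimulus means.
    Returns (per-acquisition signal tables, retained cone ids, column
    radius in px).
    """
    coords = pd.read_csv(loc_dir / "coords.csv")[["x_px", "y_px"]].to_numpy()
    T_original = int(round(cfg.duration_s * cfg.frame_rate))
    stacks = []
    trial_of_stack = []
    for trial, acqs in loc_rec["trials"].items():
        if trial == "control":
            continue
        for acq in acqs:
            valid = np.ones(T_original, dtype=bool)
            valid[acq["excluded_frames"]] = False
            stack = read_stack_tiff(
                loc_dir / f"trial_{trial}" / acq["file"],
                frame_rate=cfg.frame_rate,
                stimulus_frame=acq["stimulus_frame"],
                valid=valid,
            )
            stacks.append(stack)
            trial_of_stack.append(trial)
    kept = exclude_short_acquisitions(stacks, T_original)
    kept_trials = [tr for st, tr in zip(stacks, trial_of_stack) if st in kept]

    radius = compute_column_radius(coords, fwhm_fraction=cfg.fwhm_fraction)
    tables = []
    for stack in kept:
        if cfg.standardize:
            stack = standardize_frames(stack)
        c = coords
        if cfg.refine:
            avg = np.nanmean(
                np.where(stack.valid[:, None, None], stack.frames, np.nan), axis=0
            )
            c = refine_coordinates(avg, coords, max_radius=max(1, int(radius)))
        table = extract_cone_signals(stack, c, radius)
        table, _ = apply_exclusion(table)
        table, _ = subtract_prestim_mean(table)
        tables.append(table)
    if not tables:
        return [], np.array([]), radius
    # acquisition-count rule: cones present in < 50% of acquisitions
    n_total = len(tables)
    all_ids = np.unique(np.concatenate([t.cone_ids for t in tables]))
    present = np.array(
        [sum(cid in t.cone_ids for t in tables) for cid in all_ids], dtype=float
    )
    keep_ids = set(all_ids[present >= 0.5 * n_total])
    tables = [
        t.select(np.isin(t.cone_ids, list(keep_ids))) for t in tables
    ]
    return list(zip(tables, kept_trials)), np.array(sorted(keep_ids)), radius


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run the full pipeline; returns the results directory.

    Emits six artifact classes under ``<out_dir>/results``: population
    RMS traces, amplitude tables (population and individual), CDF
    tables, mosaic/OS metrics with z-scores, a cohort statistics report,
    and a provenance manifest.  Deterministic for a fixed config.
    """
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    res_dir = out_dir / "results"
    res_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: generating synthetic cohort")
    manifest = generate_cohort(
        cfg.response_spec("control"),
        cfg.response_spec("disease"),
        cfg.eccentricities,
        cfg.n_subjects,
        cfg.seed,
        sim_dir,
        mosaic_spec=cfg.mosaic_spec(),
        n_stim_trials=cfg.n_stim_trials,
        n_acquisitions=cfg.n_acquisitions,
        frame_rate=cfg.frame_rate,
        duration=cfg.duration_s,
    )
    # synthetic retinal sensitivities per subject x eccentricity
    rng_sens = np.random.default_rng(cfg.seed + 99)
    sens_rows = []
    for subj in manifest["subjects"]:
        for loc in subj["locations"]:
            ecc = loc["eccentricity_deg"]
            base = 30.0 - 1.2 * ecc
            if subj["arm"] == "disease":
                base -= 5.0
            sens_rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "eccentricity_deg": ecc,
                    "sensitivity_db": float(np.clip(base + rng_sens.normal(0, 1), 0, 36)),
                }
            )
    sens_df = pd.DataFrame(sens_rows)
    sens_df.to_csv(sim_dir / "sensitivities.csv", index=False)

    norm_table = (
        pd.read_csv(cfg.normative_table)
        if cfg.normative_table
        else load_normative_controls()
    )

    logger.info("stage extract+summarize: per-location signal extraction and RMS")
    trace_rows, pop_rows, indiv_rows, cdf_rows, metric_rows = [], [], [], [], []
    mosaic_scale_um_per_px = 1.0 / cfg.mosaic_spec().px_per_um
    for subj in manifest["subjects"]:
        subj_dir = sim_dir / subj["subject_id"]
        for loc in subj["locations"]:
            ecc = loc["eccentricity_deg"]
            loc_dir = subj_dir / f"ecc_{ecc:g}"
            pairs, keep_ids, radius = _extract_location(loc_dir, loc, cfg)
            if not pairs:
                logger.warning(
                    "no usable acquisitions at %s ecc %g", subj["subject_id"], ecc
                )
                continue
            tables = [t for t, _ in pairs]
            trials = [tr for _, tr in pairs]
            # population-RMS per acquisition
            per_acq_amp = []
            for i, (table, trial) in enumerate(pairs):
                trace = population_rms(table)
                rec = extract_amplitude(trace, window=cfg.amplitude_window_s)
                per_acq_amp.append({"trial": trial, "amplitude": rec.amplitude})
                for t_i in range(trace.values.size):
                    trace_rows.append(
                        {
                            "subject_id": subj["subject_id"],
                            "eccentricity_deg": ecc,
                            "trial": trial,
                            "acquisition": i,
                            "time_s": float(trace.time[t_i]),
                            "rms_au": float(trace.values[t_i]),
                            "n_contributing": int(trace.n_contributing[t_i]),
                        }
                    )
            amp_df = pd.DataFrame(per_acq_amp)
            if cfg.summary_mode == "per_trial":
                loc_amp = float(amp_df.groupby("trial")["amplitude"].mean().mean())
            else:
                loc_amp = float(amp_df["amplitude"].mean())
            pop_rows.append(
                {
                    "subject_id": subj["subject_id"],
                    "arm": subj["arm"],
                    "eccentricity_deg": ecc,
                    "population_amplitude_au": loc_amp,
                    "n_acquisitions_used": len(tables),
                    "column_radius_px": radius,
                }
            )
            # individual-RMS amplitudes
            traces = individual_rms_all(tables)
            for cid, tr in traces.items():
                try:
                    rec = extract_amplitude(tr, window=cfg.amplitude_window_s)
                except ValueError:
                    continue
                indiv_rows.append(
                    {
                        "subject_id": subj["subject_id"],
                        "arm": subj["arm"],
                        "eccentricity_deg": ecc,
                        "cone_id": int(cid),
                        "amplitude_au": rec.amplitude,
                        "log_amplitude": rec.log_amplitude,
                    }
                )
            # structural metrics
            coords = pd.read_csv(loc_dir / "coords.csv")[["x_px", "y_px"]].to_numpy()
            nnd = bound_nnd(coords, scale=mosaic_scale_um_per_px)
            lrp_df = pd.read_csv(loc_dir / "lrp.csv")
            os_res = detect_os_length(
                LRP(lrp_df["depth_um"].to_numpy(), lrp_df["reflectance"].to_numpy())
            )
            row = {
                "subject_id": subj["subject_id"],
                "arm": subj["arm"],
                "eccentricity_deg": ecc,
                "mean_nnd_um": nnd.mean_bound_nnd,
                "n_bound": nnd.n_bound_cones,
                "os_length_um": os_res.os_length_um,
                "os_qc_warning": os_res.qc_warning,
            }
            for metric, value in (("NND", nnd.mean_bound_nnd), ("OS_length", os_res.os_length_um)):
                sel = norm_table[
                    (norm_table.metric == metric)
                    & (np.isclose(norm_table.eccentricity_deg, ecc))
                ]
                if not sel.empty:
                    ref = NormativeStats(
                        eccentricity=ecc, metric=metric,
                        mean=float(sel.iloc[0]["mean"]), sd=float(sel.iloc[0]["sd"]),
                    )
                    row[f"z_{metric.lower()}"] = z_score(value, ref)
                    row[f"z_{metric.lower()}_abs"] = z_score(value, ref, absolute=True)
            metric_rows.append(row)

    traces_df = pd.DataFrame(trace_rows)
    pop_df = pd.DataFrame(pop_rows)
    indiv_df = pd.DataFrame(indiv_rows)
    traces_df.to_csv(res_dir / "population_traces.csv", index=False)
    pop_df.to_csv(res_dir / "population_amplitudes.csv", index=False)
    indiv_df.to_csv(res_dir / "individual_amplitudes.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(res_dir / "mosaic_metrics.csv", index=False)

    logger.info("stage summarize: CDFs and healthy fractions")
    from .rms import amplitude_cdf

    healthy_rows = []
    for ecc in cfg.eccentricities:
        ctrl = indiv_df[
            (indiv_df.arm == "control")
            & (indiv_df.eccentricity_deg == ecc)
            & np.isfinite(indiv_df.log_amplitude)
        ]["log_amplitude"].to_numpy()
        if ctrl.size == 0:
            continue
        normative = NormativeDistribution.from_sample(ctrl)
        for (subj_id, arm), grp in indiv_df[indiv_df.eccentricity_deg == ecc].groupby(
            ["subject_id", "arm"]
        ):
            vals = grp["log_amplitude"].to_numpy()
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            x, f = amplitude_cdf(vals)
            for xv, fv in zip(x, f):
                cdf_rows.append(
                    {
                        "subject_id": subj_id,
                        "eccentricity_deg": ecc,
                        "log_amplitude": float(xv),
                        "cumulative_probability": float(fv),
                    }
                )
            from .rms import healthy_fraction

            healthy_rows.append(
                {
                    "subject_id": subj_id,
                    "arm": arm,
                    "eccentricity_deg": ecc,
                    "healthy_fraction": healthy_fraction(vals, normative),
                    "p5_threshold_log_au": normative.p5_threshold,
                    "n_cones": int(vals.size),
                }
            )
    pd.DataFrame(cdf_rows).to_csv(res_dir / "amplitude_cdf.csv", index=False)
    healthy_df = pd.DataFrame(healthy_rows)

    logger.info("stage stats: cohort statistics")
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    merged = pop_df.merge(
        pd.DataFrame(metric_rows)[
            ["subject_id", "eccentricity_deg", "mean_nnd_um", "os_length_um"]
        ],
        on=["subject_id", "eccentricity_deg"],
    )
    ctrl = merged[merged.arm == "control"]
    if len(ctrl) >= 3 and ctrl["os_length_um"].nunique() > 1:
        fit = linear_fit_with_pi(ctrl["os_length_um"], ctrl["population_amplitude_au"])
        report["control_amplitude_vs_os_length"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "p_value": fit.p_value,
        }
    sens_vals = []
    for r in merged.itertuples():
        subj_sens = sens_df[sens_df.subject_id == r.subject_id]
        recs = [
            SensitivityRecord(s.eccentricity_deg, s.sensitivity_db)
            for s in subj_sens.itertuples()
        ]
        paired = pair_sensitivity([r.eccentricity_deg], recs)
        sens_vals.append(float(paired["sensitivity_db"].iloc[0]))
    merged = merged.assign(sensitivity_db=sens_vals)
    if merged["sensitivity_db"].nunique() > 1 and len(merged) >= 4:
        rho, p = spearman(
            merged["population_amplitude_au"], merged["sensitivity_db"], seed=cfg.seed
        )
        report["amplitude_vs_sensitivity_spearman"] = {"rho": rho, "p_value": p}
    report["arm_mean_population_amplitude"] = {
        arm: float(g["population_amplitude_au"].mean())
        for arm, g in merged.groupby("arm")
    }
    if not healthy_df.empty:
        report["arm_mean_healthy_fraction"] = {
            arm: float(g["healthy_fraction"].mean())
            for arm, g in healthy_df.groupby("arm")
        }
        healthy_df.to_csv(res_dir / "healthy_fractions.csv", index=False)

    # photometry for the bundled cohort parameters (or config overrides)
    pparams = PhotometryParams(**cfg.photometry)
    report["photon_density_default_um2"] = photon_density(pparams)
    with open(res_dir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    import scipy
    provenance = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "iorg_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
    }
    with open(res_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", res_dir)
    return res_dir
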