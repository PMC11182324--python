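"""Bundled printed tables: cohort demographics and normative control statistics."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_participants", "load_normative_controls", "normative_stats_for"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("iorg.data").joinpath(name).open("r") as fh:
        # keep literal "None" diagnoses as strings, not NaN
        return pd.read_csv(fh, keep_default_na=False)


def load_participants() -> pd.DataFrame:
    """Cohort demographics and per-subject stimulus photon density.

    Columns: subject_id, study_eye, diagnosis, inheritance_pattern,
    sex_at_birth, age_years, axial_length_mm, photon_density_um2.
    Controls have diagnosis 'None' or 'Amblyopia OS'; all others carry a
    retinal-degeneration diagnosis.
    """
    df = _read("participants.csv")
    df["is_control"] = df["diagnosis"].isin(["None", "Amblyopia OS"])
    return df


def load_normative_controls() -> pd.DataFrame:
    """Control mean/SD per eccentricity for NND (µm), OS length (µm),
    and population-RMS iORG amplitude (AU)."""
    return _read("normative_controls.csv")


def normative_stats_for(metric: str, eccentricity: float):
    """Normative stats for one metric at one eccentricity (exact match)."""
    from .mosaic import NormativeStats

    df = load_normative_controls()
    row = df[(df.metric == metric) & (df.eccentricity_deg == eccentricity)]
    if row.empty:
        raise KeyError(f"no normative entry for {metric} at {eccentricity} deg")
    r = row.iloc[0]
    return NormativeStats(
        eccentricity=float(r.eccentricity_deg),
        metric=metric,
        mean=float(r["mean"]),
        sd=float(r.sd),
    )
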