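"""RMS summaries of stimulus-evoked cone reflectance signals.

Two complementary summaries condense mean-subtracted cone signals into a
single response time course:

* **population-RMS** — the frame-wise RMS across all cones of one
  acquisition, ``RMS_pop[t] = sqrt( (1/n) * sum_c R_c[t]^2 )``;
* **individual-RMS** — the frame-wise RMS of one cone across all of its
  acquisitions, ``RMS_indiv[t] = sqrt( (1/m) * sum_a R_a[t]^2 )``.

Each RMS trace is reduced to a scalar *amplitude*: the 99th percentile of
the RMS within one second after stimulus delivery minus the mean RMS
within one second before delivery.  Individual-cone amplitudes have a
standard deviation proportional to their mean, so they are log-
transformed (base 10) before being summarized with an empirical CDF.  A
normative (control) amplitude distribution yields a 5th-percentile
threshold — chosen because roughly 5% of cones are S cones, which the
stimulus does not appreciably excite — against which the fraction of
putatively healthy cones in any sample is scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .extraction import ConeSignalTable

logger = logging.getLogger(__name__)

__all__ = [
    "RMSTrace",
    "AmplitudeRecord",
    "NormativeDistribution",
    "population_rms",
    "individual_rms",
    "individual_rms_all",
    "extract_amplitude",
    "log_transform",
    "amplitude_cdf",
    "healthy_fraction",
]


@dataclass(eq=False)
class RMSTrace:
    """Per-frame RMS values with their timebase.

    ``n_contributing[t]`` counts the non-missing terms in the RMS at
    frame t (cones for a population trace, acquisitions for an
    individual trace); frames with no contributing terms are NaN.
    """

    values: np.ndarray
    time: np.ndarray
    stimulus_frame: int
    n_contributing: np.ndarray
    kind: str  # "population" | "individual"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.kind not in ("population", "individual"):
            raise ValueError("kind must be 'population' or 'individual'")

    @property
    def stimulus_time(self) -> float:
        return float(self.time[self.stimulus_frame])


@dataclass
class AmplitudeRecord:
    prestim_mean: float
    poststim_p99: float
    amplitude: float
    log_amplitude: float  # NaN when amplitude <= 0

    @property
    def valid_log(self) -> bool:
        return np.isfinite(self.log_amplitude)


@dataclass
class NormativeDistribution:
    """Sorted control-cone log amplitudes and their 5th-percentile threshold."""

    log_amplitudes: np.ndarray
    p5_threshold: float

    @classmethod
    def from_sample(cls, log_amplitudes: np.ndarray, percentile: float = 5.0):
        vals = np.sort(np.asarray(log_amplitudes, dtype=float))
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("normative sample is empty")
        return cls(log_amplitudes=vals, p5_threshold=float(np.percentile(vals, percentile)))


def _rms_over_rows(signal: np.ndarray, missing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise RMS over axis 0, ignoring missing entries.

    The squared terms are accumulated row by row (numpy reduces over the
    leading axis sequentially), matching a naive loop exactly.
    """
    sq = np.where(missing, 0.0, signal) ** 2
    n = (~missing).sum(axis=0)
    total = np.zeros(signal.shape[1])
    for row in sq:  # accumulate in row order: matches a naive loop bit-for-bit
        total += row
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n > 0, np.sqrt(total / np.maximum(n, 1)), np.nan)
    return values, n


def population_rms(table: ConeSignalTable) -> RMSTrace:
    """Frame-wise RMS of all cones in a single acquisition.

    ``values[t] = sqrt( (1/n_t) * sum_c R_c[t]^2 )`` over the cones
    non-missing at frame t.  The table must already be pre-stimulus
    mean-subtracted.
    """
    if table.n_cones == 0:
        raise ValueError("population RMS of an empty cone table")
    values, n = _rms_over_rows(table.signal, table.missing)
    return RMSTrace(
        values=values,
        time=table.times(),
        stimulus_frame=table.stimulus_frame,
        n_contributing=n,
        kind="population",
    )


def individual_rms(acquisitions: list[ConeSignalTable], cone_id) -> RMSTrace:
    """Frame-wise RMS of a single cone across all of its acquisitions.

    ``values[t] = sqrt( (1/m_t) * sum_a R_a[t]^2 )`` over the
    acquisitions in which the cone is non-missing at frame t.
    """
    rows = []
    miss = []
    ref = None
    for acq in acquisitions:
        hit = np.flatnonzero(acq.cone_ids == cone_id)
        if hit.size == 0:
            continue
        rows.append(acq.signal[hit[0]])
        miss.append(acq.missing[hit[0]])
        ref = acq
    if ref is None:
        raise ValueError(f"cone {cone_id!r} absent from every acquisition")
    signal = np.vstack(rows)
    missing = np.vstack(miss)
    values, m = _rms_over_rows(signal, missing)
    return RMSTrace(
        values=values,
        time=ref.times(),
        stimulus_frame=ref.stimulus_frame,
        n_contributing=m,
        kind="individual",
    )


def individual_rms_all(acquisitions: list[ConeSignalTable]) -> dict:
    """Individual-RMS traces for every cone appearing in any acquisition."""
    ids: list = []
    for acq in acquisitions:
        for cid in acq.cone_ids:
            if cid not in ids:
                ids.append(cid)
    return {cid: individual_rms(acquisitions, cid) for cid in ids}


def extract_amplitude(trace: RMSTrace, window: float = 1.0) -> AmplitudeRecord:
    """Response amplitude of an RMS trace.

    Amplitude = (99th percentile of the RMS within ``window`` seconds
    after stimulus delivery) - (mean RMS within ``window`` seconds
    before delivery).  Windows are [t_stim - window, t_stim) and
    (t_stim, t_stim + window]; missing frames are dropped, and the
    percentile linearly interpolates between order statistics.
    """
    t_stim = trace.stimulus_time
    t = trace.time
    finite = np.isfinite(trace.values)
    pre = finite & (t >= t_stim - window) & (t < t_stim)
    post = finite & (t > t_stim) & (t <= t_stim + window)
    if pre.sum() < 2 or post.sum() < 2:
        raise ValueError("amplitude windows need >= 2 non-missing frames each")
    prestim_mean = float(np.mean(trace.values[pre]))
    poststim_p99 = float(np.percentile(trace.values[post], 99))
    amplitude = poststim_p99 - prestim_mean
    return AmplitudeRecord(
        prestim_mean=prestim_mean,
        poststim_p99=poststim_p99,
        amplitude=amplitude,
        log_amplitude=log_transform(amplitude) if amplitude > 0 else np.nan,
    )


def log_transform(amplitude: float, base: float = 10.0) -> float:
    """Log-transform a positive amplitude (base 10 by default)."""
    if amplitude <= 0:
        raise ValueError("log transform requires a positive amplitude")
    return float(np.log(amplitude) / np.log(base))


def amplitude_cdf(log_amplitudes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative distribution of log amplitudes.

    Returns (sorted values, F) describing the right-continuous step
    function with F(min) = 1/n and F(max) = 1.  Non-finite entries
    (flagged non-positive amplitudes) are excluded with a log message.
    """
    vals = np.asarray(log_amplitudes, dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        logger.info("amplitude_cdf: dropping %d non-finite log amplitude(s)", bad.sum())
        vals = vals[~bad]
    if vals.size == 0:
        raise ValueError("empirical CDF of an empty sample")
    x = np.sort(vals)
    f = np.arange(1, x.size + 1) / x.size
    return x, f


def evaluate_cdf(x: np.ndarray, f: np.ndarray, q: float) -> float:
    """Evaluate a right-continuous empirical CDF at q."""
    return float(f[np.searchsorted(x, q, side="right") - 1]) if q >= x[0] else 0.0


def healthy_fraction(log_amplitudes: np.ndarray, normative: NormativeDistribution) -> float:
    """Fraction of cones responding at least as well as the normative 5th percentile.

    A fully healthy mosaic scores ~0.95 against its own normative
    distribution (the bottom 5% being putative S cones).
    """
    vals = np.asarray(log_amplitudes, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("healthy fraction of an empty sample")
    return float(np.mean(vals >= normative.p5_threshold))
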