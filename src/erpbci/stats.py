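"""Aptitude statistics: rank correlations of oddball ERP features with
speller error counts, signed-r2 spatio-temporal maps, peak-correlation
tables, the median-split group contrast and the accuracy estimate.

All correlations are Spearman rank correlations (average ranks for ties)
with p-values from the t-approximation on n-2 degrees of freedom;
significance is assumed at p < 0.05.  The per-participant performance
variable is the error count averaged over sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import COMPONENTS
from .erp import ANALYSIS_CHANNELS, PeakTable
from .errors import InvalidArgumentError, UndefinedCorrelationError

ALPHA = 0.05           # significance threshold
TABLE_MASK_P = 0.1     # peak-table readability mask: hide correlations above


@dataclass
class AptitudeDataset:
    """One participant's aggregated data: mean error count across sessions,
    component peak table, and the deviant-average feature matrix."""

    participant: str
    mean_errors: float
    peak_table: PeakTable
    feature_matrix: np.ndarray  # channels x time (uV)
    sessions: int = 1

    def __post_init__(self) -> None:
        if self.mean_errors < 0:
            raise InvalidArgumentError("mean_errors must be >= 0")
        if self.sessions < 1:
            raise InvalidArgumentError("sessions must be >= 1")


@dataclass
class CorrelationMap:
    """Per (channel, time) Spearman rho, signed r2 and p-value."""

    rho: np.ndarray
    signed_r2: np.ndarray
    p_value: np.ndarray
    channel_labels: tuple[str, ...]
    time_ms: np.ndarray
    p_adjusted: np.ndarray | None = None  # optional Benjamini-Hochberg


@dataclass
class MedianSplitResult:
    """Pooled-variance t contrast of high- vs low-aptitude groups on the Cz
    P3 peak (high-aptitude group first, i.e. the low-error half)."""

    n_high_aptitude: int
    n_low_aptitude: int
    df: int
    amp_mean_high: float
    amp_mean_low: float
    t_amplitude: float
    p_amplitude: float
    lat_mean_high: float
    lat_mean_low: float
    t_latency: float
    p_latency: float
    split_errors: float = field(default=float("nan"))


def spearman_rho(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _rank_correlation_grid(features: np.ndarray, errors: np.ndarray,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman of errors against every (channel, time) cell."""
    n = errors.size
    fr = sps.rankdata(features, axis=0)
    er = sps.rankdata(errors)
    fr = fr - fr.mean(axis=0)
    er = er - er.mean()
    denom = np.sqrt((fr ** 2).sum(axis=0) * (er ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.tensordot(er, fr, axes=(0, 0)) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def correlation_map(datasets: list[AptitudeDataset],
                    channel_labels: tuple[str, ...],
                    time_ms: np.ndarray,
                    benjamini_hochberg: bool = False) -> CorrelationMap:
    """Spearman correlation of every deviant-average sample with the mean
    error count across participants; signed r2 = sign(rho) * rho^2.

    No multiple-testing correction is applied by default (the high comparison
    count is addressed by the individually-calculated peak table instead); a
    Benjamini-Hochberg adjusted p map is available on request.
    """
    if len(datasets) < 4:
        raise InvalidArgumentError("need >= 4 participants")
    shapes = {d.feature_matrix.shape for d in datasets}
    if len(shapes) != 1:
        raise InvalidArgumentError(f"mismatched feature-matrix shapes: {shapes}")
    features = np.stack([d.feature_matrix for d in datasets])
    errors = np.array([d.mean_errors for d in datasets])

    rho, p = _rank_correlation_grid(features, errors)
    signed_r2 = np.sign(rho) * rho ** 2

    p_adj = None
    if benjamini_hochberg:
        flat = p.ravel()
        order = np.argsort(flat)
        m = flat.size
        adj = flat[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        p_adj = np.empty(m)
        p_adj[order] = np.minimum(adj, 1.0)
        p_adj = p_adj.reshape(p.shape)

    return CorrelationMap(rho=rho, signed_r2=signed_r2, p_value=p,
                          channel_labels=channel_labels,
                          time_ms=np.asarray(time_ms), p_adjusted=p_adj)


def peak_correlation_table(datasets: list[AptitudeDataset],
                           mask_p: float | None = TABLE_MASK_P,
                           channels: tuple[str, ...] = ANALYSIS_CHANNELS,
                           ) -> pd.DataFrame:
    """Correlations of component peak amplitudes and latencies with the mean
    error count, per component and channel.

    Correlations with p above ``mask_p`` are masked (NaN) for readability, as
    in the published table; ``*_significant`` flags mark p < 0.05 (the
    published boldface rule).  Pass ``mask_p=None`` to keep all values.
    """
    if len(datasets) < 4:
        raise InvalidArgumentError("need >= 4 participants")
    for d in datasets:
        for comp in COMPONENTS:
            for ch in channels:
                if (comp, ch) not in d.peak_table.amplitude:
                    raise InvalidArgumentError(
                        f"participant {d.participant}: missing {comp} peak "
                        f"at {ch}")
    errors = np.array([d.mean_errors for d in datasets])

    rows = []
    for comp in COMPONENTS:
        for ch in channels:
            amps = np.array([d.peak_table.amplitude[(comp, ch)]
                             for d in datasets])
            lats = np.array([d.peak_table.latency[(comp, ch)]
                             for d in datasets])
            amp_rho, amp_p = spearman_rho(amps, errors)
            lat_rho, lat_p = spearman_rho(lats, errors)
            row = {
                "component": comp, "channel": ch,
                "amp_mean_uV": amps.mean(), "amp_sd_uV": amps.std(ddof=1),
                "amp_rho": amp_rho, "amp_p": amp_p,
                "amp_significant": amp_p < ALPHA,
                "lat_mean_ms": lats.mean(), "lat_sd_ms": lats.std(ddof=1),
                "lat_rho": lat_rho, "lat_p": lat_p,
                "lat_significant": lat_p < ALPHA,
            }
            if mask_p is not None:
                if amp_p > mask_p:
                    row["amp_rho"] = float("nan")
                if lat_p > mask_p:
                    row["lat_rho"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def median_split_compare(datasets: list[AptitudeDataset],
                         component: str = "P3",
                         channel: str = "Cz") -> MedianSplitResult:
    """Split the cohort at the median error count and compare the groups'
    P3 amplitude and latency at Cz with pooled-variance two-sample t-tests.

    Participants at or below the median (including the middle participant of
    an odd-sized cohort) form the high-aptitude (low-error) group.
    """
    if len(datasets) < 4:
        raise InvalidArgumentError("need >= 4 participants")
    errors = np.array([d.mean_errors for d in datasets])
    med = float(np.median(errors))
    high_apt = [d for d in datasets if d.mean_errors <= med]
    low_apt = [d for d in datasets if d.mean_errors > med]
    if len(high_apt) < 2 or len(low_apt) < 2:
        raise InvalidArgumentError("median split produced a group of size < 2")

    def peaks(group):
        a = np.array([d.peak_table.amplitude[(component, channel)] for d in group])
        l = np.array([d.peak_table.latency[(component, channel)] for d in group])
        return a, l

    a_hi, l_hi = peaks(high_apt)
    a_lo, l_lo = peaks(low_apt)

    def pooled_t(a, b):
        if np.ptp(np.concatenate([a, b])) == 0:  # degenerate: no variance
            return 0.0, 1.0
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return float(t), float(p)

    t_amp, p_amp = pooled_t(a_hi, a_lo)
    t_lat, p_lat = pooled_t(l_hi, l_lo)
    return MedianSplitResult(
        n_high_aptitude=len(high_apt), n_low_aptitude=len(low_apt),
        df=len(high_apt) + len(low_apt) - 2,
        amp_mean_high=float(a_hi.mean()), amp_mean_low=float(a_lo.mean()),
        t_amplitude=float(t_amp), p_amplitude=float(p_amp),
        lat_mean_high=float(l_hi.mean()), lat_mean_low=float(l_lo.mean()),
        t_latency=float(t_lat), p_latency=float(p_lat),
        split_errors=med)


def estimate_accuracy_percent(required: float, mean_errors: float) -> int:
    """Accuracy estimate for an errors-based task: the required correct
    selections out of (required + mean_errors) total, as a rounded percent."""
    if required <= 0:
        raise InvalidArgumentError("required must be > 0")
    if mean_errors < 0:
        raise InvalidArgumentError("mean_errors must be >= 0")
    return int(round(100.0 * required / (required + mean_errors)))
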