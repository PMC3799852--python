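"""Condition-average ERPs and component peak extraction.

Peaks are the extremal strict local optimum of the component's polarity
inside its detection window (N1: minimum 100-200 ms, P2: maximum 200-250 ms,
N2: minimum 250-375 ms, P3: maximum 250-700 ms), with fallback to the
window's global extremum and earliest-latency tie-breaking.  For channels
posterior to Cz the reported amplitude is sign-inverted: the common average
reference flips the apparent polarity of fronto-centrally dominant
components at posterior sites, and the inversion restores comparable signs
across the scalp.  Latencies are never inverted, and re-negating inverted
amplitudes recovers the raw values exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COMPONENT_POLARITY, COMPONENT_WINDOWS, COMPONENTS
from .errors import EmptyConditionError, InvalidArgumentError
from .recording import POSTERIOR_TO_CZ, EpochSet

#: Channels whose peaks enter the group analysis.
ANALYSIS_CHANNELS = ("Fz", "Cz", "Pz", "Oz")


@dataclass(frozen=True)
class PeakWindowSpec:
    component: str
    window: tuple[float, float]
    polarity: str  # "min" | "max"

    def __post_init__(self) -> None:
        if self.polarity not in ("min", "max"):
            raise InvalidArgumentError(f"polarity must be min/max, "
                                       f"got {self.polarity!r}")


def default_peak_specs() -> list[PeakWindowSpec]:
    return [PeakWindowSpec(c, COMPONENT_WINDOWS[c], COMPONENT_POLARITY[c])
            for c in COMPONENTS]


@dataclass
class PeakTable:
    """Per (component, channel) amplitude (uV) and latency (ms).

    ``inversion_set`` records the channels whose amplitudes were negated so
    raw scalp values are recoverable by re-negation.
    """

    amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    latency: dict[tuple[str, str], float] = field(default_factory=dict)
    inversion_set: tuple[str, ...] = POSTERIOR_TO_CZ

    def to_frame(self, participant: str = "") -> pd.DataFrame:
        rows = []
        for (comp, ch), amp in self.amplitude.items():
            rows.append({
                "participant": participant, "component": comp, "channel": ch,
                "amplitude_uV": amp, "latency_ms": self.latency[(comp, ch)],
                "inverted": ch in self.inversion_set,
            })
        return pd.DataFrame(rows)

    def raw_amplitude(self, component: str, channel: str) -> float:
        """Amplitude in the raw (non-inverted) scalp convention."""
        a = self.amplitude[(component, channel)]
        return -a if channel in self.inversion_set else a


def average_erp(epochs: EpochSet, condition: str) -> np.ndarray:
    """Arithmetic mean over epochs of one condition: channels x samples."""
    mask = epochs.labels == condition
    if not mask.any():
        raise EmptyConditionError(f"no epochs labelled {condition!r}")
    return epochs.data[mask].mean(axis=0)


def detect_peak(wave: np.ndarray, time_ms: np.ndarray,
                spec: PeakWindowSpec) -> tuple[float, float]:
    """Peak of a single-channel waveform: (amplitude uV, latency ms).

    Picks the extremal strict local optimum of the requested polarity in the
    window; falls back to the window's global extremum when no strict local
    optimum exists.  Ties break toward the earliest latency.
    """
    wave = np.asarray(wave, dtype=float)
    lo, hi = spec.window
    if lo < time_ms[0] or hi > time_ms[-1] + (time_ms[1] - time_ms[0]):
        raise InvalidArgumentError(
            f"window {spec.window} outside time axis "
            f"[{time_ms[0]:.1f}, {time_ms[-1]:.1f}] ms")
    idx = np.where((time_ms >= lo) & (time_ms <= hi))[0]
    if idx.size == 0:
        raise InvalidArgumentError("window contains no samples")

    w = wave if spec.polarity == "max" else -wave
    # strict local maxima of w inside the window (neighbors from full wave)
    cand = [i for i in idx
            if 0 < i < wave.size - 1 and w[i] > w[i - 1] and w[i] > w[i + 1]]
    if cand:
        best = max(w[cand])
        i = next(i for i in cand if w[i] == best)  # earliest-latency tie-break
    else:
        seg = w[idx]
        i = idx[int(np.argmax(seg))]  # argmax breaks ties toward earliest
    return float(wave[i]), float(time_ms[i])


def component_peak_table(target_erp: np.ndarray, time_ms: np.ndarray,
                         channel_labels: tuple[str, ...],
                         specs: list[PeakWindowSpec] | None = None,
                         channels: tuple[str, ...] = ANALYSIS_CHANNELS,
                         posterior_set: tuple[str, ...] = POSTERIOR_TO_CZ,
                         ) -> PeakTable:
    """Extract all component peaks per channel, inverting reported amplitudes
    at posterior channels.

    Detection runs on the raw waveform with the component's natural polarity;
    only the reported amplitude value is negated for posterior channels.
    That is the convention under which the published group table shows, e.g.,
    positive occipital N1 amplitudes for a minimum-polarity component at the
    component's usual latency.
    """
    specs = specs if specs is not None else default_peak_specs()
    table = PeakTable(inversion_set=tuple(posterior_set))
    for ch in channels:
        if ch not in channel_labels:
            raise InvalidArgumentError(f"channel {ch!r} missing from data")
        wave = target_erp[channel_labels.index(ch)]
        for spec in specs:
            amp, lat = detect_peak(wave, time_ms, spec)
            if ch in posterior_set:
                amp = -amp
            table.amplitude[(spec.component, ch)] = amp
            table.latency[(spec.component, ch)] = lat
    return table


def difference_topography(target_erp: np.ndarray, nontarget_erp: np.ndarray,
                          time_ms: np.ndarray,
                          times: list[float]) -> dict[float, np.ndarray]:
    """Target-minus-non-target value per channel at each requested time
    (nearest-sample lookup)."""
    if target_erp.shape != nontarget_erp.shape:
        raise InvalidArgumentError("ERP shapes differ")
    diff = target_erp - nontarget_erp
    out = {}
    for t in times:
        if t < time_ms[0] or t > time_ms[-1]:
            raise InvalidArgumentError(f"time {t} ms outside epoch")
        out[t] = diff[:, int(np.argmin(np.abs(time_ms - t)))].copy()
    return out
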