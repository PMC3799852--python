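"""Offline signal conditioning: two-way least-squares FIR band-pass, AMUSE
blind source separation for ocular-artifact removal, common average
reference, epoching and baseline correction — applied in that order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    EmptyResultError,
    InvalidArgumentError,
    SignalTooShortError,
)
from .recording import FRONTAL_SET, ContinuousRecording, EpochSet, Event

logger = logging.getLogger(__name__)

#: Whitening keeps eigenvalues above this fraction of the largest, which
#: tolerates the rank deficiency a common average reference introduces.
WHITEN_RTOL = 1e-10

#: Defaults of the deterministic ocular-component rule.
OCULAR_LF_CUT_HZ = 3.0
OCULAR_POWER_FRAC = 0.6


def _firls_taps(fs: float, cutoff: float) -> int:
    """Least-squares FIR order heuristic: 3 x (fs / cutoff), rounded to odd."""
    taps = int(3 * fs / cutoff)
    return taps + 1 if taps % 2 == 0 else taps


def bandpass_filter(rec: ContinuousRecording, low: float = 0.5,
                    high: float = 20.0) -> ContinuousRecording:
    """Zero-phase band-pass: least-squares FIR high-pass at ``low`` followed
    by low-pass at ``high``, each applied forward and backward (filtfilt).

    Transition bands are 15% of the corner frequency, mirroring common EEG
    least-squares filter practice.
    """
    ny = rec.fs / 2.0
    if not (0.0 <= low < high < ny):
        raise InvalidArgumentError(
            f"need 0 <= low < high < fs/2, got low={low}, high={high}, fs={rec.fs}")

    data = rec.data
    trans = 0.15
    stages = []
    if low > 0:
        taps = _firls_taps(rec.fs, low)
        h = signal.firls(taps, [0.0, low * (1 - trans), low, ny],
                         [0.0, 0.0, 1.0, 1.0], fs=rec.fs)
        stages.append(("high-pass", low, h))
    taps = _firls_taps(rec.fs, high)
    h = signal.firls(taps, [0.0, high, min(high * (1 + trans), ny * 0.99), ny],
                     [1.0, 1.0, 0.0, 0.0], fs=rec.fs)
    stages.append(("low-pass", high, h))

    for _name, _corner, h in stages:
        if rec.n_samples <= 3 * len(h):
            raise SignalTooShortError(
                f"{rec.n_samples} samples too short for a {len(h)}-tap "
                f"two-way filter (need > {3 * len(h)})")
        data = signal.filtfilt(h, [1.0], data, axis=1)

    return rec.with_data(
        data, step=f"two-way least-squares FIR band-pass {low}-{high} Hz")


@dataclass
class AmuseDecomposition:
    """AMUSE decomposition: whitening, unmixing/mixing and lagged sources.

    Components are ordered by descending eigenvalue of the symmetrized
    lag-``lag`` covariance of the whitened data.
    """

    whitening: np.ndarray       # (rank, channels)
    unmixing: np.ndarray        # (components, channels)
    mixing: np.ndarray          # (channels, components)
    sources: np.ndarray         # (components, samples)
    lag_eigenvalues: np.ndarray  # descending
    mean: np.ndarray            # per-channel mean removed before whitening
    lag: int
    rank: int


def amuse_decompose(rec: ContinuousRecording, lag: int = 1) -> AmuseDecomposition:
    """AMUSE: whiten the centered data, eigendecompose the symmetrized
    lag-``lag`` covariance of the whitened data, and order components by
    descending lag eigenvalue.

    Sources are mutually uncorrelated at lag 0 (identity zero-lag covariance).
    If the channel covariance is rank deficient (e.g. after CAR), the
    decomposition is computed on the retained subspace and a warning logged.
    """
    if lag < 1:
        raise InvalidArgumentError(f"lag must be >= 1, got {lag}")
    x = rec.data
    n_ch, n_samp = x.shape
    if n_samp <= max(n_ch, lag):
        raise InvalidArgumentError("need more samples than channels and lag")

    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean

    c0 = xc @ xc.T / n_samp
    evals, evecs = np.linalg.eigh(c0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > WHITEN_RTOL * evals[0]
    rank = int(keep.sum())
    if rank < n_ch:
        logger.warning("rank-deficient covariance: retaining %d of %d "
                       "components", rank, n_ch)
    whitening = (evecs[:, keep] / np.sqrt(evals[keep])).T  # (rank, channels)
    z = whitening @ xc

    # symmetrized lagged covariance of whitened data
    c_tau = z[:, lag:] @ z[:, :-lag].T / (n_samp - lag)
    c_sym = 0.5 * (c_tau + c_tau.T)
    lam, u = np.linalg.eigh(c_sym)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]

    unmixing = u.T @ whitening                    # (rank, channels)
    mixing = np.linalg.pinv(unmixing)             # (channels, rank)
    sources = unmixing @ xc
    return AmuseDecomposition(
        whitening=whitening, unmixing=unmixing, mixing=mixing,
        sources=sources, lag_eigenvalues=lam, mean=mean, lag=lag, rank=rank)


def identify_ocular_components(dec: AmuseDecomposition,
                               labels: tuple[str, ...],
                               fs: float,
                               lf_cut: float = OCULAR_LF_CUT_HZ,
                               power_frac: float = OCULAR_POWER_FRAC,
                               frontal_set: tuple[str, ...] = FRONTAL_SET,
                               ) -> list[int]:
    """Deterministic ocular-component rule: a component is ocular when the
    fraction of its source power below ``lf_cut`` exceeds ``power_frac`` AND
    its mixing column's absolute weight peaks at a frontal channel.

    An empty result is valid (no qualifying component).
    """
    if not 0.0 < power_frac < 1.0:
        raise InvalidArgumentError("power_frac must be in (0, 1)")
    frontal_idx = {labels.index(ch) for ch in frontal_set if ch in labels}
    picked = []
    nper = min(dec.sources.shape[1], 4096)
    for k in range(dec.sources.shape[0]):
        freqs, psd = signal.welch(dec.sources[k], fs=fs, nperseg=nper)
        total = psd.sum()
        if total <= 0:
            continue
        frac = psd[freqs < lf_cut].sum() / total
        col = np.abs(dec.mixing[:, k])
        if frac > power_frac and int(np.argmax(col)) in frontal_idx:
            picked.append(k)
    return picked


def remove_components(rec: ContinuousRecording, dec: AmuseDecomposition,
                      drop: list[int]) -> ContinuousRecording:
    """Reconstruct the recording with the given source components zeroed.

    Dropping nothing reproduces the input (up to the whitening-retained
    subspace, i.e. exactly for full-rank inputs).
    """
    n_comp = dec.sources.shape[0]
    for k in drop:
        if not 0 <= k < n_comp:
            raise InvalidArgumentError(f"component index {k} out of range "
                                       f"(0..{n_comp - 1})")
    keep = np.ones(n_comp, dtype=bool)
    keep[list(drop)] = False
    clean = dec.mixing[:, keep] @ dec.sources[keep] + dec.mean
    return rec.with_data(
        clean, step=f"AMUSE(lag={dec.lag}) removed components {sorted(drop)}")


def remove_ocular_artifacts(rec: ContinuousRecording, lag: int = 1,
                            lf_cut: float = OCULAR_LF_CUT_HZ,
                            power_frac: float = OCULAR_POWER_FRAC,
                            ) -> tuple[ContinuousRecording, list[int]]:
    """Convenience: AMUSE decomposition + ocular rule + reconstruction."""
    dec = amuse_decompose(rec, lag=lag)
    drop = identify_ocular_components(dec, rec.channel_labels, rec.fs,
                                      lf_cut=lf_cut, power_frac=power_frac)
    return remove_components(rec, dec, drop), drop


def apply_car(rec: ContinuousRecording) -> ContinuousRecording:
    """Common average reference: subtract the cross-channel mean per sample."""
    if rec.n_channels < 2:
        raise InvalidArgumentError("CAR needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(data, step="common average reference", reference="CAR")


def epoch_and_baseline(rec: ContinuousRecording,
                       window: tuple[float, float] = (0.0, 800.0),
                       baseline: tuple[float, float] | None = (-100.0, 0.0),
                       ) -> EpochSet:
    """Cut one epoch per stimulus event and baseline-correct per channel.

    The epoch spans the union of ``window`` and ``baseline`` (half-open in
    samples).  Events whose epoch would exceed the recording are dropped with
    a logged count.  ``baseline=None`` skips baseline correction (the
    single-trial classification path).
    """
    if not rec.events:
        raise InvalidArgumentError("recording has no events to epoch")
    lo_ms = min(window[0], baseline[0]) if baseline else window[0]
    hi_ms = window[1]
    start = int(round(lo_ms / 1000.0 * rec.fs))
    stop = int(round(hi_ms / 1000.0 * rec.fs))
    if stop <= start:
        raise InvalidArgumentError("empty epoch window")
    time_ms = np.arange(start, stop) / rec.fs * 1000.0

    kept: list[Event] = []
    chunks = []
    dropped = 0
    for ev in rec.events:
        a, b = ev.sample + start, ev.sample + stop
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        chunks.append(rec.data[:, a:b])
        kept.append(ev)
    if dropped:
        logger.info("dropped %d boundary epochs of %d", dropped, len(rec.events))
    if not kept:
        raise EmptyResultError("all epochs dropped at recording boundaries")

    data = np.stack(chunks, axis=0)
    if baseline is not None:
        sel = (time_ms >= baseline[0]) & (time_ms < baseline[1])
        if not sel.any():
            raise InvalidArgumentError("baseline window has no samples")
        data = data - data[:, :, sel].mean(axis=2, keepdims=True)

    labels = np.array([ev.code for ev in kept])
    return EpochSet(
        data=data, time=time_ms, labels=labels, fs=rec.fs,
        channel_labels=rec.channel_labels,
        baseline_window=baseline, reference=rec.reference,
        provenance=list(rec.provenance) + [
            f"epochs {window[0]}-{window[1]} ms, baseline {baseline}, "
            f"{len(kept)} kept / {dropped} dropped"],
        events=kept)


def preprocess_oddball(rec: ContinuousRecording,
                       low: float = 0.5, high: float = 20.0,
                       window: tuple[float, float] = (0.0, 800.0),
                       baseline: tuple[float, float] = (-100.0, 0.0),
                       ) -> EpochSet:
    """The full offline chain in its fixed order:
    filter -> AMUSE ocular removal -> CAR -> epoch -> baseline."""
    rec = bandpass_filter(rec, low, high)
    rec, _ = remove_ocular_artifacts(rec)
    rec = apply_car(rec)
    return epoch_and_baseline(rec, window, baseline)
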