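"""Continuous EEG simulation for oddball and speller sessions.

ERP responses are sums of Gaussian-windowed component waveforms (asymmetric
for P3: fast rise, slow decay) projected through the fixed per-component
scalp topographies of :mod:`erpbci.cohort`.  Background activity is
1/f-shaped noise with a shared low-rank spatial component; ocular artifacts
are frontally-weighted 400 ms raised-cosine transients with Poisson
arrivals.  Everything is deterministic under the provided seed.
"""

from __future__ import annotations

import numpy as np

from .cohort import (
    COMPONENTS,
    STANDARD_SENSORY_FRACTION,
    TOPOGRAPHIES,
    WAVEFORM_SD_MS,
    OddballSpec,
    SpellerSpec,
    VirtualParticipant,
)
from .errors import InvalidArgumentError, InvalidSpecError
from .recording import MONTAGE_16, ContinuousRecording, Event

DEFAULT_FS = 256.0

#: ERP template support (ms after stimulus onset); responses are identically
#: zero outside, so consecutive oddball epochs (960 ms asynchrony) never
#: overlap within the 0-800 ms analysis window.
TEMPLATE_SUPPORT_MS = 800.0

#: Blink artifact: raised-cosine transient.
BLINK_DUR_MS = 400.0
BLINK_AMP_UV = 100.0
BLINK_TOPOGRAPHY = np.array([0.90, 1.00, 0.90, 0.25, 0.25, 0.45, 0.50, 0.45,
                             0.25, 0.25, 0.15, 0.15, 0.15, 0.05, 0.05, 0.05])

#: Fraction of noise variance carried by the shared low-rank spatial part.
NOISE_SHARED_FRAC = 0.35
# three smooth spatial patterns: global, anterior-posterior, left-right
_NOISE_PATTERNS = np.array([
    np.ones(16),
    [1.0, 1.0, 1.0, 0.5, 0.5, 0.3, 0.3, 0.3, 0.0, 0.0,
     -0.4, -0.4, -0.4, -0.9, -0.9, -1.0],
    [1.0, 0.0, -1.0, 1.0, -1.0, 0.7, 0.0, -0.7, 0.6, -0.6,
     0.5, 0.0, -0.5, 0.6, -0.6, 0.0],
]).T  # (16, 3)


def _component_wave(comp: str, t_ms: np.ndarray, lat_ms: float) -> np.ndarray:
    """Unit-amplitude waveform of a component at latency ``lat_ms``."""
    sd = WAVEFORM_SD_MS[comp]
    d = t_ms - lat_ms
    if isinstance(sd, tuple):  # asymmetric (rise, decay)
        sd_arr = np.where(d < 0, sd[0], sd[1])
        return np.exp(-0.5 * (d / sd_arr) ** 2)
    return np.exp(-0.5 * (d / sd) ** 2)


def template_time_axis(fs: float = DEFAULT_FS) -> np.ndarray:
    n = int(round(TEMPLATE_SUPPORT_MS / 1000.0 * fs))
    return np.arange(n) / fs * 1000.0


def erp_template(p: VirtualParticipant, components: dict[str, float],
                 fs: float = DEFAULT_FS) -> np.ndarray:
    """Channels x samples response built from ``components`` (name -> gain)."""
    t = template_time_axis(fs)
    out = np.zeros((len(MONTAGE_16), t.size))
    for comp, gain in components.items():
        if gain == 0.0:
            continue
        wave = _component_wave(comp, t, p.comp_lat[comp])
        out += gain * p.comp_amp[comp][:, None] * wave[None, :]
    return out


def deviant_template(p: VirtualParticipant, fs: float = DEFAULT_FS) -> np.ndarray:
    """Full target response: all four components."""
    return erp_template(p, {c: 1.0 for c in COMPONENTS}, fs)


def standard_template(p: VirtualParticipant, fs: float = DEFAULT_FS) -> np.ndarray:
    """Non-target response: attenuated sensory N1/P2 only."""
    f = STANDARD_SENSORY_FRACTION
    return erp_template(p, {"N1": f, "P2": f}, fs)


def target_flash_template(p: VirtualParticipant, fs: float = DEFAULT_FS) -> np.ndarray:
    """Target-flash response: non-target response plus the aptitude-scaled
    target/non-target difference, so aptitude 0 is exactly null-effect."""
    std = standard_template(p, fs)
    return std + p.aptitude * (deviant_template(p, fs) - std)


def pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
               fs: float, channel_sd: float,
               shared_frac: float = NOISE_SHARED_FRAC) -> np.ndarray:
    """1/f-shaped noise, per-channel SD exactly ``channel_sd``, with a shared
    low-rank spatial component across channels."""
    if channel_sd <= 0:
        return np.zeros((n_channels, n_samples))

    def pink(rows: int) -> np.ndarray:
        n_f = n_samples // 2 + 1
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
        spec = (rng.standard_normal((rows, n_f))
                + 1j * rng.standard_normal((rows, n_f)))
        amp = np.zeros(n_f)
        amp[1:] = 1.0 / np.sqrt(freqs[1:])  # 1/f power spectrum
        x = np.fft.irfft(spec * amp[None, :], n=n_samples, axis=1)
        return x / x.std(axis=1, keepdims=True)

    indep = pink(n_channels)
    common = pink(_NOISE_PATTERNS.shape[1])
    mix = _NOISE_PATTERNS / np.linalg.norm(_NOISE_PATTERNS, axis=0, keepdims=True)
    shared = mix @ common
    shared /= shared.std(axis=1, keepdims=True)
    noise = (np.sqrt(1 - shared_frac) * indep
             + np.sqrt(shared_frac) * shared[:n_channels])
    noise *= channel_sd / noise.std(axis=1, keepdims=True)
    return noise


def add_blinks(data: np.ndarray, rng: np.random.Generator, fs: float,
               blink_rate_per_min: float) -> int:
    """Superimpose Poisson-arriving blink transients in place; returns count."""
    if blink_rate_per_min <= 0:
        return 0
    n_samples = data.shape[1]
    dur_min = n_samples / fs / 60.0
    n_blinks = rng.poisson(blink_rate_per_min * dur_min)
    blink_len = int(round(BLINK_DUR_MS / 1000.0 * fs))
    t = np.arange(blink_len) / blink_len
    wave = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    for _ in range(n_blinks):
        onset = rng.integers(0, max(1, n_samples - blink_len))
        amp = max(40.0, rng.normal(BLINK_AMP_UV, 20.0))
        data[:, onset:onset + blink_len] += (
            amp * BLINK_TOPOGRAPHY[:, None] * wave[None, :])
    return int(n_blinks)


def _add_response(data: np.ndarray, template: np.ndarray, onset: int) -> None:
    stop = min(data.shape[1], onset + template.shape[1])
    data[:, onset:stop] += template[:, : stop - onset]


def simulate_oddball_session(p: VirtualParticipant,
                             spec: OddballSpec | None = None,
                             seed: int = 0,
                             fs: float = DEFAULT_FS) -> ContinuousRecording:
    """Simulate one auditory-oddball session (all runs, concatenated).

    Exactly ``deviants_per_run`` deviant tones are placed uniformly at random
    within each run (the stated standards:deviants ratio is enforced per run;
    positions are otherwise unconstrained).  Deviants evoke the participant's
    full target response, standards the attenuated sensory response.
    """
    spec = spec or OddballSpec()
    n_dev = spec.deviants_per_run
    if abs(n_dev - round(n_dev)) > 1e-9:
        raise InvalidSpecError(
            f"ratio {spec.standard_deviant_ratio}:1 implies a non-integer "
            f"deviant count {n_dev} per run of {spec.tones_per_run} tones")
    n_dev = int(round(n_dev))

    rng = np.random.default_rng(seed)
    pre_roll_s, gap_s, post_roll_s = 2.0, 4.0, 2.0
    soa_s = spec.soa_ms / 1000.0
    run_samples = int(round(spec.run_length_s * fs))
    gap_samples = int(round(gap_s * fs))
    n_samples = (int(round(pre_roll_s * fs))
                 + spec.n_runs * run_samples
                 + (spec.n_runs - 1) * gap_samples
                 + int(round(post_roll_s * fs)))

    data = np.zeros((len(MONTAGE_16), n_samples))
    dev = deviant_template(p, fs)
    std = standard_template(p, fs)

    events: list[Event] = []
    tone_samples = int(round(spec.tone_dur_ms / 1000.0 * fs))
    for run in range(spec.n_runs):
        run_start = int(round(pre_roll_s * fs)) + run * (run_samples + gap_samples)
        dev_positions = set(rng.choice(spec.tones_per_run, size=n_dev,
                                       replace=False).tolist())
        for k in range(spec.tones_per_run):
            onset = run_start + int(round(k * soa_s * fs))
            is_dev = k in dev_positions
            _add_response(data, dev if is_dev else std, onset)
            events.append(Event(sample=onset,
                                code="deviant" if is_dev else "standard",
                                is_target=is_dev,
                                duration_samples=tone_samples))

    data += pink_noise(rng, len(MONTAGE_16), n_samples, fs, p.noise_sd)
    add_blinks(data, rng, fs, p.blink_rate)

    return ContinuousRecording(
        data=data, fs=fs, events=events,
        provenance=[f"simulated oddball session (participant {p.id}, seed {seed})"],
    )


def default_matrix(rows: int, cols: int) -> list[str]:
    """Row-major symbol layout filling the matrix from a fixed alphabet."""
    alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
                "._,;:!?&*+-=/@#%()<>[]{}|~^\"'\\$")
    n = rows * cols
    if n > len(alphabet):
        raise InvalidArgumentError(f"matrix of {n} symbols exceeds alphabet")
    return list(alphabet[:n])


def symbol_position(symbol: str, spec: SpellerSpec) -> tuple[int, int]:
    symbols = default_matrix(spec.matrix_rows, spec.matrix_cols)
    try:
        idx = symbols.index(symbol)
    except ValueError:
        raise InvalidArgumentError(
            f"symbol {symbol!r} not addressable in "
            f"{spec.matrix_rows}x{spec.matrix_cols} matrix") from None
    return idx // spec.matrix_cols, idx % spec.matrix_cols


def simulate_speller_session(p: VirtualParticipant, spec: SpellerSpec,
                             target_text: str, seed: int = 0,
                             fs: float = DEFAULT_FS) -> ContinuousRecording:
    """Simulate a row/column speller session for the given intended symbols.

    For each intended symbol, ``repetitions_per_selection`` complete sequences
    of (rows + cols) flashes are presented in independently randomized order.
    Flashes of the target's row or column evoke the aptitude-scaled target
    response; all other flashes evoke the non-target response.
    """
    if spec.repetitions_per_selection < 1:
        raise InvalidArgumentError("repetitions_per_selection must be >= 1")
    targets = [symbol_position(s, spec) for s in target_text]

    rng = np.random.default_rng(seed)
    pre_roll_s, post_roll_s = 1.0, 1.5
    soa_samples = int(round(spec.flash_soa_ms / 1000.0 * fs))
    pause_samples = int(round(spec.pause_after_selection_s * fs))
    flashes_per_selection = (spec.repetitions_per_selection
                             * spec.flashes_per_sequence)
    sel_samples = flashes_per_selection * soa_samples + pause_samples
    n_samples = (int(round(pre_roll_s * fs)) + len(targets) * sel_samples
                 + int(round(post_roll_s * fs)))

    data = np.zeros((len(MONTAGE_16), n_samples))
    tgt_tpl = target_flash_template(p, fs)
    non_tpl = standard_template(p, fs)

    base_sequence = ([("row", i) for i in range(spec.matrix_rows)]
                     + [("col", j) for j in range(spec.matrix_cols)])
    events: list[Event] = []
    for sel_idx, (t_row, t_col) in enumerate(targets):
        sel_start = int(round(pre_roll_s * fs)) + sel_idx * sel_samples
        flash_idx = 0
        for _rep in range(spec.repetitions_per_selection):
            order = rng.permutation(len(base_sequence))
            for k in order:
                kind, idx = base_sequence[k]
                onset = sel_start + flash_idx * soa_samples
                is_target = ((kind == "row" and idx == t_row)
                             or (kind == "col" and idx == t_col))
                _add_response(data, tgt_tpl if is_target else non_tpl, onset)
                events.append(Event(
                    sample=onset, code="flash",
                    row=idx if kind == "row" else -1,
                    col=idx if kind == "col" else -1,
                    is_target=is_target,
                    duration_samples=int(round(
                        spec.flash_dur_ms / 1000.0 * fs))))
                flash_idx += 1

    data += pink_noise(rng, len(MONTAGE_16), n_samples, fs, p.noise_sd)
    add_blinks(data, rng, fs, p.blink_rate)

    return ContinuousRecording(
        data=data, fs=fs, events=events,
        provenance=[f"simulated speller session (participant {p.id}, "
                    f"targets {target_text!r}, seed {seed})"],
    )
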