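"""Virtual cohorts for the oddball-predicts-speller study design.

Each :class:`VirtualParticipant` carries a latent BCI aptitude in [0, 1] and
per-component ERP parameters (amplitude topography scale and latency for
N1, P2, N2 and P3), plus background-noise and blink-rate parameters.  The
cohort generator plants a monotone link between the participant's N2
strength and the speller error count expected from their aptitude, so the
downstream rank-correlation analysis has a known ground truth to recover.

Component calibration targets the published group statistics of severely
motor-impaired P300-BCI users: latency means/SDs are taken from the Cz rows
of the group peak table (N1 159.45 +- 25.8 ms, P2 236.51 +- 18.3 ms,
N2 304.69 +- 36.6 ms, P3 361.51 +- 87.1 ms) and the amplitude topographies
reproduce the post-CAR sign pattern of that table at Fz/Cz/Pz/Oz (frontal
N1/N2 negativity, fronto-central P2 positivity, centro-parietal P3, and
genuine occipital N1/N2 negativity, which is what makes the posterior
sign-inverted Oz amplitudes come out positive on average).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError
from .recording import MONTAGE_16

COMPONENTS = ("N1", "P2", "N2", "P3")

#: Peak-detection windows (ms) and polarities, as used in the offline analysis.
COMPONENT_WINDOWS = {
    "N1": (100.0, 200.0),
    "P2": (200.0, 250.0),
    "N2": (250.0, 375.0),
    "P3": (250.0, 700.0),
}
COMPONENT_POLARITY = {"N1": "min", "P2": "max", "N2": "min", "P3": "max"}

#: Latency calibration (ms): mean and between-participant SD of the latency
#: parameter.  Means are the group Cz values; the parameter SD is 0.7x the
#: published SD because the published spread also contains single-session
#: measurement noise that the generator adds separately.
LATENCY_MEAN = {"N1": 159.45, "P2": 236.51, "N2": 304.69, "P3": 361.51}
LATENCY_SD = {"N1": 0.7 * 25.8, "P2": 0.7 * 18.3, "N2": 0.7 * 36.6, "P3": 0.7 * 87.1}
_LAT_MARGIN_MS = 8.0  # latencies stay this far inside their window

#: Fixed per-component scalp topographies (relative units, mastoid reference,
#: montage order F3 Fz F4 T7 T8 C3 Cz C4 Cp3 Cp4 P3 Pz P4 Po7 Po8 Oz).
#: N1/N2 carry frontal and occipital negative lobes (auditory N1/N2 with the
#: polarity flip at the temporal sites), P2 is fronto-central positive and P3
#: centro-parietal positive.
TOPOGRAPHIES = {
    "N1": np.array([-0.85, -1.00, -0.85, -0.12, -0.12, -0.62, -0.81, -0.62,
                    -0.35, -0.35, -0.35, -0.38, -0.35, -0.73, -0.73, -0.96]),
    "P2": np.array([0.70, 0.80, 0.70, 0.15, 0.15, 0.80, 1.00, 0.80,
                    0.55, 0.55, 0.35, 0.40, 0.35, 0.25, 0.25, 0.30]),
    "N2": np.array([-0.90, -1.00, -0.90, -0.05, -0.05, -0.60, -0.85, -0.60,
                    -0.20, -0.20, -0.35, -0.40, -0.35, -1.30, -1.30, -1.50]),
    "P3": np.array([0.62, 0.68, 0.62, 0.10, 0.10, 0.75, 0.85, 0.75,
                    0.90, 0.90, 0.95, 1.00, 0.95, 0.35, 0.35, 0.63]),
}

#: Mean amplitude scale (uV at the topography's unit channel) and lognormal
#: sigma of the between-participant scale distribution.
AMPLITUDE_SCALE_MEAN = {"N1": 4.0, "P2": 2.6, "N2": 2.6, "P3": 6.0}
AMPLITUDE_SCALE_SIGMA = {"N1": 0.35, "P2": 0.45, "N2": 0.45, "P3": 0.35}

#: Temporal waveform shape: Gaussian SD (ms).  P3 is asymmetric (fast rise,
#: slow decay), the classic P300 morphology.
WAVEFORM_SD_MS = {"N1": 22.0, "P2": 20.0, "N2": 45.0, "P3": (35.0, 110.0)}

#: Fraction of the N1/P2 response evoked by standard (non-target) stimuli;
#: N2/P3 are target-only.
STANDARD_SENSORY_FRACTION = 0.5

#: Default planted coupling: the published Oz N2 amplitude-vs-errors rank
#: correlation of r = -0.85.
DEFAULT_PLANTED_RHO = -0.85

#: Aptitude location: aptitude = Phi(z + APTITUDE_SHIFT).  The shift is
#: calibrated so the expected mean error count of a default 40-selection task
#: matches the published cohort mean of 15.1 errors.
APTITUDE_SHIFT = 0.4

NOISE_SD_MEAN = 9.0     # uV, broadband background EEG per channel
NOISE_SD_SIGMA = 0.15   # lognormal sigma of between-participant spread
BLINK_RATE_MEAN = 8.0   # blinks per minute
BLINK_RATE_SIGMA = 0.4


@dataclass(frozen=True)
class OddballSpec:
    """Auditory oddball paradigm: 3 runs x 20 sequences x 5 tones,
    standards:deviants 4:1, 160 ms tones, 800 ms ISI."""

    n_runs: int = 3
    sequences_per_run: int = 20
    tones_per_sequence: int = 5
    standard_deviant_ratio: float = 4.0
    tone_dur_ms: float = 160.0
    isi_ms: float = 800.0
    standard_chord_hz: tuple[float, ...] = (517.0, 646.0, 775.0)
    deviant_hz: float = 517.0

    @property
    def soa_ms(self) -> float:
        """Stimulus-onset asynchrony: tone duration + ISI."""
        return self.tone_dur_ms + self.isi_ms

    @property
    def tones_per_run(self) -> int:
        return self.sequences_per_run * self.tones_per_sequence

    @property
    def deviants_per_run(self) -> float:
        return self.tones_per_run / (self.standard_deviant_ratio + 1.0)

    @property
    def run_length_s(self) -> float:
        return self.tones_per_run * self.soa_ms / 1000.0

    @property
    def session_length_s(self) -> float:
        return self.n_runs * self.run_length_s


@dataclass(frozen=True)
class SpellerSpec:
    """Row/column matrix speller: 7x7 matrix, 62.5 ms flashes with 125 ms
    inter-flash interval, 8 s pause after each selection, 40 selections."""

    matrix_rows: int = 7
    matrix_cols: int = 7
    flash_dur_ms: float = 62.5
    inter_flash_ms: float = 125.0
    repetitions_per_selection: int = 10
    n_selections: int = 40
    pause_after_selection_s: float = 8.0

    @property
    def flashes_per_sequence(self) -> int:
        """One flash per row plus one per column."""
        return self.matrix_rows + self.matrix_cols

    @property
    def flash_soa_ms(self) -> float:
        return self.flash_dur_ms + self.inter_flash_ms

    @property
    def chance_accuracy(self) -> float:
        return 1.0 / (self.matrix_rows * self.matrix_cols)


@dataclass
class VirtualParticipant:
    """Latent aptitude plus ERP parameters for one simulated subject."""

    id: str
    aptitude: float
    comp_amp: dict[str, np.ndarray]   # component -> 16-channel amplitudes (uV)
    comp_lat: dict[str, float]        # component -> latency (ms)
    noise_sd: float                   # uV
    blink_rate: float                 # events/min
    amp_scale: dict[str, float] = field(default_factory=dict)

    def amplitude(self, component: str, channel: str) -> float:
        return float(self.comp_amp[component][MONTAGE_16.index(channel)])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def expected_accuracy(aptitude: float, spec: SpellerSpec | None = None) -> float:
    """Expected selection accuracy: chance at aptitude 0, perfect at 1."""
    spec = spec or SpellerSpec()
    c = spec.chance_accuracy
    return c + (1.0 - c) * float(aptitude)


def expected_errors(p: VirtualParticipant, spec: SpellerSpec | None = None) -> float:
    """Expected error count of a speller task for this participant."""
    spec = spec or SpellerSpec()
    return spec.n_selections * (1.0 - expected_accuracy(p.aptitude, spec))


def oz_n2_parameter(p: VirtualParticipant) -> float:
    """The planted N2 parameter: the participant's Oz N2 template amplitude in
    the analysis convention (common average reference, posterior sign
    inversion).  Positive; grows with N2 strength."""
    t = p.comp_amp["N2"]
    return float(t.mean() - t[MONTAGE_16.index("Oz")])


def make_cohort(n: int, planted_rho: float = DEFAULT_PLANTED_RHO,
                seed: int = 0) -> list[VirtualParticipant]:
    """Generate ``n`` virtual participants with a planted rank correlation.

    The population Spearman correlation between the N2 strength parameter
    (equivalently :func:`oz_n2_parameter`) and :func:`expected_errors` equals
    ``planted_rho``.  The coupling uses a Gaussian copula with Pearson
    correlation ``2*sin(pi*planted_rho/6)``, the exact inverse of the
    bivariate-normal Spearman relation.  Deterministic for a given seed.
    """
    if n < 2:
        raise InvalidArgumentError(f"need n >= 2 participants, got {n}")
    if not -1.0 <= planted_rho <= 1.0:
        raise InvalidArgumentError(f"|planted_rho| must be <= 1, got {planted_rho}")

    rng = np.random.default_rng(seed)
    z_apt = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    # expected errors decrease monotonically with aptitude, so coupling the
    # N2 latent with -z_apt by rho_pearson plants Spearman(s_N2, errors).
    rho_p = 2.0 * np.sin(np.pi * planted_rho / 6.0)
    z_n2 = rho_p * (-z_apt) + np.sqrt(max(0.0, 1.0 - rho_p ** 2)) * eps

    aptitude = stats.norm.cdf(z_apt + APTITUDE_SHIFT)

    scales = {}
    for comp in COMPONENTS:
        sigma = AMPLITUDE_SCALE_SIGMA[comp]
        z = z_n2 if comp == "N2" else rng.standard_normal(n)
        scales[comp] = AMPLITUDE_SCALE_MEAN[comp] * np.exp(
            sigma * z - sigma ** 2 / 2.0)

    lats = {}
    for comp in COMPONENTS:
        lo, hi = COMPONENT_WINDOWS[comp]
        lats[comp] = _truncated_normal(
            rng, LATENCY_MEAN[comp], LATENCY_SD[comp],
            lo + _LAT_MARGIN_MS, hi - _LAT_MARGIN_MS, n)

    noise_sd = NOISE_SD_MEAN * np.exp(
        NOISE_SD_SIGMA * rng.standard_normal(n) - NOISE_SD_SIGMA ** 2 / 2)
    blink_rate = BLINK_RATE_MEAN * np.exp(
        BLINK_RATE_SIGMA * rng.standard_normal(n) - BLINK_RATE_SIGMA ** 2 / 2)

    cohort = []
    for i in range(n):
        comp_amp = {c: scales[c][i] * TOPOGRAPHIES[c] for c in COMPONENTS}
        cohort.append(VirtualParticipant(
            id=f"P{i + 1:02d}",
            aptitude=float(aptitude[i]),
            comp_amp=comp_amp,
            comp_lat={c: float(lats[c][i]) for c in COMPONENTS},
            noise_sd=float(noise_sd[i]),
            blink_rate=float(blink_rate[i]),
            amp_scale={c: float(scales[c][i]) for c in COMPONENTS},
        ))
    return cohort
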