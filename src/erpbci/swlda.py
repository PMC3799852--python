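"""Stepwise linear discriminant analysis and the simulated online speller.

Single-trial spatiotemporal features (moving-average smoothed and decimated)
are selected by forward/backward stepwise regression of the binary
target/non-target label: the most significant candidate (partial F-test) is
added while its p-value is below ``p_enter`` (the very first step failing
that criterion aborts model generation), features whose partial p-value
rises to ``p_remove`` or above are removed again, and selection stops after
``max_features`` inclusions or when no candidate qualifies.  Classification
sums the linear scores over all flashes of each row and each column and
selects the argmax of both; no bias term is needed because the offset is
common to all stimuli.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import SpellerSpec, VirtualParticipant
from .errors import InvalidArgumentError, ModelGenerationFailureError
from .preprocess import epoch_and_baseline
from .recording import EpochSet
from .simulate import default_matrix, simulate_speller_session

_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class SWLDAConfig:
    """Classifier configuration: 25-sample moving average, decimation by 25,
    0-1000 ms window, entry p < 0.1, removal p >= 0.15, at most 60 features."""

    smooth_width: int = 25
    decim_factor: int = 25
    window: tuple[float, float] = (0.0, 1000.0)
    p_enter: float = 0.1
    p_remove: float = 0.15
    max_features: int = 60


@dataclass
class LinearDiscriminantModel:
    """Selected (channel, time-bin) features, their OLS weights and the
    stepwise-selection audit trail."""

    selected: list[int]
    weights: np.ndarray
    intercept: float
    selection_log: list[tuple[int, str, int, float]]  # (step, action, feature, p)
    config: SWLDAConfig = field(default_factory=SWLDAConfig)
    n_channels: int = 0
    n_bins: int = 0

    def score(self, X: np.ndarray) -> np.ndarray:
        """Linear score per trial (no bias; see module docstring)."""
        return X[:, self.selected] @ self.weights

    def to_json(self) -> str:
        return json.dumps({
            "selected": list(map(int, self.selected)),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "selection_log": [[int(s), a, int(f), float(p)]
                              for s, a, f, p in self.selection_log],
            "config": {
                "smooth_width": self.config.smooth_width,
                "decim_factor": self.config.decim_factor,
                "window": list(self.config.window),
                "p_enter": self.config.p_enter,
                "p_remove": self.config.p_remove,
                "max_features": self.config.max_features,
            },
            "n_channels": self.n_channels,
            "n_bins": self.n_bins,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LinearDiscriminantModel":
        d = json.loads(text)
        cfgd = d["config"]
        cfgd["window"] = tuple(cfgd["window"])
        return cls(
            selected=list(d["selected"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            selection_log=[(s, a, f, p) for s, a, f, p in d["selection_log"]],
            config=SWLDAConfig(**cfgd),
            n_channels=d.get("n_channels", 0),
            n_bins=d.get("n_bins", 0),
        )


def build_feature_vectors(epochs: EpochSet, cfg: SWLDAConfig | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Trials x features matrix plus binary labels (1 = target).

    Per trial and channel: crop to the configured window, smooth with a
    centered ``smooth_width``-sample moving average (edges truncated to the
    available samples) and keep every ``decim_factor``-th sample starting at
    the first.  Features are ordered channel-major, so the count is
    ``n_channels * ceil(window_samples / decim_factor)``.
    """
    cfg = cfg or SWLDAConfig()
    lo, hi = cfg.window
    dt = 1000.0 / epochs.fs
    sel = (epochs.time >= lo - dt / 2) & (epochs.time < hi - dt / 2)
    n_expected = int(round(hi / 1000.0 * epochs.fs)) - int(round(lo / 1000.0 * epochs.fs))
    if sel.sum() < n_expected:
        raise InvalidArgumentError(
            f"epochs span {epochs.time[0]:.1f}-{epochs.time[-1]:.1f} ms, "
            f"shorter than the classification window {cfg.window}")
    data = epochs.data[:, :, sel]

    # centered moving average evaluated only at the decimated positions,
    # via cumulative sums (edges truncated to the available samples)
    n_t = data.shape[2]
    half = cfg.smooth_width // 2
    centers = np.arange(0, n_t, cfg.decim_factor)
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers + cfg.smooth_width - half, n_t)
    cs = np.concatenate(
        [np.zeros(data.shape[:2] + (1,)), np.cumsum(data, axis=2)], axis=2)
    decimated = (cs[:, :, hi] - cs[:, :, lo]) / (hi - lo)

    X = decimated.reshape(decimated.shape[0], -1)  # channel-major
    y = np.array([ev.is_target for ev in epochs.events], dtype=float)
    return X, y


def _forward_pvalues(Q: np.ndarray, resid: np.ndarray, rss: float,
                     X: np.ndarray, n_in_model: int) -> np.ndarray:
    """Partial-F p-value of adding each column of X to the current model.

    ``Q`` is an orthonormal basis of the current design (intercept +
    selected), ``resid``/``rss`` the current residual and its sum of squares.
    """
    n = X.shape[0]
    Xt = X - Q @ (Q.T @ X)
    d = np.einsum("ij,ij->j", Xt, Xt)
    c = Xt.T @ resid
    df2 = n - n_in_model - 2  # after adding the candidate
    pvals = np.full(X.shape[1], np.inf)
    ok = d > _COLLINEAR_TOL * n
    explained = np.zeros_like(d)
    explained[ok] = c[ok] ** 2 / d[ok]
    rss_new = np.maximum(rss - explained, 0.0)
    denom = rss_new / df2
    # degenerate residuals: a candidate absorbing all remaining variance is
    # maximally significant; one explaining nothing of a zero residual is not
    f = np.where(denom > 0, explained / np.where(denom > 0, denom, 1.0),
                 np.where(explained > 0, np.inf, 0.0))
    pvals[ok] = stats.f.sf(f[ok], 1, df2)
    return pvals


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS with intercept: (coefs incl. intercept first, p-values, RSS)."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    dof = n - design.shape[1]
    xtx_inv = np.linalg.pinv(design.T @ design)
    if dof > 0:
        sigma2 = rss / dof
        se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 1e-300))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    else:
        pvals = np.ones_like(beta)
    return beta, pvals, rss


def swlda_train(X: np.ndarray, y: np.ndarray,
                cfg: SWLDAConfig | None = None) -> LinearDiscriminantModel:
    """Forward/backward stepwise feature selection with OLS weights.

    Raises :class:`ModelGenerationFailureError` when no feature reaches the
    entry criterion on the first forward step.  Constant feature columns are
    skipped with a log entry.
    """
    cfg = cfg or SWLDAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= 2:
        raise InvalidArgumentError("need more than 2 trials")
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidArgumentError("both classes must be present")
    y = (y == classes.max()).astype(float)

    log: list[tuple[int, str, int, float]] = []
    step = 0
    usable = np.ones(p, dtype=bool)
    const = X.std(axis=0) <= _COLLINEAR_TOL
    for j in np.where(const)[0]:
        usable[j] = False
        log.append((step, "skip_constant", int(j), float("nan")))

    selected: list[int] = []
    while len(selected) < cfg.max_features:
        # forward step: most significant remaining candidate
        cand = np.where(usable)[0]
        cand = cand[~np.isin(cand, selected)]
        if cand.size == 0:
            break
        design = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        Q, _ = np.linalg.qr(design)
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        pvals = _forward_pvalues(Q, resid, rss, X[:, cand], len(selected))
        best = int(np.argmin(pvals))
        best_p = float(pvals[best])
        if not best_p < cfg.p_enter:
            if not selected:
                raise ModelGenerationFailureError(
                    f"no feature reached p < {cfg.p_enter} "
                    f"(best p = {best_p:.3f}); model generation fails")
            break
        step += 1
        feat = int(cand[best])
        selected.append(feat)
        log.append((step, "add", feat, best_p))

        # backward step: drop features that no longer meet p < p_remove
        while len(selected) > 1:
            _, pv, _ = _ols(X[:, selected], y)
            pv = pv[1:]  # skip intercept
            worst = int(np.argmax(pv))
            if pv[worst] >= cfg.p_remove:
                step += 1
                removed = selected.pop(worst)
                log.append((step, "remove", removed, float(pv[worst])))
                usable[removed] = False  # do not re-enter removed features
            else:
                break

    beta, _, _ = _ols(X[:, selected], y)
    return LinearDiscriminantModel(
        selected=selected, weights=beta[1:], intercept=float(beta[0]),
        selection_log=log, config=cfg)


def classify_symbol(model: LinearDiscriminantModel, X: np.ndarray,
                    rows: np.ndarray, cols: np.ndarray) -> tuple[int, int]:
    """Sum per-flash linear scores over each row and column; return the
    argmax of both (ties break toward the lowest index).

    ``rows[i]``/``cols[i]`` give the flashed row/column index of trial ``i``
    (-1 when the flash was of the other kind).
    """
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    scores = model.score(np.asarray(X, dtype=float))

    def summed(idx: np.ndarray) -> np.ndarray:
        present = idx[idx >= 0]
        if present.size == 0:
            raise InvalidArgumentError("no flashes of this kind")
        n = int(present.max()) + 1
        if np.unique(present).size != n:
            raise InvalidArgumentError("not every row/col index was flashed")
        out = np.zeros(n)
        np.add.at(out, present, scores[idx >= 0])
        return out

    return int(np.argmax(summed(rows))), int(np.argmax(summed(cols)))


def features_from_recording(rec, cfg: SWLDAConfig | None = None):
    """Single-trial features computed straight from the continuous recording.

    Numerically identical to epoching (no baseline) followed by
    :func:`build_feature_vectors`, but via one cumulative sum over the
    recording instead of materializing every epoch — the moving-average /
    decimation chain only ever reads ``smooth_width`` samples around each
    retained time bin.  Returns (X, y, rows, cols) plus the retained events.
    """
    cfg = cfg or SWLDAConfig()
    lo_ms, hi_ms = cfg.window
    s0 = int(round(lo_ms / 1000.0 * rec.fs))
    n_t = int(round(hi_ms / 1000.0 * rec.fs)) - s0
    half = cfg.smooth_width // 2
    centers = np.arange(0, n_t, cfg.decim_factor)
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers + cfg.smooth_width - half, n_t)

    events = [ev for ev in rec.events
              if ev.sample + s0 >= 0 and ev.sample + s0 + n_t <= rec.n_samples]
    if not events:
        raise InvalidArgumentError("no events with a complete epoch window")
    starts = np.array([ev.sample + s0 for ev in events])

    cs = np.concatenate([np.zeros((rec.n_channels, 1)),
                         np.cumsum(rec.data, axis=1)], axis=1)
    idx_lo = starts[:, None] + lo[None, :]
    idx_hi = starts[:, None] + hi[None, :]
    feats = (cs[:, idx_hi] - cs[:, idx_lo]) / (hi - lo)  # (ch, trials, bins)
    X = np.ascontiguousarray(feats.transpose(1, 0, 2)).reshape(len(events), -1)

    y = np.array([ev.is_target for ev in events], dtype=float)
    rows = np.array([ev.row for ev in events])
    cols = np.array([ev.col for ev in events])
    return X, y, rows, cols, events


def _speller_features(rec, cfg: SWLDAConfig):
    X, y, rows, cols, _ = features_from_recording(rec, cfg)
    return X, y, rows, cols


def _random_text(rng: np.random.Generator, spec: SpellerSpec, n: int) -> str:
    symbols = default_matrix(spec.matrix_rows, spec.matrix_cols)
    return "".join(rng.choice(symbols, size=n))


def train_speller_model(p: VirtualParticipant, train_spec: SpellerSpec,
                        cfg: SWLDAConfig, seed: int,
                        calibration_text: str | None = None,
                        ) -> LinearDiscriminantModel:
    """Train SWLDA on a simulated calibration session."""
    rng = np.random.default_rng(seed)
    text = calibration_text or _random_text(rng, train_spec,
                                            train_spec.n_selections)
    rec = simulate_speller_session(p, train_spec, text,
                                   seed=int(rng.integers(2 ** 31)))
    X, y, _, _ = _speller_features(rec, cfg)
    return swlda_train(X, y, cfg)


def classify_session(model: LinearDiscriminantModel, rec,
                     spec: SpellerSpec, cfg: SWLDAConfig) -> list[str]:
    """Classify every selection of a simulated speller session."""
    X, _, rows, cols = _speller_features(rec, cfg)
    block = spec.repetitions_per_selection * spec.flashes_per_sequence
    if X.shape[0] % block:
        raise InvalidArgumentError("flash count is not a whole number of "
                                   "selections")
    symbols = default_matrix(spec.matrix_rows, spec.matrix_cols)
    out = []
    for s in range(X.shape[0] // block):
        sl = slice(s * block, (s + 1) * block)
        r, c = classify_symbol(model, X[sl], rows[sl], cols[sl])
        out.append(symbols[r * spec.matrix_cols + c])
    return out


def simulate_speller_run(p: VirtualParticipant,
                         train_spec: SpellerSpec | None = None,
                         test_spec: SpellerSpec | None = None,
                         cfg: SWLDAConfig | None = None,
                         target_text: str | None = None,
                         seed: int = 0) -> tuple[list[str], int]:
    """Calibration, SWLDA training and simulated online spelling.

    The default calibration mirrors the study protocol (17 spelled symbols
    at 15 stimulus repetitions each); the default test is the 40-selection
    task.  Returns the classified selections and the error count.
    """
    train_spec = train_spec or SpellerSpec(n_selections=17,
                                           repetitions_per_selection=15)
    test_spec = test_spec or SpellerSpec()
    cfg = cfg or SWLDAConfig()

    rng = np.random.default_rng(seed)
    model = train_speller_model(p, train_spec, cfg,
                                seed=int(rng.integers(2 ** 31)))
    text = target_text or _random_text(rng, test_spec, test_spec.n_selections)
    rec = simulate_speller_session(p, test_spec, text,
                                   seed=int(rng.integers(2 ** 31)))
    selections = classify_session(model, rec, test_spec, cfg)
    errors = sum(a != b for a, b in zip(selections, text))
    return selections, errors
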