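"""Rate coding of the input signal and the linear-regression readout.

Each raw sample ``E_k`` (electrostatic potential in mV) is converted to a
Poisson firing frequency via the affine map

    F_in(k) = F_poisson · (4 + 2·E_k) / 5,

held for a duration ``T_bin`` while every input-layer neuron independently
emits Bernoulli(F_in·dt) spikes per step.  The admissible sample range
defaults to [−2.0, +0.5] mV — the non-negativity interval of the map, with
unit gain (F_in = F_poisson) at +0.5 mV.

The readout is a single rectified linear unit over the excitatory per-bin
firing rates, trained by (ridge-regularized) least squares to predict the
*next* sample's input frequency: row k of the design matrix pairs with
target F_in(k+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Ridge

from .network import SpikeRaster

__all__ = [
    "EncodingConfig",
    "Readout",
    "encode_rate",
    "gen_input_raster",
    "fit_readout",
    "predict_Fout",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EncodingConfig:
    """Input-encoding parameters."""

    F_poisson: float = 150.0  # conversion coefficient, Hz
    T_bin: float = 0.150  # hold duration per sample, s
    dt: float = 1e-4  # s
    E_min: float = -2.0  # mV
    E_max: float = 0.5  # mV

    def __post_init__(self) -> None:
        if self.F_poisson <= 0:
            raise ValueError("F_poisson must be positive")
        if self.T_bin <= 0 or self.dt <= 0:
            raise ValueError("T_bin and dt must be positive")
        if self.E_min >= self.E_max:
            raise ValueError("require E_min < E_max")
        if self.F_poisson * (4 + 2 * self.E_min) / 5 < 0:
            raise ValueError("encoded rate would be negative at E_min")


def encode_rate(E_k, cfg: EncodingConfig):
    """Affine potential→frequency map; accepts scalars or arrays.

    Samples outside ``[E_min, E_max]`` are clipped (and counted in the log);
    the result is guaranteed non-negative.
    """
    E = np.asarray(E_k, dtype=float)
    n_clipped = int(np.sum((E < cfg.E_min) | (E > cfg.E_max)))
    if n_clipped:
        log.warning("encode_rate: clipped %d out-of-range samples", n_clipped)
    E = np.clip(E, cfg.E_min, cfg.E_max)
    F = cfg.F_poisson * (4.0 + 2.0 * E) / 5.0
    F = np.maximum(F, 0.0)
    return float(F) if np.isscalar(E_k) else F


def gen_input_raster(
    rates,
    cfg: EncodingConfig,
    N_input: int,
    rng: np.random.Generator | int | None = None,
) -> SpikeRaster:
    """Poisson spike trains: one ``T_bin`` window per sample rate.

    During sample k's window each of the ``N_input`` input neurons
    independently emits a spike per step with probability ``F_in(k)·dt``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rates = np.asarray(rates, dtype=float)
    if not np.all(np.isfinite(rates)) or np.any(rates < 0):
        raise ValueError("rates must be finite and non-negative")
    if np.any(rates * cfg.dt >= 1.0):
        raise ValueError(
            "F_in*dt >= 1: rate unresolvable at this dt; decrease dt or the rate"
        )
    steps_per_bin = int(round(cfg.T_bin / cfg.dt))
    all_steps: list[np.ndarray] = []
    all_neurons: list[np.ndarray] = []
    for k, r in enumerate(rates):
        p = r * cfg.dt
        if p <= 0.0:
            continue
        draws = rng.random((steps_per_bin, N_input)) < p
        s, n = np.nonzero(draws)
        all_steps.append(s + k * steps_per_bin)
        all_neurons.append(n)
    if all_steps:
        steps = np.concatenate(all_steps)
        neurons = np.concatenate(all_neurons)
    else:
        steps = np.empty(0, dtype=np.int64)
        neurons = np.empty(0, dtype=np.int64)
    T = len(rates) * cfg.T_bin
    return SpikeRaster(steps * cfg.dt, neurons, N_input, T)


@dataclass
class Readout:
    """Rectified linear readout over excitatory rates (fires/s units)."""

    weights: np.ndarray  # (N_exc,)
    intercept: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("readout coefficients must be finite")

    def to_text(self, path) -> None:
        np.savetxt(path, np.concatenate([[self.intercept], self.weights]))

    @classmethod
    def from_text(cls, path) -> "Readout":
        v = np.loadtxt(path)
        return cls(weights=v[1:], intercept=float(v[0]))


def fit_readout(X, y, ridge: float = 1e-6) -> Readout:
    """Least-squares fit of next-bin input frequency from per-bin rates.

    ``X`` has one row per bin (columns: excitatory neurons, fires/s) and
    ``y[k] = F_in(k+1)``.  The tiny default ridge term is for numerical
    conditioning only; set ``ridge=0`` for plain least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if X.shape[0] < 2:
        raise ValueError("insufficient data: need at least 2 bins to fit a readout")
    model = Ridge(alpha=ridge, fit_intercept=True, solver="svd")
    model.fit(X, y)
    return Readout(weights=model.coef_.copy(), intercept=float(model.intercept_))


def predict_Fout(readout: Readout, x_k) -> np.ndarray | float:
    """Rectified prediction ``max(0, w·x + b)`` — a frequency cannot be < 0.

    ``x_k`` may be one rate vector or a (n_bins, N_exc) matrix.
    """
    x = np.asarray(x_k, dtype=float)
    out = x @ readout.weights + readout.intercept
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out
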