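"""Synthetic periodic "beat" waveforms with labeled morphology anomalies.

A deterministic, seeded stand-in for an exported long-term ECG recording:
a train of identical beats, each the sum of three Gaussian bumps over a
baseline (a simplified P/QRS/T morphology), sampled at 128 samples/s in a
bounded mV range matched to the rate encoder's admissible interval.
Selected beats are transformed (inverted/widened/scaled/dropped main bump)
and every sample of a transformed beat carries an anomaly label.

The generator deliberately emulates only what the detection method
consumes — a periodic amplitude profile plus localized morphology changes —
not physiologically accurate electrocardiography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WaveformSpec", "generate", "load_csv", "write_csv", "default_benchmark"]

log = logging.getLogger(__name__)

#: simplified P/QRS/T template: (center, width, amplitude) per bump, with
#: center and width as fractions of the beat period and amplitude in mV
#: above the baseline.  The QRS center sits exactly on a sample of the
#: default 96-sample beat grid so its sampled peak equals the template peak.
DEFAULT_BEAT_SHAPE = ((0.20, 0.035, 0.50), (38.0 / 96.0, 0.030, 2.30), (0.62, 0.070, 0.80))

#: the ectopic surrogate: one premature, very narrow R-wave (sub-sample
#: width) at an off-schedule phase, same peak amplitude as the normal QRS,
#: with the beat's normal complexes absent
ECTOPIC_BUMP = (75.0 / 96.0, 0.004, 2.30)

TRANSFORMS = ("invert", "widen", "scale", "drop", "invert_widen", "ectopic")


@dataclass(frozen=True)
class WaveformSpec:
    """Specification of one generated series."""

    beat_period: float = 0.75  # s
    sample_rate: float = 128.0  # samples/s
    n_beats: int = 60
    beat_shape: tuple = DEFAULT_BEAT_SHAPE
    baseline: float = -1.8  # mV
    anomaly_spec: tuple = ()  # ((beat_index, transform), ...)
    noise_sd: float = 0.02  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beat_period <= 0 or self.sample_rate <= 0 or self.n_beats <= 0:
            raise ValueError("beat_period, sample_rate and n_beats must be positive")
        spb = self.beat_period * self.sample_rate
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("beat_period*sample_rate must be an integer sample count")
        for idx, kind in self.anomaly_spec:
            if not 0 <= idx < self.n_beats:
                raise ValueError(f"anomaly beat index {idx} out of range")
            if kind not in TRANSFORMS:
                raise ValueError(f"unknown transform {kind!r}")

    @property
    def samples_per_beat(self) -> int:
        return int(round(self.beat_period * self.sample_rate))


def _beat(spec: WaveformSpec, shape) -> np.ndarray:
    """One noise-free beat template sampled on the beat grid."""
    n = spec.samples_per_beat
    t = np.arange(n) / spec.sample_rate
    y = np.full(n, spec.baseline)
    for c, w, a in shape:
        y += a * np.exp(-0.5 * ((t - c * spec.beat_period) / (w * spec.beat_period)) ** 2)
    return y


def _transform_shape(shape, kind: str):
    """Apply a morphology transform to the largest bump of the template."""
    shape = [list(b) for b in shape]
    main = max(range(len(shape)), key=lambda i: abs(shape[i][2]))
    if kind == "invert":
        shape[main][2] = -shape[main][2]
    elif kind == "widen":
        shape[main][1] *= 3.0
    elif kind == "scale":
        shape[main][2] *= 2.0
    elif kind == "drop":
        shape[main][2] = 0.0
    elif kind == "invert_widen":
        shape[main][2] = -shape[main][2]
        shape[main][1] *= 3.0
    elif kind == "ectopic":
        # premature sharp beat: normal complexes suppressed, one narrow
        # full-amplitude bump at an unexpected phase
        return (ECTOPIC_BUMP,)
    return tuple(tuple(b) for b in shape)


def generate(spec: WaveformSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate (series_mV, labels) for the given spec.

    Deterministic given ``spec.seed``.  Normal beats are identical up to the
    additive Gaussian noise; every sample of a transformed beat is labeled 1.
    """
    normal = _beat(spec, spec.beat_shape)
    spb = spec.samples_per_beat
    series = np.tile(normal, spec.n_beats)
    labels = np.zeros(spec.n_beats * spb, dtype=np.int8)
    for idx, kind in spec.anomaly_spec:
        series[idx * spb : (idx + 1) * spb] = _beat(spec, _transform_shape(spec.beat_shape, kind))
        labels[idx * spb : (idx + 1) * spb] = 1
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        series = series + rng.normal(0.0, spec.noise_sd, series.shape)
    return series, labels


def default_benchmark(seed: int = 0, n_train_beats: int = 60, n_test_beats: int | None = None,
                      anomaly_beats: tuple | None = None,
                      transform: str = "ectopic"):
    """The repository's end-to-end benchmark: (train, test, labels, specs).

    Training: ``n_train_beats`` anomaly-free beats.  Test: ``n_test_beats``
    beats of which the listed ones carry the default arrhythmia-like
    anomaly (a premature narrow ectopic beat replacing the normal
    complexes; its peak amplitude equals the normal QRS peak, so the
    anomaly is a timing/morphology change with no amplitude cue).  Returns
    ``(train_series, test_series, test_labels, (train_spec, test_spec))``.
    """
    if n_test_beats is None:
        n_test_beats = n_train_beats + 4
    if anomaly_beats is None:
        anomaly_beats = tuple(b for b in range(8, n_test_beats - 1, 10))
        if not anomaly_beats:
            anomaly_beats = (n_test_beats // 2,)
    train_spec = WaveformSpec(n_beats=n_train_beats, seed=seed)
    test_spec = WaveformSpec(
        n_beats=n_test_beats,
        anomaly_spec=tuple((b, transform) for b in anomaly_beats),
        seed=seed + 1,
    )
    train_series, _ = generate(train_spec)
    test_series, test_labels = generate(test_spec)
    return train_series, test_series, test_labels, (train_spec, test_spec)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_csv(path, rescale: bool = False, E_min: float = -2.0, E_max: float = 0.5):
    """Read a 2–3 column CSV ``time_or_index, value_mV[, label]``.

    Returns ``(series, labels_or_None)``.  With ``rescale`` the series is
    affinely mapped into ``[E_min, E_max]`` and the transform is logged.
    Malformed rows raise a parse error naming the line number.
    """
    values: list[float] = []
    labels: list[int] = []
    has_labels = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            if len(parts) < 2 or len(parts) > 3:
                raise ValueError(f"parse error at line {lineno}: expected 2-3 columns, got {len(parts)}")
            try:
                values.append(float(parts[1]))
                if len(parts) == 3:
                    labels.append(int(float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"parse error at line {lineno}: {exc}") from None
            row_has_label = len(parts) == 3
            if has_labels is None:
                has_labels = row_has_label
            elif has_labels != row_has_label:
                raise ValueError(f"parse error at line {lineno}: inconsistent column count")
    if not values:
        raise ValueError(f"parse error: {path} contains no data rows")
    series = np.asarray(values)
    if rescale:
        lo, hi = series.min(), series.max()
        if hi > lo:
            scale = (E_max - E_min) / (hi - lo)
            series = (series - lo) * scale + E_min
            log.info("load_csv: rescaled series with E' = (E - %.6g)*%.6g + %.6g", lo, scale, E_min)
        else:
            series = np.full_like(series, 0.5 * (E_min + E_max))
            log.info("load_csv: constant series mapped to range midpoint")
    return series, (np.asarray(labels, dtype=np.int8) if has_labels else None)


def write_csv(path, series, labels=None) -> None:
    """Write the ``load_csv`` format: index, value[, label]."""
    series = np.asarray(series)
    with open(path, "w") as fh:
        for i, v in enumerate(series):
            if labels is None:
                fh.write(f"{i},{float(v)!r}\n")
            else:
                fh.write(f"{i},{float(v)!r},{int(labels[i])}\n")
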