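"""Anomaly detection: the D statistic, judgment margin, ROC and sweeps.

The network-plus-readout acts as a one-step-ahead predictor of the encoded
input frequency.  At sample k the readout's prediction F_out(k) is compared
with the next sample's input frequency, and the detection statistic is

    D(k+1) = |F_out(k) − F_in(k+1)|.

A sample is flagged abnormal when D exceeds a judgment level D_thr.  Two
reference levels summarize separability on a labeled test segment:
``D_thr_no``, the highest D over normal-labeled samples (smallest level
that misdetects nothing), and ``D_thr_ab``, the smallest over anomaly
events of the event's peak D (smallest level that overlooks nothing, with
events = maximal runs of abnormal labels).  Their difference
``Δ_thr = D_thr_ab − D_thr_no`` is the judgment margin: any level strictly
inside a positive margin gives event-level TPR = 1 and FPR = 0.

``run_pipeline`` executes the full three-phase protocol: Phase 1
reconstructs the recurrent layer by IP+SDSP on anomaly-free training data;
Phase 2 freezes plasticity and fits the linear readout; Phase 3 evaluates
D, the margin and the ROC on the labeled test segment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coding import EncodingConfig, Readout, encode_rate, fit_readout, gen_input_raster, predict_Fout
from .dynamics import NeuronParams
from .network import Network, NetworkConfig, build_network
from .plasticity import PlasticityConfig

__all__ = [
    "PipelineConfig",
    "DetectionResult",
    "SweepResult",
    "MarginUndefinedError",
    "compute_D",
    "judgment_margin",
    "anomaly_events",
    "tpr_fpr_curve",
    "run_pipeline",
    "effective_labels",
    "sweep",
]

log = logging.getLogger(__name__)


class MarginUndefinedError(ValueError):
    """No labeled anomaly events: D_thr_ab does not exist.

    Carries the still well-defined ``D_thr_no``.
    """

    def __init__(self, D_thr_no: float):
        super().__init__("no anomaly events in labels; judgment margin undefined")
        self.D_thr_no = D_thr_no


def compute_D(F_out, F_in) -> np.ndarray:
    """One-step-ahead absolute prediction error, NaN at index 0.

    ``D[k] = |F_out[k-1] − F_in[k]|`` for k ≥ 1; both series must have the
    same per-sample indexing.
    """
    F_out = np.asarray(F_out, dtype=float)
    F_in = np.asarray(F_in, dtype=float)
    if F_out.shape != F_in.shape or F_out.ndim != 1:
        raise ValueError("alignment error: F_out and F_in must be 1-D with equal length")
    D = np.empty_like(F_in)
    D[0] = np.nan
    D[1:] = np.abs(F_out[:-1] - F_in[1:])
    return D


def anomaly_events(labels) -> list[tuple[int, int]]:
    """Maximal runs of abnormal labels, as [start, stop) index pairs."""
    lab = np.asarray(labels).astype(bool)
    edges = np.flatnonzero(np.diff(np.concatenate([[False], lab, [False]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def judgment_margin(D, labels) -> tuple[float, float, float]:
    """(D_thr_no, D_thr_ab, delta_thr) from a labeled D series.

    ``D_thr_no`` is the max of D over normal samples; ``D_thr_ab`` the min
    over anomaly events of the event's peak D.  ``delta_thr`` may be
    negative (no level separates perfectly).  NaN entries (the undefined
    D[0]) are ignored.
    """
    D = np.asarray(D, dtype=float)
    lab = np.asarray(labels).astype(bool)
    if D.shape != lab.shape:
        raise ValueError("alignment error: D and labels must have equal length")
    normal = D[~lab]
    normal = normal[np.isfinite(normal)]
    if normal.size == 0:
        raise ValueError("need at least one normal sample with defined D")
    d_no = float(np.max(normal))
    peaks = []
    for a, b in anomaly_events(lab):
        seg = D[a:b]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            peaks.append(float(np.max(seg)))
    if not peaks:
        raise MarginUndefinedError(d_no)
    d_ab = float(min(peaks))
    return d_no, d_ab, d_ab - d_no


def tpr_fpr_curve(D, labels, thresholds=None) -> pd.DataFrame:
    """Detection/misdetection rates as a function of the judgment level.

    At each level: FPR is the fraction of normal samples with D > level;
    event-level TPR is the fraction of anomaly events whose peak D exceeds
    the level (consistent with TPR = 1 ⇔ level < D_thr_ab); the per-point
    TPR over abnormal samples is reported alongside.
    """
    D = np.asarray(D, dtype=float)
    lab = np.asarray(labels).astype(bool)
    finite = np.isfinite(D)
    normal = D[~lab & finite]
    abnormal = D[lab & finite]
    peaks = np.array([np.nanmax(D[a:b]) for a, b in anomaly_events(lab)] or [np.nan])
    if thresholds is None:
        base = D[finite]
        thresholds = np.unique(np.concatenate([[0.0], base, [base.max() * 1.001 + 1e-9]]))
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    n_events = len(anomaly_events(lab))
    for thr in thresholds:
        fpr = float(np.mean(normal > thr)) if normal.size else 0.0
        tpr_ev = float(np.mean(peaks > thr)) if n_events else np.nan
        tpr_pt = float(np.mean(abnormal > thr)) if abnormal.size else np.nan
        rows.append((fpr, tpr_ev, tpr_pt, thr))
    return pd.DataFrame(rows, columns=["fpr", "tpr_event", "tpr_point", "D_thr"])


# ---------------------------------------------------------------------------
# Three-phase pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full detection run needs (defaults: reference setup)."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    plast: PlasticityConfig = field(default_factory=PlasticityConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    ridge: float = 1e-6
    #: deployment rule when D_thr_ab is unknowable: D_thr = D_thr_no·(1+ε)
    epsilon: float = 0.05


def effective_labels(labels) -> np.ndarray:
    """Labels for judging the D series: events dilated by one sample.

    ``D(k+1)`` compares a prediction made *from* sample k with sample k+1,
    so the first sample after an anomaly event still reflects abnormal
    context; it is attributed to the event rather than to the normal set.
    """
    lab = np.asarray(labels).astype(bool)
    out = lab.copy()
    out[1:] |= lab[:-1]
    return out.astype(np.int8)


@dataclass
class DetectionResult:
    """Output of one Phase 1–3 run on a labeled test segment.

    ``labels`` are the raw per-sample labels; margin, ROC and the rates
    returned by :meth:`rates_at` use the event-dilated ``labels_eff``.
    """

    D: np.ndarray
    labels: np.ndarray
    labels_eff: np.ndarray
    D_thr_no: float
    D_thr_ab: float
    delta_thr: float
    roc: pd.DataFrame
    readout: Readout
    F_in_test: np.ndarray
    F_out_test: np.ndarray
    exc_rates_test: np.ndarray

    @property
    def midpoint_threshold(self) -> float:
        return 0.5 * (self.D_thr_no + self.D_thr_ab)

    def rates_at(self, D_thr: float) -> tuple[float, float, float]:
        """(event TPR, point TPR, FPR) at a given judgment level."""
        row = tpr_fpr_curve(self.D, self.labels_eff, np.array([D_thr]))
        return float(row.tpr_event[0]), float(row.tpr_point[0]), float(row.fpr[0])

    def practical_threshold(self, epsilon: float = 0.05) -> float:
        """Deployment rule: slightly above the largest normal excursion."""
        return self.D_thr_no * (1.0 + epsilon)

    def write_report(self, samples_path, summary_path) -> None:
        pd.DataFrame({"D": self.D, "label": self.labels}).to_csv(samples_path, index_label="k")
        tpr_ev, tpr_pt, fpr = self.rates_at(self.midpoint_threshold)
        with open(summary_path, "w") as fh:
            fh.write(f"D_thr_no\t{self.D_thr_no!r}\n")
            fh.write(f"D_thr_ab\t{self.D_thr_ab!r}\n")
            fh.write(f"delta_thr\t{self.delta_thr!r}\n")
            fh.write(f"midpoint_threshold\t{self.midpoint_threshold!r}\n")
            fh.write(f"tpr_event_at_midpoint\t{tpr_ev!r}\n")
            fh.write(f"tpr_point_at_midpoint\t{tpr_pt!r}\n")
            fh.write(f"fpr_at_midpoint\t{fpr!r}\n")


def _phase_rngs(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(4)]


def phase1_train(net: Network, train_series, cfg: PipelineConfig, rng) -> Network:
    """Phase 1: unsupervised reconstruction by IP + SDSP on normal data."""
    enc = cfg.encoding
    F_train = encode_rate(np.asarray(train_series, dtype=float), enc)
    raster = gen_input_raster(F_train, enc, net.cfg.N_input, rng)
    net.run(raster, len(F_train) * enc.T_bin, plasticity_on=True, record_spikes=False)
    return net

def phase2_fit(net: Network, train_series, cfg: PipelineConfig, rng) -> Readout:
    """Phase 2: plasticity frozen; fit the next-frequency linear readout."""
    enc = cfg.encoding
    F_train = encode_rate(np.asarray(train_series, dtype=float), enc)
    raster = gen_input_raster(F_train, enc, net.cfg.N_input, rng)
    _, trace = net.run(raster, len(F_train) * enc.T_bin, plasticity_on=False,
                       T_bin=enc.T_bin, record_spikes=False)
    return fit_readout(trace.exc_rates[:-1], F_train[1:], ridge=cfg.ridge)

def phase3_detect(net: Network, readout: Readout, test_series, test_labels,
                  cfg: PipelineConfig, rng) -> DetectionResult:
    """Phase 3: plasticity frozen; compute D, margin and ROC on test data."""
    enc = cfg.encoding
    test_labels = np.asarray(test_labels).astype(np.int8)
    F_test = encode_rate(np.asarray(test_series, dtype=float), enc)
    raster = gen_input_raster(F_test, enc, net.cfg.N_input, rng)
    _, trace = net.run(raster, len(F_test) * enc.T_bin, plasticity_on=False,
                       T_bin=enc.T_bin, record_spikes=False)
    rates = trace.exc_rates
    F_out = predict_Fout(readout, rates)
    D = compute_D(F_out, F_test)
    lab_eff = effective_labels(test_labels)
    d_no, d_ab, delta = judgment_margin(D, lab_eff)
    roc = tpr_fpr_curve(D, lab_eff)
    return DetectionResult(
        D=D, labels=test_labels, labels_eff=lab_eff, D_thr_no=d_no, D_thr_ab=d_ab,
        delta_thr=delta, roc=roc, readout=readout, F_in_test=F_test,
        F_out_test=F_out, exc_rates_test=rates,
    )


def run_pipeline(
    train_series,
    test_series,
    test_labels,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
    plasticity: bool = True,
    train_labels=None,
    network: Network | None = None,
) -> DetectionResult:
    """Execute Phases 1–3 and evaluate detection on the test segment.

    With ``plasticity=False`` Phase 1 is skipped entirely, which evaluates
    the initial (unreconstructed) network.  A pre-built ``network`` may be
    supplied to reuse Phase-1 work across evaluations; it is used as-is.
    """
    cfg = cfg or PipelineConfig()
    if train_labels is not None and np.any(np.asarray(train_labels) != 0):
        raise ValueError("training segment must not contain labeled anomalies")
    test_labels = np.asarray(test_labels).astype(np.int8)
    if len(test_labels) != len(np.asarray(test_series)):
        raise ValueError("test labels misaligned with test series")

    rng_build, rng_p1, rng_p2, rng_p3 = _phase_rngs(seed)
    net = network
    if net is None:
        net = build_network(cfg.network, cfg.plast, rng_build, neuron=cfg.neuron)
        if plasticity:
            phase1_train(net, train_series, cfg, rng_p1)
    readout = phase2_fit(net, train_series, cfg, rng_p2)
    return phase3_detect(net, readout, test_series, test_labels, cfg, rng_p3)


# ---------------------------------------------------------------------------
# Parameter-sweep harness
# ---------------------------------------------------------------------------

#: the binary-feasible corner of the learning-rate grid
BINARY_CELL = (2.0, 0.3)


@dataclass
class SweepResult:
    """Tidy per-cell-per-seed table of judgment margins."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def delta_grid(self, row="lr_thr", col="lr_sdsp") -> pd.DataFrame:
        """Mean delta_thr heat-map table over seeds."""
        ok = self.table[self.table.error.isna()] if "error" in self.table else self.table
        return ok.pivot_table(index=row, columns=col, values="delta_thr", aggfunc="mean")


def sweep(
    train_series,
    test_series,
    test_labels,
    base_cfg: PipelineConfig | None = None,
    lr_sdsp_values=(2.0,),
    lr_thr_values=(0.025,),
    tbin_values=None,
    ninput_values=None,
    fpoisson_values=None,
    seeds=(0,),
) -> SweepResult:
    """Grid of full pipeline runs; one row per cell per seed.

    Axes default to single points so that a 1×1 grid equals a direct
    ``run_pipeline`` call.  Per-cell simulation failures are recorded in the
    ``error`` column rather than aborting the sweep.
    """
    base_cfg = base_cfg or PipelineConfig()
    tbin_values = tbin_values or [base_cfg.encoding.T_bin]
    ninput_values = ninput_values or [base_cfg.network.N_input]
    fpoisson_values = fpoisson_values or [base_cfg.encoding.F_poisson]
    grid = list(itertools.product(lr_sdsp_values, lr_thr_values, tbin_values,
                                  ninput_values, fpoisson_values, seeds))
    if not grid:
        raise ValueError("sweep grid is empty")
    rows = []
    for lr_sdsp, lr_thr, tbin, ninput, fpoisson, seed in grid:
        cfg = replace(
            base_cfg,
            plast=replace(base_cfg.plast, LR_SDSP=lr_sdsp, LR_thr=lr_thr),
            encoding=replace(base_cfg.encoding, T_bin=tbin, F_poisson=fpoisson),
            network=replace(base_cfg.network, N_input=ninput),
        )
        rec = {
            "lr_sdsp": lr_sdsp, "lr_thr": lr_thr, "tbin": tbin,
            "ninput": ninput, "fpoisson": fpoisson, "seed": seed,
            "binary_feasible": (lr_sdsp, lr_thr) == BINARY_CELL,
            "d_thr_no": np.nan, "d_thr_ab": np.nan, "delta_thr": np.nan,
            "max_rate": np.nan, "error": None,
        }
        try:
            res = run_pipeline(train_series, test_series, test_labels, cfg, seed=seed)
            rec.update(d_thr_no=res.D_thr_no, d_thr_ab=res.D_thr_ab,
                       delta_thr=res.delta_thr,
                       max_rate=float(res.exc_rates_test.max()))
        except Exception as exc:  # recorded, not fatal
            log.warning("sweep cell %s failed: %s", rec, exc)
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    table = pd.DataFrame(rows)
    table["error"] = table["error"].astype("string")
    return SweepResult(table)
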