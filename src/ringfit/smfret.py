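"""Single-molecule FRET trace analysis for ssDNA wrapping dynamics.

A TIRF microscope records donor and acceptor intensity per 150 ms frame
for each immobilized molecule. This module computes corrected per-frame
FRET efficiencies, segments traces into hidden states with a
Gaussian-emission hidden Markov model (EM fit + Viterbi decoding), and
summarizes occupancies, dwell times and pooled histograms.

The hidden-state segmentation is a plain maximum-likelihood HMM with a
BIC sweep over state counts — a deliberate, documented departure from
variational-Bayes tools that return the same contract (states + dwells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from ._cluster import kmeans1d

log = logging.getLogger(__name__)

# hmmlearn's monitor logs a spurious "not converging" when the loglik
# jitters by ~1e-6 at the optimum; real non-convergence is surfaced via
# monitor_.converged below.
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "FretTrace",
    "StateModel",
    "trace_efficiency",
    "truncate_photobleached",
    "segment_states",
    "state_histogram",
    "dwell_table",
]

#: E values outside this window are physically implausible and flagged
E_WINDOW = (-0.2, 1.2)


@dataclass
class FretTrace:
    """One molecule's background-corrected intensity trace.

    ``crosstalk`` is the donor-leakage fraction alpha (donor emission
    bleeding into the acceptor channel); ``cross_excitation`` is the
    direct-acceptor-excitation fraction delta, which requires an
    acceptor-only reference level ``i_ref`` to apply.
    """

    i_d: np.ndarray
    i_a: np.ndarray
    frame_time: float = 0.150
    crosstalk: float = 0.0
    cross_excitation: float = 0.0
    i_ref: float | None = None
    latent_states: np.ndarray | None = None   # ground truth, if synthetic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_d = np.asarray(self.i_d, dtype=float)
        self.i_a = np.asarray(self.i_a, dtype=float)
        if self.i_d.shape != self.i_a.shape:
            raise ValueError("donor and acceptor channels must have equal length")
        for name in ("crosstalk", "cross_excitation"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {v}")

    def __len__(self) -> int:
        return len(self.i_d)


def trace_efficiency(trace: FretTrace) -> tuple[np.ndarray, bool]:
    """Corrected per-frame FRET efficiency of one trace.

    ``E = A_corr / (A_corr + I_D)`` with
    ``A_corr = I_A - alpha*I_D - delta*I_ref``. With both corrections
    zero this is the plain ratiometric efficiency. If cross-excitation
    correction is requested without an acceptor-only reference, delta is
    forced to 0 and the omission logged.

    Returns ``(E, flagged)``; the trace is flagged when the corrected
    acceptor goes negative on more than 10% of frames. E is reported
    unclipped; values outside [-0.2, 1.2] should be treated as junk
    frames by callers.
    """
    delta = trace.cross_excitation
    if delta > 0 and trace.i_ref is None:
        log.warning("no acceptor-only reference: cross-excitation correction disabled")
        delta = 0.0
    a_corr = trace.i_a - trace.crosstalk * trace.i_d - delta * (trace.i_ref or 0.0)
    total = a_corr + trace.i_d
    bad = total == 0
    if np.any(bad):
        raise ValueError(f"zero total intensity at frame {int(np.flatnonzero(bad)[0])}")
    e = a_corr / total
    flagged = bool(np.mean(a_corr < 0) > 0.10)
    return e, flagged


def truncate_photobleached(trace: FretTrace, floor_fraction: float = 0.25) -> FretTrace:
    """Cut a trace at the photobleaching step.

    Truncates at the last frame before total intensity first falls below
    ``floor_fraction`` of its median; returns the trace unchanged if no
    frame does.
    """
    total = trace.i_d + trace.i_a
    floor = floor_fraction * np.median(total)
    below = np.flatnonzero(total < floor)
    if below.size == 0:
        return trace
    end = int(below[0])
    return FretTrace(
        i_d=trace.i_d[:end], i_a=trace.i_a[:end], frame_time=trace.frame_time,
        crosstalk=trace.crosstalk, cross_excitation=trace.cross_excitation,
        i_ref=trace.i_ref,
        latent_states=None if trace.latent_states is None else trace.latent_states[:end],
        meta=dict(trace.meta),
    )


@dataclass
class StateModel:
    """Fitted hidden-state model over a set of traces."""

    n_states: int
    means: np.ndarray            # per-state E, ascending
    sds: np.ndarray
    transition_matrix: np.ndarray
    occupancies: np.ndarray      # fraction of decoded frames per state
    paths: list                  # per-trace Viterbi path (state indices)
    loglik: float
    loglik_history: np.ndarray
    converged: bool
    bic_table: dict | None = None


def _fit_k(e_concat: np.ndarray, lengths: list[int], k: int, seed: int):
    """Deterministic GaussianHMM fit: quantile-initialized means."""
    X = e_concat.reshape(-1, 1)
    model = GaussianHMM(
        n_components=k, covariance_type="diag", n_iter=500, tol=1e-8,
        random_state=seed, init_params="", params="stmc",
    )
    qs, _ = kmeans1d(e_concat, k)
    model.startprob_ = np.full(k, 1.0 / k)
    if k == 1:
        model.transmat_ = np.ones((1, 1))
    else:
        model.transmat_ = np.full((k, k), 0.1 / (k - 1))
        np.fill_diagonal(model.transmat_, 0.9)
    model.means_ = qs.reshape(-1, 1)
    spread = max(np.std(e_concat) / max(k, 1), 1e-3)
    model.covars_ = np.full((k, 1), spread**2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, lengths)
    history = np.array(model.monitor_.history, dtype=float)
    loglik = float(model.score(X, lengths))
    return model, loglik, history


def segment_states(
    traces,
    K: int | None = None,
    seed: int = 0,
    k_max: int = 4,
) -> StateModel:
    """Hidden-state segmentation of FRET traces.

    Computes corrected E per trace, fits a Gaussian-emission hidden
    Markov model with ``K`` states by expectation-maximization
    (deterministic: means initialized at pooled-E quantiles), and
    Viterbi-decodes each trace. With ``K=None`` the state count is
    chosen by a BIC sweep over 1..``k_max``.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    es = [trace_efficiency(t)[0] for t in traces]
    lengths = [len(e) for e in es]
    e_concat = np.concatenate(es)
    n = e_concat.size

    bic_table = None
    if K is None:
        bic_table = {}
        for k in range(1, k_max + 1):
            if n < 50 * k:
                break
            try:
                _, ll, _ = _fit_k(e_concat, lengths, k, seed)
            except Exception:  # noqa: BLE001 - candidate simply dropped
                continue
            n_par = k * k - 1 + 2 * k  # transmat+start (k^2-1 free) + means + vars
            bic_table[k] = -2.0 * ll + n_par * np.log(n)
        if not bic_table:
            raise RuntimeError("BIC sweep produced no valid state model")
        K = min(bic_table, key=bic_table.get)
    if n < 50 * K:
        raise ValueError(f"need >= {50 * K} pooled frames for {K} states, got {n}")

    model, loglik, history = _fit_k(e_concat, lengths, K, seed)
    converged = bool(model.monitor_.converged)
    if not converged:
        warnings.warn("HMM EM hit the iteration cap before converging", stacklevel=2)

    # sort states by mean E
    order = np.argsort(model.means_[:, 0])
    means = model.means_[order, 0]
    sds = np.sqrt(model.covars_.reshape(K, -1)[order, 0])
    transmat = model.transmat_[np.ix_(order, order)]
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(K)

    paths = []
    for e in es:
        path = model.predict(e.reshape(-1, 1))
        paths.append(rank[path])
    all_states = np.concatenate(paths)
    occ = np.bincount(all_states, minlength=K) / all_states.size
    return StateModel(
        n_states=K, means=means, sds=sds, transition_matrix=transmat,
        occupancies=occ, paths=paths, loglik=loglik,
        loglik_history=history, converged=converged, bic_table=bic_table,
    )


def dwell_table(model: StateModel, frame_time: float = 0.150) -> list[dict]:
    """Run-length encode Viterbi paths into dwell events.

    One row per contiguous visit: trace index, state, duration in frames
    and seconds. Durations within each trace sum to the trace length.
    """
    rows = []
    for i, path in enumerate(model.paths):
        if len(path) == 0:
            continue
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(path)]))
        for s, e in zip(starts, ends):
            rows.append({
                "trace": i, "state": int(path[s]),
                "frames": int(e - s), "seconds": float((e - s) * frame_time),
            })
    return rows


def state_histogram(traces, bin_width: float = 0.05) -> dict:
    """Frame-weighted pooled FRET histogram over [0, 1].

    Returns bin edges, centers, counts, density and the mode bin center.
    Frames outside [0, 1] (possible after corrections) are excluded from
    the pooled histogram but counted in ``n_excluded``.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    if not 0 < bin_width <= 0.2:
        raise ValueError("bin width must be in (0, 0.2]")
    e = np.concatenate([trace_efficiency(t)[0] for t in traces])
    in_range = (e >= 0) & (e <= 1)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(e[in_range], bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[int(np.argmax(counts))])
    return {
        "edges": edges, "centers": centers, "counts": counts,
        "density": counts / max(counts.sum(), 1) / bin_width,
        "mode": mode, "n_frames": int(e.size), "n_excluded": int((~in_range).sum()),
    }
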