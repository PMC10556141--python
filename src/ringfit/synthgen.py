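"""Synthetic datasets with the statistical structure of each assay.

Every generator draws from numpy's default PCG64 generator seeded
explicitly, so a fixed seed gives bit-identical output, and every
generator returns its latent truth alongside the observations so that
downstream recovery tests compare against truth rather than constants.

Default truth parameters are the study conditions of the assays being
emulated: a 50 nM ring (decamer) titrated with poly(dT), biphasic
saturation at 56 and 158 nt per ring; a three-component landing-event
mixture at 72.9 / 498.4 / 991.8 kDa with ~5/85/10 % weights; bimodal
deuterium-uptake distributions with a 30 % low-uptake population;
four-state FRET traces dominated by a state at E = 0.2, 150 ms frames.
Noise magnitudes are not printed anywhere for these assays; the
defaults here (2 % multiplicative signal noise and the artifact rates
below) are stated as package choices in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binding import BindingModel, TitrationSeries, predict_titration
from .corrections import CorrectionLedger, correct_fluorescence, normalized_quenching
from .smfret import FretTrace
from .stoichiometry import MassEventSet

__all__ = [
    "TitrationTruth",
    "TitrationDataset",
    "gen_titration",
    "DEFAULT_MP_COMPONENTS",
    "gen_mp_events",
    "HdxBimodalDataset",
    "gen_hdx_bimodal",
    "FretTruth",
    "gen_fret_traces",
]


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TitrationTruth:
    """Latent truth of a synthetic quenching titration.

    ``breakpoints`` are cumulative occluded site sizes (nt per ring) and
    ``plateaus`` the quenching level reached at each: the latent curve is
    piecewise linear through (0, 0), (b_i, p_i), flat past the last
    corner — the stoichiometric (tight-binding) regime. Alternatively a
    :class:`~ringfit.binding.BindingModel` can supply a smooth isotherm
    latent curve (``mode="isotherm"``).
    """

    breakpoints: tuple = (56.0, 158.0)
    plateaus: tuple = (0.45, 0.75)
    protein_nM: float = 50.0
    model: BindingModel | None = None
    mode: str = "segments"   # "segments" | "isotherm"

    def latent(self, x: np.ndarray) -> np.ndarray:
        if self.mode == "isotherm":
            if self.model is None:
                raise ValueError("isotherm mode requires a BindingModel")
            return predict_titration(self.model, x)
        if self.mode != "segments":
            raise ValueError(f"unknown latent mode {self.mode!r}")
        xp = np.concatenate(([0.0], np.asarray(self.breakpoints, dtype=float)))
        fp = np.concatenate(([0.0], np.asarray(self.plateaus, dtype=float)))
        if np.any(np.diff(xp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        return np.interp(x, xp, fp)   # flat extrapolation past the last corner


@dataclass
class TitrationDataset:
    """Observed series plus the full per-step ledger and latent truth."""

    series: TitrationSeries          # corrected signal (from the raw ledger)
    ledger: CorrectionLedger         # exact V_i, f_i bookkeeping
    raw: np.ndarray                  # artifact-contaminated fluorescence
    clean_signal: np.ndarray         # latent quenching, noise- and artifact-free
    truth: TitrationTruth
    seed: int

    def truth_dict(self) -> dict:
        return {
            "breakpoints": list(self.truth.breakpoints),
            "plateaus": list(self.truth.plateaus),
            "protein_nM": self.truth.protein_nM,
            "mode": self.truth.mode,
            "seed": self.seed,
        }


def gen_titration(
    truth: TitrationTruth | None = None,
    n_steps: int = 30,
    max_x: float = 250.0,
    noise_sd: float = 0.02,
    dilution_per_step: float = 0.0015,
    photobleach_per_scan: float = 0.002,
    f0_counts: float = 1.0e5,
    v0_mL: float = 1.2,
    schedule: str = "linear",
    seed: int = 0,
) -> TitrationDataset:
    """Synthesize one cuvette titration with realistic artifacts.

    The latent quenching curve is contaminated in reverse order of the
    correction algebra: the clean fluorescence ``F0*(1 - q(x))`` is
    diluted (volume grows by ``dilution_per_step`` per addition),
    photobleached (reference decays by ``photobleach_per_scan`` per
    scan), and multiplied by ``1 + eps`` with ``eps ~ N(0, noise_sd)``.
    The returned dataset carries the exact per-step volume and
    photobleach ledgers so the correction round-trip is testable, plus
    the corrected quenching series ready for fitting.

    Total dilution is required to stay within 5 % of the initial
    volume, matching standard titration practice.
    """
    truth = truth or TitrationTruth()
    if n_steps < 5:
        raise ValueError("need at least 5 titration steps")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    for name, v in (("dilution_per_step", dilution_per_step),
                    ("photobleach_per_scan", photobleach_per_scan)):
        if not 0 <= v <= 0.05:
            raise ValueError(f"{name} must be in [0, 0.05], got {v}")
    if truth.mode == "segments" and max_x <= max(truth.breakpoints):
        raise ValueError("max_x must exceed the largest breakpoint")
    total_dilution = (1 + dilution_per_step) ** (n_steps - 1) - 1
    if total_dilution > 0.05:
        raise ValueError(
            f"total dilution {total_dilution:.1%} exceeds the 5% budget; "
            "reduce dilution_per_step or n_steps"
        )

    rng = np.random.default_rng(seed)
    if schedule == "linear":
        x = np.linspace(0.0, max_x, n_steps)
    elif schedule == "log":
        # dense early points resolve a tight first phase
        x = np.concatenate(([0.0], np.geomspace(max_x / 200.0, max_x, n_steps - 1)))
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("ligand schedule must be strictly increasing")
    q = truth.latent(x)

    steps = np.arange(n_steps)
    V = v0_mL * (1 + dilution_per_step) ** steps
    f = f0_counts * (1 - photobleach_per_scan) ** steps
    F_clean = f0_counts * (1.0 - q)
    # invert the correction algebra, then add multiplicative read noise
    F_raw_noiseless = F_clean * (v0_mL / V) * (f / f0_counts)
    F_raw = F_raw_noiseless * (1.0 + noise_sd * rng.standard_normal(n_steps))

    ledger = CorrectionLedger(F_raw=F_raw, V=V, f=f, V0=v0_mL, f0=f0_counts)
    F_corr = correct_fluorescence(ledger)
    signal = normalized_quenching(F_corr[0], F_corr)
    series = TitrationSeries(
        x=x, signal=signal, protein_nM=truth.protein_nM,
        meta={"ligand": "poly(dT)", "ligand_length_nt": 1100, "seed": seed},
    )
    return TitrationDataset(
        series=series, ledger=ledger, raw=F_raw, clean_signal=q,
        truth=truth, seed=seed,
    )


# ---------------------------------------------------------------------------
# Mass-photometry landing events
# ---------------------------------------------------------------------------

#: (mean kDa, sd kDa, weight): free monomer, ring, ring-of-rings dimer
DEFAULT_MP_COMPONENTS = (
    (72.9, 13.9, 0.05),
    (498.4, 23.8, 0.85),
    (991.8, 75.34, 0.10),
)


def gen_mp_events(
    components=DEFAULT_MP_COMPONENTS,
    n_events: int = 5000,
    seed: int = 0,
) -> MassEventSet:
    """Draw landing-event masses from a Gaussian mixture.

    ``components`` is a sequence of ``(mean_kDa, sd_kDa, weight)``;
    weights must be positive and sum to 1. Component labels are retained
    on the returned event set for truth-aware recovery tests.
    """
    comps = [(float(m), float(s), float(w)) for m, s, w in components]
    weights = np.array([c[2] for c in comps])
    if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("component weights must be positive and sum to 1")
    if any(c[1] <= 0 for c in comps):
        raise ValueError("component sds must be positive")
    if n_events < 10 * len(comps):
        warnings.warn(
            f"{n_events} events for {len(comps)} components: "
            "a mixture fit will be unidentifiable", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(comps), size=n_events, p=weights)
    means = np.array([c[0] for c in comps])
    sds = np.array([c[1] for c in comps])
    masses = rng.normal(means[labels], sds[labels])
    return MassEventSet(events=masses, calibration_applied=True, labels=labels)


# ---------------------------------------------------------------------------
# HDX bimodal centroid-intensity distributions
# ---------------------------------------------------------------------------

@dataclass
class HdxBimodalDataset:
    centers: np.ndarray      # centroid-mass bin centers, Da
    intensity: np.ndarray    # counts per bin
    truth: dict
    seed: int


def gen_hdx_bimodal(
    means_Da: tuple = (8.0, 11.0),
    widths_Da: tuple = (0.6, 0.6),
    f1: float = 0.30,
    bin_width_Da: float = 0.25,
    n_draws: int = 1000,
    seed: int = 0,
) -> HdxBimodalDataset:
    """Binned bimodal centroid-intensity distribution for one peptide.

    Two exchanger populations at ``means_Da`` (low then high uptake)
    with Gaussian widths; ``f1`` is the intensity fraction of the
    low-uptake population. Ions are drawn from the mixture and binned on
    a fixed grid spanning both modes, so the integrated low-uptake mass
    fraction equals ``f1`` up to sampling error.
    """
    m1, m2 = float(means_Da[0]), float(means_Da[1])
    w1, w2 = float(widths_Da[0]), float(widths_Da[1])
    if w1 <= 0 or w2 <= 0:
        raise ValueError("population widths must be positive")
    if not 0 <= f1 <= 1:
        raise ValueError("f1 must be in [0, 1]")
    if m2 < m1:
        raise ValueError("low-uptake mean must not exceed high-uptake mean")
    rng = np.random.default_rng(seed)
    labels = rng.random(n_draws) >= f1   # False -> population 1 (low uptake)
    mu = np.where(labels, m2, m1)
    sd = np.where(labels, w2, w1)
    draws = rng.normal(mu, sd)
    lo = m1 - 5 * max(w1, w2)
    hi = m2 + 5 * max(w1, w2)
    edges = np.arange(lo, hi + bin_width_Da, bin_width_Da)
    counts, edges = np.histogram(draws, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return HdxBimodalDataset(
        centers=centers, intensity=counts.astype(float),
        truth={"means_Da": [m1, m2], "widths_Da": [w1, w2], "f1": f1,
               "n_draws": n_draws, "seed": seed},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# smFRET traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FretTruth:
    """Ground truth for synthetic wrapping-state traces.

    Up to four hidden states with mean E and stationary occupancy.
    Dwell times are geometric (discrete-frame memoryless). The chain is
    an independence sampler — ``T[i, j] = c * occ_j`` for ``j != i`` —
    whose stationary distribution is exactly ``occupancies``; the rate
    ``c`` is set so the DOMINANT state's mean dwell equals
    ``dwell_mean_frames`` (other states' dwells follow as
    ``dwell * (1 - occ_dom) / (1 - occ_i)``, necessarily shorter for
    rarer states). Only the dominant E = 0.2 state is a printed study
    value; the remaining means are qualitative.
    """

    state_means: tuple = (0.2, 0.4, 0.6, 0.8)
    occupancies: tuple = (0.70, 0.15, 0.10, 0.05)
    dwell_mean_frames: float = 20.0
    total_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if len(self.state_means) != len(self.occupancies):
            raise ValueError("state_means and occupancies must have equal length")
        if len(self.state_means) > 4:
            raise ValueError("at most 4 states")
        if any(not 0 <= m <= 1 for m in self.state_means):
            raise ValueError("state means must lie in [0, 1]")
        if abs(sum(self.occupancies) - 1.0) > 1e-9:
            raise ValueError("occupancies must sum to 1")
        if self.dwell_mean_frames < 1:
            raise ValueError("mean dwell must be at least one frame")

    def transition_matrix(self) -> np.ndarray:
        k = len(self.state_means)
        if k == 1:
            return np.ones((1, 1))
        occ = np.asarray(self.occupancies)
        dom = int(np.argmax(occ))
        c = 1.0 / (self.dwell_mean_frames * (1.0 - occ[dom]))
        if np.any(c * (1.0 - occ) > 1.0):
            raise ValueError(
                "dwell_mean_frames too short for the requested occupancies "
                "(leave probability would exceed 1 for a rare state)"
            )
        T = c * np.tile(occ, (k, 1))
        np.fill_diagonal(T, 1.0 - c * (1.0 - occ))
        return T


def gen_fret_traces(
    truth: FretTruth | None = None,
    n_traces: int = 20,
    frames_per_trace: int = 300,
    frame_time: float = 0.150,
    noise_sd: float = 30.0,
    seed: int = 0,
) -> list[FretTrace]:
    """Simulate donor/acceptor intensity traces from a hidden Markov chain.

    Each frame's latent state sets E; channel intensities are
    ``I_A = E * I_tot + noise`` and ``I_D = (1-E) * I_tot + noise`` with
    additive Gaussian camera noise (sd in counts). Frames whose noisy
    total would be zero or negative are redrawn, never emitted. Latent
    state paths are retained on each trace.
    """
    truth = truth or FretTruth()
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = np.random.default_rng(seed)
    k = len(truth.state_means)
    T = truth.transition_matrix()
    occ = np.asarray(truth.occupancies)
    means = np.asarray(truth.state_means)
    traces = []
    for _ in range(n_traces):
        states = np.empty(frames_per_trace, dtype=int)
        states[0] = rng.choice(k, p=occ)
        for t in range(1, frames_per_trace):
            states[t] = rng.choice(k, p=T[states[t - 1]])
        e = means[states]
        i_a = e * truth.total_intensity
        i_d = (1.0 - e) * truth.total_intensity
        if noise_sd > 0:
            na = i_a + noise_sd * rng.standard_normal(frames_per_trace)
            nd = i_d + noise_sd * rng.standard_normal(frames_per_trace)
            for _attempt in range(100):
                bad = np.flatnonzero((na + nd) <= 0)
                if bad.size == 0:
                    break
                # redraw only the offending frames from the clean values
                na[bad] = i_a[bad] + noise_sd * rng.standard_normal(bad.size)
                nd[bad] = i_d[bad] + noise_sd * rng.standard_normal(bad.size)
            else:  # pragma: no cover - needs pathological noise levels
                raise RuntimeError("could not draw positive-total frames")
            i_a, i_d = na, nd
        traces.append(FretTrace(
            i_d=i_d, i_a=i_a, frame_time=frame_time,
            latent_states=states,
            meta={"truth_occupancies": list(truth.occupancies),
                  "truth_means": list(truth.state_means)},
        ))
    return traces
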