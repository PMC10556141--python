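"""Signal-correction algebra for ensemble fluorescence assays.

Four small, exact transformations shared by the titration and FRET
pipelines:

* dilution / photobleaching / inner-filter correction of raw
  fluorescence, ``F_corr = F_raw * (V/V0) * (1/C) * (f0/f)``;
* quantum-yield correction of fluorescence anisotropy, which converts a
  measured anisotropy into the value it would take if the bound and free
  fluorophore were equally bright;
* ratiometric FRET efficiency ``E = I_A / (I_A + I_D)`` for ensemble
  spectra (deliberately without crosstalk terms — single-molecule
  corrections live in :mod:`ringfit.smfret`);
* normalized quenching ``|ΔF| / F0``.

All functions are vectorized over numpy arrays and validate their
physical preconditions, naming the offending step in the error message.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrectionLedger",
    "AnisotropyResult",
    "correct_fluorescence",
    "correct_anisotropy",
    "fret_efficiency",
    "normalized_quenching",
]


@dataclass
class CorrectionLedger:
    """Per-step bookkeeping needed to correct a cuvette titration.

    Parameters
    ----------
    F_raw : array
        Measured fluorescence at each step (counts).
    V : array
        Cuvette volume after each step (mL); non-decreasing, ``V[0]`` may
        exceed ``V0`` if the first read follows an addition.
    f : array
        Photobleach-reference fluorescence at each step: the signal of an
        identical sample never exposed to ligand, so any decay is
        photobleaching alone.
    V0 : float, optional
        Initial volume before titration; defaults to ``V[0]``.
    f0 : float, optional
        Initial photobleach-reference fluorescence; defaults to ``f[0]``.
    C : float
        Inner-filter correction factor. Defaults to 1, appropriate when
        the sample optical density is well below 0.1.
    sem : array, optional
        Per-step SEM of ``F_raw`` (e.g. from triplicate scans).
    """

    F_raw: np.ndarray
    V: np.ndarray
    f: np.ndarray
    V0: float | None = None
    f0: float | None = None
    C: float = 1.0
    sem: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.F_raw = np.asarray(self.F_raw, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        if self.V0 is None:
            self.V0 = float(self.V[0])
        if self.f0 is None:
            self.f0 = float(self.f[0])
        self.validate()

    def validate(self) -> None:
        n = len(self.F_raw)
        if len(self.V) != n or len(self.f) != n:
            raise ValueError("F_raw, V and f must have equal length")
        if self.C <= 0:
            raise ValueError(f"inner-filter factor C must be > 0, got {self.C}")
        bad = np.flatnonzero(self.f <= 0)
        if bad.size:
            raise ValueError(f"photobleach reference f <= 0 at step {bad[0]}")
        bad = np.flatnonzero(self.V < self.V0 - 1e-12)
        if bad.size:
            raise ValueError(
                f"volume V ({self.V[bad[0]]}) below initial V0 ({self.V0}) at step {bad[0]}"
            )
        if np.any(np.diff(self.V) < -1e-12):
            step = int(np.flatnonzero(np.diff(self.V) < -1e-12)[0]) + 1
            raise ValueError(f"volume decreases at step {step}")


def correct_fluorescence(ledger: CorrectionLedger) -> np.ndarray:
    """Correct raw fluorescence for dilution, photobleaching, inner filter.

    Returns ``F_raw * (V/V0) * (1/C) * (f0/f)`` per step. If the ledger
    carries per-point SEMs they are propagated through the same linear
    factor and stored as ``ledger.sem_corr``.
    """
    factor = (ledger.V / ledger.V0) * (1.0 / ledger.C) * (ledger.f0 / ledger.f)
    if ledger.sem is not None:
        # linear map => SEM scales by the same factor
        ledger.sem_corr = ledger.sem * factor
    return ledger.F_raw * factor


@dataclass(frozen=True)
class AnisotropyResult:
    A_c: float
    bound_fraction: float
    flagged: bool


def correct_anisotropy(
    A: float,
    A_f: float,
    A_b: float,
    Q_f: float,
    Q_b: float,
    flag_tolerance: float = 0.02,
) -> AnisotropyResult:
    """Quantum-yield-corrected anisotropy of a partially bound fluorophore.

    With ``r = ((A - A_f) / (A_b - A)) * (Q_f / Q_b)`` the corrected value
    is ``A_c = (r * A_b + A_f) / (1 + r)``; ``r / (1 + r)`` is the bound
    fraction implied by the two-state model. When ``Q_f == Q_b`` the
    correction is the identity.

    Points outside ``[A_f, A_b]`` by more than ``flag_tolerance *
    (A_b - A_f)`` are returned flagged (never clipped); within tolerance
    they are clamped to the nearest endpoint before the algebra.
    """
    if Q_f <= 0 or Q_b <= 0:
        raise ValueError("quantum yields must be positive")
    if not A_f < A_b:
        raise ValueError(f"require A_f < A_b, got A_f={A_f}, A_b={A_b}")
    span = A_b - A_f
    flagged = bool(A < A_f - flag_tolerance * span or A > A_b + flag_tolerance * span)
    A_eff = float(np.clip(A, A_f, A_b))
    if A_eff == A_b:  # r -> inf limit
        return AnisotropyResult(A_c=A_b, bound_fraction=1.0, flagged=flagged)
    r = ((A_eff - A_f) / (A_b - A_eff)) * (Q_f / Q_b)
    A_c = (r * A_b + A_f) / (1.0 + r)
    return AnisotropyResult(A_c=float(A_c), bound_fraction=float(r / (1.0 + r)), flagged=flagged)


def fret_efficiency(I_A, I_D):
    """Ratiometric FRET efficiency ``I_A / (I_A + I_D)`` for ensemble spectra.

    Inputs are background-subtracted intensities; no crosstalk or
    cross-excitation terms are applied at the spectrum level. Scalar in,
    scalar out; arrays are handled elementwise.
    """
    I_A = np.asarray(I_A, dtype=float)
    I_D = np.asarray(I_D, dtype=float)
    if np.any(I_A < 0) or np.any(I_D < 0):
        raise ValueError("intensities must be non-negative (background-subtracted)")
    total = I_A + I_D
    if np.any(total == 0):
        raise ValueError("I_A + I_D = 0: FRET efficiency undefined")
    out = I_A / total
    return float(out) if out.ndim == 0 else out


def normalized_quenching(F_0: float, F_series) -> np.ndarray:
    """Absolute fluorescence change normalized to the initial value.

    ``|F_0 - F_i| / F_0`` per step — the standard presentation of a
    tryptophan-quenching titration.
    """
    if F_0 <= 0:
        raise ValueError("initial fluorescence F_0 must be > 0")
    F = np.asarray(F_series, dtype=float)
    out = np.abs(F_0 - F) / F_0
    return float(out) if out.ndim == 0 else out
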