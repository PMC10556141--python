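"""Mass-photometry analysis: contrast-to-mass calibration, Gaussian-mixture
deconvolution of landing events, and oligomer stoichiometry calls.

A mass photometer reports one interferometric-scattering contrast per
particle landing; a linear calibration against protein standards maps
contrast to molecular mass. The mass histogram of a ring-forming protein
is a mixture of Gaussian components (free monomer, the ring, a
ring-of-rings dimer, ...) and the analysis task is to recover each
component's mean mass and share of events.

Two deconvolution routes are provided:

* :func:`fit_mixture` — expectation-maximization on the raw event
  masses. Canonical: binning loses information.
* :func:`fit_mixture_histogram` — least squares of an explicit
  sum-of-Gaussians to the binned histogram, the form in which mass-
  photometry software usually presents the fit.

Reported component fractions are event (mass) fractions, i.e. mixture
weights, not amplitude ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._cluster import kmeans1d

__all__ = [
    "MassEventSet",
    "Calibration",
    "MixtureFit",
    "StoichiometryCall",
    "calibrate",
    "fit_mixture",
    "fit_mixture_histogram",
    "call_stoichiometry",
]

#: instrument sensitivity floor; events below are flagged unreliable
SENSITIVITY_FLOOR_KDA = 50.0


@dataclass
class MassEventSet:
    """Per-event masses (kDa) or raw contrasts from one acquisition."""

    events: np.ndarray
    calibration_applied: bool = True
    labels: np.ndarray | None = None   # ground-truth component labels, if synthetic

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.size < 1:
            raise ValueError("event set must contain at least one event")
        if not np.all(np.isfinite(self.events)):
            raise ValueError("event masses must be finite")

    @property
    def n(self) -> int:
        return self.events.size

    def flag_sub_sensitivity(self, floor: float = SENSITIVITY_FLOOR_KDA) -> np.ndarray:
        """Boolean mask of events below the instrument sensitivity floor."""
        return self.events < floor


@dataclass(frozen=True)
class Calibration:
    """Linear contrast -> mass map fitted to standards."""

    slope: float
    intercept: float
    r_squared: float
    standards: tuple   # (name, known_kDa, contrast) triples

    def to_mass(self, contrast) -> np.ndarray:
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept


def calibrate(standards) -> Calibration:
    """Ordinary least-squares contrast-to-mass line from >= 2 standards.

    ``standards`` is an iterable of ``(name, known_kDa, contrast)``
    triples, e.g. the three species of a beta-amylase preparation plus
    thyroglobulin.
    """
    standards = [(str(n), float(m), float(c)) for n, m, c in standards]
    if len(standards) < 2:
        raise ValueError("need at least 2 standards to calibrate")
    contrast = np.array([s[2] for s in standards])
    mass = np.array([s[1] for s in standards])
    if np.ptp(contrast) == 0:
        raise ValueError("standards have identical contrast: degenerate calibration")
    res = stats.linregress(contrast, mass)
    if res.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return Calibration(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), standards=tuple(standards),
    )


@dataclass
class MixtureFit:
    """Gaussian-mixture deconvolution result, components sorted by mean."""

    n_components: int
    means: np.ndarray            # kDa
    sds: np.ndarray              # kDa
    mass_fractions: np.ndarray   # share of events per component, sums to 1
    loglik: float
    loglik_history: np.ndarray   # per-EM-iteration loglik (monotone)
    converged: bool
    n_iter: int
    n_restarts: int = 0

    @property
    def dominant(self) -> int:
        """Index of the highest-mass-fraction component."""
        return int(np.argmax(self.mass_fractions))

    def bic(self, n: int) -> float:
        k = 3 * self.n_components - 1
        return -2.0 * self.loglik + k * np.log(n)


def _em_init(x: np.ndarray, k: int, rng: np.random.Generator, jitter: bool):
    """K-means initialization (deterministic unless jittered)."""
    means, labels = kmeans1d(x, k)
    sds = np.empty(k)
    weights = np.empty(k)
    for j in range(k):
        sel = labels == j
        weights[j] = max(sel.mean(), 1.0 / x.size)
        sds[j] = max(x[sel].std(), 1e-3 * max(abs(means[j]), 1.0)) if np.any(sel) \
            else max(x.std() / k, 1e-3)
    weights /= weights.sum()
    if jitter:
        means = means * (1.0 + 0.05 * rng.standard_normal(k))
        sds = sds * np.exp(0.2 * rng.standard_normal(k))
    return weights, means, sds


def _em_run(x, weights, means, sds, max_iter, tol, min_sd):
    n = x.size
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities via log-sum-exp
        logpdf = (
            np.log(weights)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds)[None, :] - 0.5 * np.log(2 * np.pi)
        )
        mx = logpdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        loglik = float(lse.sum())
        history.append(loglik)
        resp = np.exp(logpdf - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return None, np.array(history), it  # empty component
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < min_sd):
            return None, np.array(history), it  # component collapse
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol * abs(history[-2]):
            converged = True
            break
    return (weights, means, sds, converged), np.array(history), it


def fit_mixture(
    events: MassEventSet | np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    rel_tol: float = 1e-8,
    min_sd_kDa: float = 1.0,
    max_restarts: int = 5,
    exclude_sub_sensitivity: bool = False,
) -> MixtureFit:
    """EM fit of a Gaussian mixture to raw landing-event masses.

    Initialization comes from a deterministic 1-D k-means on the events,
    so the first start is reproducible; the seed only matters if a
    component collapses (sd below ``min_sd_kDa`` on calibrated data, or
    a scale-relative floor on raw contrasts) or empties and a jittered
    restart is needed (up to ``max_restarts``). Convergence: relative
    log-likelihood change below ``rel_tol``.

    With ``exclude_sub_sensitivity`` events below the ~50 kDa
    instrument floor are dropped before fitting (they are otherwise kept
    and merely flagged by :meth:`MassEventSet.flag_sub_sensitivity`).
    """
    if not isinstance(events, MassEventSet):
        events = MassEventSet(events)
    x = events.events
    if exclude_sub_sensitivity:
        x = x[x >= SENSITIVITY_FLOOR_KDA]
    if x.size < 10 * n_components:
        warnings.warn(
            f"{x.size} events for {n_components} components: "
            "mixture fit may be unidentifiable", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # the collapse floor is in kDa for calibrated events; for raw contrasts
    # fall back to a scale-relative floor
    min_sd = min_sd_kDa if events.calibration_applied \
        else 1e-4 * max(np.ptp(x), 1e-12)
    history = np.array([])
    it = 0
    result = None
    restarts = 0
    for attempt in range(max_restarts + 1):
        w0, m0, s0 = _em_init(x, n_components, rng, jitter=attempt > 0)
        result, history, it = _em_run(x, w0, m0, s0, max_iter, rel_tol, min_sd)
        if result is not None:
            restarts = attempt
            break
    if result is None:
        raise RuntimeError(
            f"mixture EM collapsed in all {max_restarts + 1} starts "
            f"(component sd < {min_sd} or empty component)"
        )
    weights, means, sds, converged = result
    if not converged:
        warnings.warn("mixture EM hit the iteration cap before converging", stacklevel=2)
    order = np.argsort(means)
    return MixtureFit(
        n_components=n_components,
        means=means[order], sds=sds[order], mass_fractions=weights[order],
        loglik=float(history[-1]), loglik_history=history,
        converged=bool(converged), n_iter=it, n_restarts=restarts,
    )


def fit_mixture_histogram(
    events: MassEventSet | np.ndarray,
    n_components: int,
    bin_width_kDa: float = 5.0,
    seed: int = 0,
) -> MixtureFit:
    """Sum-of-Gaussians least squares on the binned event histogram.

    The literal histogram-domain form ``f(x) = sum_i a_i exp(-((x-b_i)/c_i)^2)``
    (note the convention: ``c_i`` here absorbs the sqrt(2), as mass-
    photometry software writes it; reported sds are ``c_i/sqrt(2)`` so
    both routes share units). Event fractions are recovered from the
    component areas ``a_i * c_i``.
    """
    if not isinstance(events, MassEventSet):
        events = MassEventSet(events)
    x = events.events
    edges = np.arange(x.min() - bin_width_kDa, x.max() + 2 * bin_width_kDa, bin_width_kDa)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    em = fit_mixture(events, n_components, seed=seed)  # initialize from EM

    def model(c, *theta):
        a = np.asarray(theta[:n_components])
        b = np.asarray(theta[n_components:2 * n_components])
        w = np.asarray(theta[2 * n_components:])
        return (a[None, :] * np.exp(-(((c[:, None] - b[None, :]) / w[None, :]) ** 2))).sum(axis=1)

    a0 = em.mass_fractions * x.size * bin_width_kDa / (em.sds * np.sqrt(2 * np.pi))
    p0 = np.concatenate([a0, em.means, em.sds * np.sqrt(2.0)])
    lo = np.concatenate([np.zeros(n_components), np.full(n_components, x.min()),
                         np.full(n_components, 1e-3)])
    hi = np.concatenate([np.full(n_components, np.inf), np.full(n_components, x.max()),
                         np.full(n_components, np.inf)])
    popt, _ = optimize.curve_fit(model, centers, counts, p0=p0, bounds=(lo, hi), maxfev=20000)
    a = popt[:n_components]
    b = popt[n_components:2 * n_components]
    w = popt[2 * n_components:]
    areas = a * w  # proportional to sqrt(pi) * a * w
    frac = areas / areas.sum()
    order = np.argsort(b)
    resid = counts - model(centers, *popt)
    pseudo_ll = -0.5 * float(resid @ resid)
    return MixtureFit(
        n_components=n_components,
        means=b[order], sds=(w / np.sqrt(2.0))[order], mass_fractions=frac[order],
        loglik=pseudo_ll, loglik_history=np.array([pseudo_ll]),
        converged=True, n_iter=1,
    )


def select_n_components(
    events: MassEventSet | np.ndarray, k_max: int = 4, seed: int = 0
) -> MixtureFit:
    """BIC sweep over 1..k_max components; returns the winning EM fit."""
    if not isinstance(events, MassEventSet):
        events = MassEventSet(events)
    best = None
    for k in range(1, k_max + 1):
        if events.n < 10 * k:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = fit_mixture(events, k, seed=seed)
            except RuntimeError:
                continue
        b = fit.bic(events.n)
        if best is None or b < best[0]:
            best = (b, fit)
    if best is None:
        raise RuntimeError("no component count produced a valid mixture fit")
    return best[1]


@dataclass(frozen=True)
class StoichiometryCall:
    """Nearest-integer subunit count for a measured species mass."""

    species_mass: float
    monomer_mass: float
    n_subunits: int
    residual_fraction: float


def call_stoichiometry(species_mass: float, monomer_mass: float) -> StoichiometryCall:
    """Call the oligomeric state of a species from its measured mass.

    ``n = round(species_mass / monomer_mass)`` with exact .5 ratios
    rounded up (not banker's rounding). The residual fraction
    ``|mass - n*monomer| / (n*monomer)`` quantifies how clean the call
    is; disordered or extended proteins can carry several percent.
    """
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be positive")
    ratio = species_mass / monomer_mass
    if ratio < 0.5:
        raise ValueError(
            f"species mass {species_mass} kDa is below half a monomer "
            f"({monomer_mass} kDa): not an oligomer of this subunit"
        )
    n = int(np.floor(ratio + 0.5))  # ties round up
    resid = abs(species_mass - n * monomer_mass) / (n * monomer_mass)
    return StoichiometryCall(
        species_mass=float(species_mass), monomer_mass=float(monomer_mass),
        n_subunits=n, residual_fraction=float(resid),
    )
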