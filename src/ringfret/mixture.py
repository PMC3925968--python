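"""Corrected FRET efficiencies and unbinned Gaussian-mixture inference.

Per-molecule efficiencies are corrected for donor leakage ``l`` into the
acceptor channel and for the detection-factor ``gamma``:

    E = (I_A - l * I_D) / (I_A + gamma * I_D).

The efficiency sample of each condition is fitted with an m-component
Gaussian mixture by direct maximum likelihood on the raw (unbinned) values
via expectation-maximization, and the component count is selected with the
small-sample corrected Akaike criterion

    AICc = -2 ln L + 2k + 2k(k+1)/(N-k-1),    BIC = -2 ln L + k ln N,

with k = 3m - 1 free parameters (m means, m standard deviations, m-1
weights).  Binning is used for display and for the histogram-difference
metric dP^2 = sum_i (P_i^+ - P_i^-)^2 only, never for fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "EfficiencySample",
    "MixtureModel",
    "HistogramDistribution",
    "fret_efficiency",
    "fit_gmm_mle",
    "aicc",
    "bic",
    "select_model",
    "assign_state_efficiencies",
    "histogram_probability",
    "delta_p",
    "delta_p2",
    "DEFAULT_BIN_EDGES",
]

#: Display/metric binning: width 0.05 on [-0.1, 1.1].
DEFAULT_BIN_EDGES = np.round(np.arange(-0.1, 1.1001, 0.05), 10)

#: Smallest admissible component sd.  A per-molecule efficiency is itself
#: uncertain by ~0.015 (shot noise through the intensity ratio), so a
#: narrower component cannot be a population; without this constraint the
#: mixture likelihood is unbounded (a component can collapse onto a point)
#: and best-of-restarts EM reliably finds spurious spike components.
SD_FLOOR = 0.015


def fret_efficiency(i_a, i_d, leakage: float = 0.0, gamma: float = 1.0):
    """Leakage- and gamma-corrected FRET efficiency (vectorised).

    Values slightly below 0 or above 1 are legitimate under noise and are
    *not* clipped here; clipping happens only at histogram display.
    """
    i_a = np.asarray(i_a, dtype=float)
    i_d = np.asarray(i_d, dtype=float)
    denom = i_a + gamma * i_d
    if np.any(denom <= 0):
        raise ValueError("I_A + gamma*I_D must be positive")
    out = (i_a - leakage * i_d) / denom
    return out if out.ndim else float(out)


@dataclass
class EfficiencySample:
    values: np.ndarray
    condition: str  # "minusLPC" | "plusLPC"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("efficiency values must be finite")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class MixtureModel:
    m: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    n: int

    @property
    def k(self) -> int:
        """Free parameters: m means + m sds + (m-1) weights."""
        return 3 * self.m - 1

    @property
    def aicc(self) -> float:
        return aicc(self.log_likelihood, self.k, self.n)

    @property
    def bic(self) -> float:
        return bic(self.log_likelihood, self.k, self.n)

    def density(self, x):
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.weights[:, None]
            * norm.pdf(x[None, :], self.means[:, None], self.sds[:, None]),
            axis=0,
        )

    def as_dict(self) -> dict:
        return {
            "m": self.m,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "bic": self.bic,
        }


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError("AICc requires N > k + 1")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion."""
    if n < 1:
        raise ValueError("BIC requires N >= 1")
    return -2.0 * log_likelihood + k * math.log(n) if k else -2.0 * log_likelihood


def _log_mixture_density(x, means, sds, weights):
    # log sum_j w_j phi(x; mu_j, sd_j), stabilised
    log_comp = (
        np.log(weights)[:, None]
        - 0.5 * np.log(2 * np.pi)
        - np.log(sds)[:, None]
        - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
    )
    mx = np.max(log_comp, axis=0)
    return mx + np.log(np.sum(np.exp(log_comp - mx), axis=0))


def _em_once(x, means, sds, weights, tol, max_iter, sd_floor):
    n = x.size
    prev = -np.inf
    clamped = False
    for _ in range(max_iter):
        log_comp = (
            np.log(weights)[:, None]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[:, None]
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        mx = np.max(log_comp, axis=0)
        log_px = mx + np.log(np.sum(np.exp(log_comp - mx), axis=0))
        ll = float(np.sum(log_px))
        if not clamped and ll + 1e-9 < prev:  # EM guarantee (unconstrained steps)
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(log_comp - log_px[None, :])
        if abs(ll - prev) < tol:
            prev = ll
            break
        prev = ll
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            return None  # empty component: dead restart
        weights = nk / n
        means = resp @ x / nk
        var = resp @ (x**2) / nk - means**2
        sds = np.sqrt(np.maximum(var, 0.0))
        clamped = bool(np.any(sds < sd_floor))
        sds = np.maximum(sds, sd_floor)  # constrained MLE: project onto sd >= floor
    return means, sds, weights, prev


def fit_gmm_mle(
    sample,
    m: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    sd_floor: float = SD_FLOOR,
) -> MixtureModel:
    """Unbinned maximum-likelihood Gaussian mixture fit by EM.

    ``sample`` may be an :class:`EfficiencySample` or a plain array.  The
    best of ``n_restarts`` seeded initialisations is kept; initial means are
    spread over sample quantiles and jittered.  Component sds are
    constrained to ``sd_floor`` (see :data:`SD_FLOOR`); a restart whose
    component empties entirely is discarded, and if every restart dies an
    error is raised.
    """
    x = sample.values if isinstance(sample, EfficiencySample) else np.asarray(sample, float).ravel()
    n = x.size
    if not 1 <= m <= 4:
        raise ValueError("component count m must be in 1..4")
    if n <= 3 * m:
        raise ValueError(f"need N > 3m data points (N={n}, m={m})")

    if m == 1:
        mu = float(np.mean(x))
        sd = float(np.std(x))  # MLE (1/N) standard deviation
        sd = max(sd, sd_floor)
        ll = float(np.sum(norm.logpdf(x, mu, sd)))
        return MixtureModel(1, np.array([mu]), np.array([sd]), np.array([1.0]), ll, n)

    rng = np.random.default_rng(seed)
    spread = np.std(x)
    q = np.quantile(x, (np.arange(m) + 0.5) / m)
    best = None
    best_spurious = None
    for r in range(n_restarts):
        means = q if r == 0 else q + rng.normal(0, spread / 2, m)
        sds = np.full(m, max(spread / m, 2 * sd_floor))
        weights = np.full(m, 1.0 / m)
        fit = _em_once(x, means.copy(), sds.copy(), weights.copy(), tol, max_iter, sd_floor)
        if fit is None:
            continue
        # a maximizer with a component pinned at the sd floor or holding
        # almost no data is a spurious likelihood spike, not a population;
        # prefer the best interior solution (McLachlan-Peel practice)
        spurious = bool(
            np.any(fit[1] <= sd_floor * 1.001) or np.any(fit[2] * n < 3.0)
        )
        if spurious:
            if best_spurious is None or fit[3] > best_spurious[3]:
                best_spurious = fit
        elif best is None or fit[3] > best[3]:
            best = fit
    if best is None:
        best = best_spurious
    if best is None:
        raise RuntimeError("every EM restart lost a component")
    means, sds, weights, _ = best
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    # report logL evaluated exactly at the returned parameters
    ll = float(np.sum(_log_mixture_density(x, means, sds, weights)))
    return MixtureModel(m, means, sds, weights, ll, n)


def select_model(models: list[MixtureModel]) -> tuple[MixtureModel, dict]:
    """Choose the component count minimising AICc.

    Returns the chosen model and a report dict; if BIC prefers a different
    m, both minima are reported and a flag is set (AICc decides).  Ties go
    to the smaller m.
    """
    if len(models) < 2:
        raise ValueError("need at least two candidate models")
    models = sorted(models, key=lambda mod: mod.m)
    by_aicc = min(models, key=lambda mod: (mod.aicc, mod.m))
    by_bic = min(models, key=lambda mod: (mod.bic, mod.m))
    report = {
        "m_aicc": by_aicc.m,
        "m_bic": by_bic.m,
        "agree": by_aicc.m == by_bic.m,
        "aicc": {mod.m: mod.aicc for mod in models},
        "bic": {mod.m: mod.bic for mod in models},
    }
    if not report["agree"]:
        warnings.warn(
            f"AICc selects m={by_aicc.m} but BIC selects m={by_bic.m}; using AICc",
            stacklevel=2,
        )
    return by_aicc, report


def assign_state_efficiencies(
    model_minus: MixtureModel,
    model_plus: MixtureModel,
    residual_tol: float = 0.1,
) -> tuple[float, float]:
    """Closed- and open-state near-pair peak efficiencies (E_nc, E_no).

    The closed-enriched (no-LPC) fit contributes its highest-mean component
    as E_nc.  In the open (with-LPC) fit, any component within
    ``residual_tol`` of E_nc is treated as residual closed channels and
    excluded; the highest remaining mean is E_no.
    """
    if model_plus.m < 2:
        raise ValueError("open-condition fit needs at least two components")
    e_nc = float(np.max(model_minus.means))
    candidates = [mu for mu in model_plus.means if abs(mu - e_nc) > residual_tol]
    if not candidates:
        raise ValueError("every open-condition component matches the closed peak")
    e_no = float(max(candidates))
    return e_nc, e_no


@dataclass
class HistogramDistribution:
    bin_edges: np.ndarray
    probabilities: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")


def histogram_probability(values, bin_edges=None, condition: str = "") -> HistogramDistribution:
    """Normalised probability per bin; out-of-range values are clipped into
    the edge bins (display-time clipping only)."""
    edges = DEFAULT_BIN_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    x = np.clip(np.asarray(values, dtype=float), edges[0], edges[-1] - 1e-12)
    counts, _ = np.histogram(x, bins=edges)
    if counts.sum() == 0:
        raise ValueError("empty sample")
    return HistogramDistribution(edges, counts / counts.sum(), condition)


def delta_p(p_plus: HistogramDistribution, p_minus: HistogramDistribution) -> np.ndarray:
    """Per-bin difference P_i^+ - P_i^- on a shared binning."""
    if not np.array_equal(p_plus.bin_edges, p_minus.bin_edges):
        raise ValueError("histograms must share bin edges")
    return p_plus.probabilities - p_minus.probabilities


def delta_p2(p_plus: HistogramDistribution, p_minus: HistogramDistribution) -> float:
    """Unscaled variance between two normalised histograms."""
    d = delta_p(p_plus, p_minus)
    return float(np.sum(d**2))
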