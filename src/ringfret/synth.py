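"""Seeded generator of single-molecule FRET trace datasets and spectra.

Emulates TIRF recordings of a liposome-reconstituted homo-pentameric
channel labelled stochastically on an engineered cysteine: each subunit
independently carries a donor, an acceptor, or nothing (at most one dye per
subunit), matching mean stoichiometries of ~1.7 donors and ~1.3 acceptors
per pentamer.  Dyes photobleach exponentially (donors faster, so donors
usually bleach first); before a donor bleach the donor channel carries the
unquenched donor emission and the acceptor channel carries sensitized
emission plus a leakage fraction l of the donor signal.  ``gamma`` is the
*measured* detection factor, the ratio dI_A/dI_D observed at an acceptor
bleach; because the leakage contribution to the acceptor channel rises by
l*dI_D at that event, the physical sensitized-emission scaling is
gamma + l.  With that convention the corrected-efficiency formula
E = (I_A - l I_D)/(I_A + gamma I_D) inverts the trace model exactly.
Gaussian per-frame noise stands in for shot noise — downstream
analysis uses level differences, which are insensitive to the exact noise
family.

Each molecule's conformational state (closed/open) is drawn per condition:
immobilisation tension leaves a configurable fraction of channels open even
without the opening agent (LPC), which is what produces the three-peak
efficiency histogram — near-pair closed, the overlap of far-pair closed
with near-pair open, and far-pair open.  Ground truth for every generating
value is recorded for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    diameter_from_adjacent,
    efficiency_at_distance,
    ring_pair_distance,
)

__all__ = [
    "LabelingConfig",
    "TraceTruth",
    "IntensityTrace",
    "SpectrumPair",
    "DatasetConfig",
    "draw_label_counts",
    "simulate_trace",
    "simulate_dataset",
    "simulate_spectra",
    "gaussian_spectrum",
    "rectangular_spectrum",
    "truth_table",
]


@dataclass(frozen=True)
class LabelingConfig:
    """Stochastic labelling of an n-subunit ring."""

    n_subunits: int = 5
    mean_donors: float = 1.7
    mean_acceptors: float = 1.3
    labeled_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_subunits not in (5, 6):
            raise ValueError("n_subunits must be 5 or 6")
        if self.mean_donors < 0 or self.mean_acceptors < 0:
            raise ValueError("mean dye counts must be non-negative")
        if self.mean_donors + self.mean_acceptors > self.n_subunits:
            raise ValueError("mean dye counts cannot exceed the subunit count")
        p = (self.mean_donors + self.mean_acceptors) / self.n_subunits
        if p > 1.0:
            raise ValueError("per-subunit dye probability exceeds 1: invalid config")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")


def draw_label_counts(
    cfg: LabelingConfig, n_molecules: int, seed: int = 0
) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Draw (donor_count, acceptor_count, donor_positions, acceptor_positions).

    Each subunit independently carries a donor with probability
    mean_donors/n, an acceptor with probability mean_acceptors/n, or
    nothing; a subunit holds at most one dye, so the marginal donor count
    is Binomial(n, mean_donors/n).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    n = cfg.n_subunits
    pd_, pa = cfg.mean_donors / n, cfg.mean_acceptors / n
    if pd_ + pa > 1.0:
        raise ValueError("per-subunit donor+acceptor probability exceeds 1")
    out = []
    u = rng.random((n_molecules, n))
    labeled = rng.random(n_molecules) < cfg.labeled_fraction
    for i in range(n_molecules):
        if not labeled[i]:
            out.append((0, 0, np.array([], int), np.array([], int)))
            continue
        d_pos = np.flatnonzero(u[i] < pd_)
        a_pos = np.flatnonzero((u[i] >= pd_) & (u[i] < pd_ + pa))
        out.append((d_pos.size, a_pos.size, d_pos, a_pos))
    return out


@dataclass
class TraceTruth:
    """Generator-side ground truth for one molecule."""

    molecule_id: str
    condition: str  # "minusLPC" | "plusLPC"
    state: str  # "closed" | "open"
    oligomer_size: int
    donor_positions: np.ndarray
    acceptor_positions: np.ndarray
    pair_efficiencies: np.ndarray  # shape (n_donors, n_acceptors), each in (0, 1)
    donor_bleach_times: np.ndarray  # seconds
    acceptor_bleach_times: np.ndarray
    leakage: float
    gamma: float
    brightness: float  # mean counts/frame per dye
    background: float = 0.0

    def __post_init__(self) -> None:
        self.donor_positions = np.asarray(self.donor_positions, int)
        self.acceptor_positions = np.asarray(self.acceptor_positions, int)
        if np.intersect1d(self.donor_positions, self.acceptor_positions).size:
            raise ValueError("a subunit cannot carry both a donor and an acceptor")
        self.pair_efficiencies = np.atleast_2d(np.asarray(self.pair_efficiencies, float))
        if self.pair_efficiencies.size and not np.all(
            (self.pair_efficiencies > 0) & (self.pair_efficiencies < 1)
        ):
            raise ValueError("per-pair efficiencies must lie in (0, 1)")
        if self.leakage < 0:
            raise ValueError("leakage must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    @property
    def donor_count(self) -> int:
        return self.donor_positions.size

    @property
    def acceptor_count(self) -> int:
        return self.acceptor_positions.size

    @property
    def true_e(self) -> float:
        """Total transfer efficiency of the (first) donor with all acceptors live."""
        if self.donor_count == 0 or self.acceptor_count == 0:
            return 0.0
        k = self.pair_efficiencies[0] / (1.0 - self.pair_efficiencies[0])
        ktot = float(np.sum(k))
        return ktot / (1.0 + ktot)


@dataclass
class IntensityTrace:
    frame_times: np.ndarray  # seconds
    donor_channel: np.ndarray  # counts/frame
    acceptor_channel: np.ndarray
    condition: str
    molecule_id: str

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, float)
        self.donor_channel = np.asarray(self.donor_channel, float)
        self.acceptor_channel = np.asarray(self.acceptor_channel, float)
        n = self.frame_times.size
        if self.donor_channel.size != n or self.acceptor_channel.size != n:
            raise ValueError("channels and times must have equal length")
        if n and (self.frame_times[0] < 0 or np.any(np.diff(self.frame_times) <= 0)):
            raise ValueError("frame times must be non-negative and strictly increasing")


def simulate_trace(
    truth: TraceTruth,
    n_frames: int = 300,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval: float = 0.1,
) -> IntensityTrace:
    """Render one two-channel trace from its ground truth.

    Per frame, each surviving donor transfers to the surviving acceptors
    with combined efficiency E_i = K/(1+K), K = sum_j E_ij/(1-E_ij) (rate
    competition between acceptors).  The donor channel sums B*(1-E_i); the
    acceptor channel carries (gamma+leakage)*B*sum(E_i) sensitized emission
    plus leakage*donor-channel signal (see module docstring: ``gamma`` is
    the measured dI_A/dI_D convention).  A donor bleach therefore drops
    both channels simultaneously; an acceptor bleach drops the acceptor
    channel while the donor channel rises.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval

    d_alive = t[:, None] < truth.donor_bleach_times[None, :] if truth.donor_count else np.zeros((n_frames, 0), bool)
    a_alive = t[:, None] < truth.acceptor_bleach_times[None, :] if truth.acceptor_count else np.zeros((n_frames, 0), bool)

    b = truth.brightness
    donor = np.full(n_frames, truth.background, dtype=float)
    sensitized = np.zeros(n_frames)
    if truth.donor_count:
        if truth.acceptor_count:
            k = truth.pair_efficiencies / (1.0 - truth.pair_efficiencies)  # (nd, na)
            ktot = a_alive @ k.T  # (n_frames, nd): per-donor live-acceptor rate sum
            e_tot = ktot / (1.0 + ktot)
        else:
            e_tot = np.zeros((n_frames, truth.donor_count))
        donor = donor + b * np.sum(d_alive * (1.0 - e_tot), axis=1)
        sensitized = b * np.sum(d_alive * e_tot, axis=1)
    acceptor = (
        (truth.gamma + truth.leakage) * sensitized
        + truth.leakage * (donor - truth.background)
        + truth.background
    )

    if noise_sd > 0:
        donor = donor + rng.normal(0.0, noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0.0, noise_sd, n_frames)
    return IntensityTrace(t, donor, acceptor, truth.condition, truth.molecule_id)


@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for a synthetic dataset.

    The default state-efficiency table is the published M42C phenomenology:
    near-pair closed 0.63, far-pair closed 0.28, far-pair open 0.10, and
    near-pair open set equal to the closed far-pair value (0.28) — the
    observed middle peak is precisely the overlap of (closed, far) with
    (open, near), which is why only three peaks are resolvable.
    ``closed_fraction`` reflects the
    residual tension-opened population per condition.  Trace length, frame
    rate and brightness are not dictated by any published value and are
    plain configuration.
    """

    n_molecules: dict = field(
        default_factory=lambda: {"minusLPC": 450, "plusLPC": 450}
    )
    closed_fraction: dict = field(
        default_factory=lambda: {"minusLPC": 0.6, "plusLPC": 0.05}
    )
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    state_efficiencies: dict = field(
        default_factory=lambda: {
            ("closed", 1): 0.63,
            ("closed", 2): 0.28,
            ("open", 1): 0.28,  # equal to (closed, far): the overlapped middle peak
            ("open", 2): 0.10,
        }
    )
    geometry: dict | None = None  # {"r0": nm, "d_closed": nm, "d_open": nm} overrides the table
    e_jitter_sd: float = 0.05  # per-pair heterogeneity; matches observed peak widths
    f_hex: float = 0.0
    force_single_pair: bool = False  # exactly one donor + one acceptor
    force_sep: int | None = None  # fixed separation, or None for a uniform partner subunit
    brightness: float = 500.0
    background: float = 0.0
    noise_sd: float = 25.0  # counts/frame (5% of brightness)
    n_frames: int = 300
    frame_interval: float = 0.1  # s
    donor_bleach_mean_s: float = 8.0
    acceptor_bleach_mean_s: float = 16.0
    leakage: float = 0.09
    gamma: float = 0.89

    def pair_efficiency(self, state: str, sep: int, n_sub: int) -> float:
        if self.geometry is not None:
            d = self.geometry["d_closed"] if state == "closed" else self.geometry["d_open"]
            if n_sub != 5:
                # same subunit packing: adjacent chord fixed, circumcircle rescales
                d = diameter_from_adjacent(ring_pair_distance(d, 5, 1), n_sub)
            r = ring_pair_distance(d, n_sub, sep)
            return float(efficiency_at_distance(r, self.geometry["r0"]))
        return self.state_efficiencies[(state, min(sep, 2))]


def _make_truth(cfg: DatasetConfig, condition: str, idx: int, rng: np.random.Generator) -> TraceTruth:
    n_sub = 6 if rng.random() < cfg.f_hex else 5
    state = "closed" if rng.random() < cfg.closed_fraction[condition] else "open"
    if cfg.force_single_pair:
        d_pos = np.array([0])
        partner = cfg.force_sep if cfg.force_sep is not None else int(rng.integers(1, n_sub))
        a_pos = np.array([partner])
    else:
        lab = cfg.labeling if n_sub == cfg.labeling.n_subunits else replace(cfg.labeling, n_subunits=n_sub)
        n = lab.n_subunits
        u = rng.random(n)
        if rng.random() >= lab.labeled_fraction:
            u[:] = 1.0
        pd_, pa = lab.mean_donors / n, lab.mean_acceptors / n
        d_pos = np.flatnonzero(u < pd_)
        a_pos = np.flatnonzero((u >= pd_) & (u < pd_ + pa))
    eff = np.empty((d_pos.size, a_pos.size))
    for i, dp in enumerate(d_pos):
        for j, ap in enumerate(a_pos):
            sep = int(min(abs(dp - ap), n_sub - abs(dp - ap)))
            e = cfg.pair_efficiency(state, sep, n_sub)
            if cfg.e_jitter_sd > 0:
                e = e + rng.normal(0.0, cfg.e_jitter_sd)
            eff[i, j] = np.clip(e, 1e-3, 1.0 - 1e-3)
    return TraceTruth(
        molecule_id=f"{condition}_{idx:05d}",
        condition=condition,
        state=state,
        oligomer_size=n_sub,
        donor_positions=d_pos,
        acceptor_positions=a_pos,
        pair_efficiencies=eff,
        donor_bleach_times=rng.exponential(cfg.donor_bleach_mean_s, d_pos.size),
        acceptor_bleach_times=rng.exponential(cfg.acceptor_bleach_mean_s, a_pos.size),
        leakage=cfg.leakage,
        gamma=cfg.gamma,
        brightness=cfg.brightness,
        background=cfg.background,
    )


def simulate_dataset(
    cfg: DatasetConfig, seed: int = 0
) -> tuple[list[IntensityTrace], list[TraceTruth]]:
    """Generate per-condition trace sets with full ground truth.

    Reproducible under ``seed``; identical seeds give identical datasets.
    """
    if not cfg.n_molecules:
        raise ValueError("empty condition list")
    root = np.random.SeedSequence(seed)
    traces: list[IntensityTrace] = []
    truths: list[TraceTruth] = []
    for cond_seq, condition in zip(root.spawn(len(cfg.n_molecules)), cfg.n_molecules):
        rng = np.random.default_rng(cond_seq)
        for idx in range(cfg.n_molecules[condition]):
            truth = _make_truth(cfg, condition, idx, rng)
            trace = simulate_trace(
                truth,
                n_frames=cfg.n_frames,
                noise_sd=cfg.noise_sd,
                seed=int(rng.integers(2**31)),
                frame_interval=cfg.frame_interval,
            )
            traces.append(trace)
            truths.append(truth)
    return traces, truths


def truth_table(truths: list[TraceTruth]) -> pd.DataFrame:
    """Flatten ground truth into one row per molecule."""
    rows = []
    for t in truths:
        rows.append(
            {
                "molecule_id": t.molecule_id,
                "condition": t.condition,
                "state": t.state,
                "oligomer_size": t.oligomer_size,
                "donor_count": t.donor_count,
                "acceptor_count": t.acceptor_count,
                "donor_positions": ";".join(map(str, t.donor_positions)),
                "acceptor_positions": ";".join(map(str, t.acceptor_positions)),
                "true_e": t.true_e,
                "first_donor_bleach_s": float(np.min(t.donor_bleach_times)) if t.donor_count else np.nan,
                "first_acceptor_bleach_s": float(np.min(t.acceptor_bleach_times)) if t.acceptor_count else np.nan,
                "leakage": t.leakage,
                "gamma": t.gamma,
                "brightness": t.brightness,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumPair:
    """A spectrum on a strictly increasing nm grid (values >= 0)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be non-negative")
        if self.wavelengths.size != self.values.size:
            raise ValueError("grid and values must have equal length")


def gaussian_spectrum(lo: float, hi: float, center: float, width: float, peak: float, step: float = 1.0) -> SpectrumPair:
    if width <= 0 or peak < 0:
        raise ValueError("width must be positive and peak non-negative")
    grid = np.arange(lo, hi + step / 2, step)
    return SpectrumPair(grid, peak * np.exp(-0.5 * ((grid - center) / width) ** 2))


def rectangular_spectrum(lo: float, hi: float, band_lo: float, band_hi: float, value: float, step: float = 0.5) -> SpectrumPair:
    grid = np.arange(lo, hi + step / 2, step)
    vals = np.where((grid >= band_lo) & (grid <= band_hi), value, 0.0)
    return SpectrumPair(grid, vals)


def simulate_spectra(
    donor_em_center: float = 525.0,
    donor_em_width: float = 28.0,
    acceptor_ext_center: float = 578.0,
    acceptor_ext_width: float = 26.0,
    acceptor_ext_peak: float = 91300.0,  # M^-1 cm^-1, AF568-like
) -> dict[str, SpectrumPair]:
    """Smooth AF488/AF568-like spectra for the photophysics chain.

    The Gaussian widths are generous so that the single Gaussian stands in
    for the real donor's long red emission tail; with these defaults the
    overlap integral lands at the literature magnitude for this dye pair
    (~2e15 M^-1 cm^-1 nm^4).  Returns donor emission, acceptor molar
    extinction, and donor/standard absorbance+emission curves suitable for
    the quantum-yield protocol.
    """
    return {
        "donor_emission": gaussian_spectrum(460, 700, donor_em_center, donor_em_width, 1.0),
        "acceptor_extinction": gaussian_spectrum(
            460, 700, acceptor_ext_center, acceptor_ext_width, acceptor_ext_peak
        ),
        "donor_absorbance": gaussian_spectrum(400, 540, 495, 15, 0.05),
        "standard_absorbance": gaussian_spectrum(400, 540, 490, 15, 0.05),
        "standard_emission": gaussian_spectrum(460, 650, 512, 16, 1.0),
    }
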