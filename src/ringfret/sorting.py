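"""Virtual sorting of single-molecule traces by photobleaching steps.

A ring protein carrying a stochastic number of dyes produces staircase
photobleaching.  Counting the downward steps per detection channel
identifies the molecules with exactly one donor and one acceptor — the only
ones whose FRET efficiency is interpretable — without any physical sorting.
Subtracting the mean intensity just before and after the donor bleach gives
the donor and acceptor intensities I_D and I_A (this difference also
removes direct acceptor excitation, which is state-independent).  Traces in
which the acceptor bleaches first instead calibrate the detection factor
gamma from the anti-correlated intensity change, and donor-only molecules
calibrate the spectral leakage l.

Step detection is penalized least-squares change-point segmentation
(optimal partitioning, penalty proportional to sigma^2 log n per change
point) followed by merging of segments whose level difference is below
3x the robust noise sd.  It is deterministic and training-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepFit",
    "TraceClassification",
    "SortedPair",
    "count_bleach_steps",
    "classify_trace",
    "extract_pair_intensities",
    "donor_only_pair",
    "estimate_leakage",
    "estimate_gamma",
]

#: frames discarded on each side of a change point when averaging a segment
GUARD_FRAMES = 2

#: a merged level difference below this many noise sd is not a step
MERGE_SD = 3.0

#: "simultaneous" change points may differ by this many frames
SIMULTANEOUS_TOL = 1

#: shortest usable averaging window (guards on both sides plus two frames)
MIN_SEGMENT = 2 * GUARD_FRAMES + 2


@dataclass
class StepFit:
    change_points: np.ndarray  # frame index of the first frame of each new segment
    levels: np.ndarray  # guarded mean counts per segment
    sigma: float  # robust per-frame noise sd
    residual: float  # sum of squared deviations of the final segmentation
    threshold: float = 0.0  # minimum level change that counts as a step

    @property
    def n_steps(self) -> int:
        """Number of downward (photobleaching) steps."""
        return int(np.sum(np.diff(self.levels) < -self.threshold))

    @property
    def down_points(self) -> np.ndarray:
        return self.change_points[np.diff(self.levels) < -self.threshold]

    @property
    def up_points(self) -> np.ndarray:
        return self.change_points[np.diff(self.levels) > self.threshold]


def _robust_sigma(y: np.ndarray) -> float:
    # MAD of first differences; a single step contaminates only one diff
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _segment_means(y: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Mean per segment, trimming GUARD_FRAMES at interior boundaries."""
    means = np.empty(len(bounds) - 1)
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        lo = a + (GUARD_FRAMES if a != bounds[0] else 0)
        hi = b - (GUARD_FRAMES if b != bounds[-1] else 0)
        if hi <= lo:  # segment too short to trim
            lo, hi = a, b
        means[i] = np.mean(y[lo:hi])
    return means


def _optimal_partition(y: np.ndarray, penalty: float) -> list[int]:
    """Exact penalized least-squares segmentation (O(n^2), vectorised)."""
    n = y.size
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    cost_best = np.empty(n + 1)
    cost_best[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    idx = np.arange(n + 1)
    for t in range(1, n + 1):
        lens = t - idx[:t]
        seg = (s2[t] - s2[:t]) - (s1[t] - s1[:t]) ** 2 / lens
        total = cost_best[:t] + seg + penalty
        j = int(np.argmin(total))
        cost_best[t] = total[j]
        last[t] = j
    cps: list[int] = []
    t = n
    while t > 0:
        j = last[t]
        if j > 0:
            cps.append(j)
        t = j
    return sorted(cps)


def count_bleach_steps(channel, min_frames: int = 20) -> StepFit:
    """Detect photobleaching steps in one intensity channel.

    Returns the change points, guarded segment levels and the downward step
    count.  Deterministic for fixed input; a constant trace yields zero
    steps.
    """
    y = np.asarray(channel, dtype=float).ravel()
    if y.size < min_frames:
        raise ValueError(f"need at least {min_frames} frames, got {y.size}")

    sigma = _robust_sigma(y)
    if np.ptp(y) == 0.0:  # perfectly constant
        return StepFit(np.array([], dtype=int), np.array([np.mean(y)]), 0.0, 0.0)
    # relative floor keeps the penalty above float accumulation noise so a
    # noiseless trace still segments exactly at its true steps
    sigma_eff = max(sigma, 1e-6 * (np.ptp(y) + 1.0))
    penalty = 2.0 * sigma_eff**2 * np.log(y.size)

    cps = _optimal_partition(y, penalty)
    bounds = np.array([0, *cps, y.size])
    levels = _segment_means(y, bounds)

    # merge steps indistinguishable from noise, smallest first
    threshold = MERGE_SD * sigma_eff
    while len(cps) > 0:
        diffs = np.abs(np.diff(levels))
        i = int(np.argmin(diffs))
        if diffs[i] >= threshold:
            break
        cps.pop(i)
        bounds = np.array([0, *cps, y.size])
        levels = _segment_means(y, bounds)

    fitted = np.repeat(levels, np.diff(bounds))
    residual = float(np.sum((y - fitted) ** 2))
    return StepFit(np.asarray(cps, dtype=int), levels, sigma, residual, threshold)


@dataclass(frozen=True)
class TraceClassification:
    keep: bool
    bleach_order: str | None  # "donor_first" | "acceptor_first" | None
    reason: str = ""


def classify_trace(
    donor_fit: StepFit,
    acceptor_fit: StepFit,
    tol: int = SIMULTANEOUS_TOL,
) -> TraceClassification:
    """Keep a molecule only if both channels show one terminal bleach.

    donor-first: both channels drop together (within ``tol`` frames) —
    the only geometry that defines a FRET efficiency.  acceptor-first: the
    acceptor drops while the donor rises (transfer lost), and the donor
    bleaches on its own later; used solely for gamma calibration.  In the
    acceptor-first case the residual donor leakage in the acceptor channel
    also vanishes at the later donor bleach, so one extra acceptor drop is
    accepted if (and only if) it coincides with the donor bleach.

    Both channels must end at background (traces are background-subtracted,
    so the final segment level must be indistinguishable from zero): a
    second dye surviving past the recording window would otherwise
    masquerade as a single-dye molecule.
    """
    if donor_fit.n_steps != 1:
        return TraceClassification(False, None, f"{donor_fit.n_steps} donor steps")
    dark = max(donor_fit.threshold, 1e-9)
    if abs(donor_fit.levels[-1]) > dark:
        return TraceClassification(False, None, "donor channel does not end dark")
    dark_a = max(acceptor_fit.threshold, 1e-9)
    if abs(acceptor_fit.levels[-1]) > dark_a:
        return TraceClassification(False, None, "acceptor channel does not end dark")

    d_down = int(donor_fit.down_points[0])
    a_downs = acceptor_fit.down_points

    if acceptor_fit.n_steps == 1:
        a_down = int(a_downs[0])
        if abs(d_down - a_down) <= tol:
            if donor_fit.change_points[-1] != d_down or acceptor_fit.change_points[-1] != a_down:
                return TraceClassification(False, None, "bleach is not terminal")
            if d_down < MIN_SEGMENT:
                return TraceClassification(False, None, "bleach too early to average a level")
            return TraceClassification(True, "donor_first")
    elif acceptor_fit.n_steps == 2:
        # second drop must be the leakage loss at the donor bleach
        if abs(int(a_downs[1]) - d_down) > tol:
            return TraceClassification(False, None, "2 acceptor steps")
    else:
        return TraceClassification(False, None, f"{acceptor_fit.n_steps} acceptor steps")

    a_down = int(a_downs[0])
    donor_up = donor_fit.up_points
    if donor_up.size and np.min(np.abs(donor_up - a_down)) <= tol and d_down > a_down:
        if a_down < MIN_SEGMENT or d_down - a_down < MIN_SEGMENT:
            return TraceClassification(False, None, "bleaches too close to average levels")
        return TraceClassification(True, "acceptor_first")

    return TraceClassification(False, None, "drops neither simultaneous nor anti-correlated")


@dataclass(frozen=True)
class SortedPair:
    i_d: float  # donor step difference (counts/frame)
    i_a: float  # acceptor step difference (counts/frame)
    bleach_order: str
    molecule_id: str = ""


def _window_mean(y: np.ndarray, lo: int, hi: int) -> float:
    """Guarded mean over y[lo:hi]; falls back to the raw window if too short."""
    glo, ghi = lo + GUARD_FRAMES, hi - GUARD_FRAMES
    if ghi <= glo:
        glo, ghi = lo, hi
    return float(np.mean(y[glo:ghi]))


def extract_pair_intensities(
    trace,
    donor_fit: StepFit,
    acceptor_fit: StepFit,
    classification: TraceClassification,
    molecule_id: str = "",
) -> SortedPair:
    """Before/after level differences across the relevant bleach.

    donor-first: I_D and I_A are the drops of each channel across the donor
    bleach (the fitted terminal levels).  acceptor-first: I_A is the
    acceptor drop and I_D the donor *rise* across the acceptor bleach,
    both measured on the window between the two bleaches directly from the
    trace — the post-acceptor leakage plateau can sit below the step-merge
    threshold, so the fitted tail level would understate it.
    """
    if not classification.keep:
        raise ValueError(f"trace was discarded by sorting: {classification.reason}")

    if classification.bleach_order == "donor_first":
        i_d = float(donor_fit.levels[-2] - donor_fit.levels[-1])
        i_a = float(acceptor_fit.levels[-2] - acceptor_fit.levels[-1])
    else:  # acceptor_first
        a_down = int(acceptor_fit.down_points[0])
        d_down = int(donor_fit.down_points[0])
        donor = np.asarray(trace.donor_channel, dtype=float)
        acceptor = np.asarray(trace.acceptor_channel, dtype=float)
        up = donor_fit.up_points
        d_up = int(up[np.argmin(np.abs(up - a_down))])
        prev_a = [int(c) for c in acceptor_fit.change_points if c < a_down]
        prev_d = [int(c) for c in donor_fit.change_points if c < d_up]
        i_a = _window_mean(acceptor, prev_a[-1] if prev_a else 0, a_down) - _window_mean(
            acceptor, a_down, d_down
        )
        i_d = _window_mean(donor, d_up, d_down) - _window_mean(
            donor, prev_d[-1] if prev_d else 0, d_up
        )
    return SortedPair(i_d=i_d, i_a=i_a, bleach_order=classification.bleach_order, molecule_id=molecule_id)


def donor_only_pair(
    donor_channel, acceptor_channel, molecule_id: str = ""
) -> SortedPair:
    """Leakage pair from a donor-only labelled molecule.

    The acceptor channel of such a molecule carries only leakage, which can
    be below the step-detection threshold (or exactly zero), so both level
    differences are taken across the *donor* bleach: the donor channel must
    show exactly one terminal step, and the acceptor channel is averaged
    over the same guarded windows.
    """
    donor_fit = count_bleach_steps(donor_channel)
    if donor_fit.n_steps != 1 or donor_fit.change_points[-1] != donor_fit.down_points[0]:
        raise ValueError("donor channel must show exactly one terminal bleaching step")
    y = np.asarray(acceptor_channel, dtype=float).ravel()
    bounds = np.array([0, *donor_fit.change_points, y.size])
    a_levels = _segment_means(y, bounds)
    return SortedPair(
        i_d=float(donor_fit.levels[-2] - donor_fit.levels[-1]),
        i_a=float(a_levels[-2] - a_levels[-1]),
        bleach_order="donor_first",
        molecule_id=molecule_id,
    )


def _mean_se(ratios: np.ndarray) -> tuple[float, float]:
    se = float(np.std(ratios, ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else float("nan")
    return float(np.mean(ratios)), se


def estimate_leakage(pairs: list[SortedPair]) -> tuple[float, float]:
    """Donor leakage l = mean of per-molecule acceptor/donor step ratios.

    ``pairs`` must come from a donor-only labelled sample, where the entire
    acceptor-channel step is spectral leakage.  Returns (l, standard error).
    """
    ratios = np.array([p.i_a / p.i_d for p in pairs if p.bleach_order == "donor_first"])
    if ratios.size == 0:
        raise ValueError("no donor-first pairs to estimate leakage from")
    return _mean_se(ratios)


def estimate_gamma(pairs: list[SortedPair]) -> tuple[float, float]:
    """Detection factor gamma = mean of dI_A/dI_D across acceptor bleaches.

    This is the measured convention: the net acceptor-channel change at an
    acceptor bleach (sensitized emission lost minus leakage gained) over
    the donor-channel rise.  It is exactly the factor the corrected
    efficiency formula requires.  Returns (gamma, standard error).
    """
    ratios = np.array([p.i_a / p.i_d for p in pairs if p.bleach_order == "acceptor_first"])
    if ratios.size == 0:
        raise ValueError("no acceptor-first pairs to estimate gamma from")
    return _mean_se(ratios)
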