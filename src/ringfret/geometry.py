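"""Ring geometry of homo-oligomeric membrane channels.

A residue mutated to a cysteine on every subunit of an n-mer defines a
regular n-gon inscribed in a circumcircle of diameter ``D`` centred on the
pore axis.  A donor and an acceptor attached to two subunits separated by
``sep`` positions sit at a chord distance

    R_sep = D * sin(pi * sep / n),

so for a pentamer the neighbouring (R_n) and non-neighbouring (R_f)
distances obey R_f / R_n = sin(2pi/5) / sin(pi/5), the golden ratio.  FRET
efficiency converts to distance through R = R0 * (1/E - 1)^(1/6), and a
change in the neighbouring-pair distance converts back into a change of
protein diameter, ``dD = dR_n / sin(pi/n)``, and a radial residue movement
``dr = dD / 2``.  The open-pore diameter follows as
``phi_open = phi_close + dD`` evaluated at the residue lining the gate.

Because the dye linkers add an (unknown but state-independent) offset to
the apparent radius, all structural statements are made on *changes* of
distances, never on absolute distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingModel",
    "ResidueGeometry",
    "PoreEstimate",
    "fret_distance",
    "efficiency_at_distance",
    "ring_pair_distance",
    "diameter_from_adjacent",
    "residue_movement",
    "pore_diameter",
    "oligomer_scaling",
    "simulate_oligomer_mixture",
    "expected_far_efficiency",
    "helix_tilt_indicator",
]


def fret_distance(E: float, r0: float) -> float:
    """Donor-acceptor distance (same units as ``r0``) from efficiency ``E``.

    R = R0 * (1/E - 1)^(1/6).  Only defined for 0 < E < 1.
    """
    if not 0.0 < E < 1.0:
        raise ValueError(f"FRET efficiency must lie in (0, 1), got {E}")
    if r0 <= 0:
        raise ValueError("Forster radius must be positive")
    return r0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def efficiency_at_distance(R, r0: float):
    """Inverse of :func:`fret_distance`: E = 1 / (1 + (R/R0)^6)."""
    R = np.asarray(R, dtype=float)
    if r0 <= 0:
        raise ValueError("Forster radius must be positive")
    out = 1.0 / (1.0 + (R / r0) ** 6)
    return out if out.ndim else float(out)


def ring_pair_distance(diameter: float, n_mer: int, sep: int) -> float:
    """Chord distance between subunits ``sep`` apart on a regular ``n_mer`` ring."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if not 1 <= sep <= n_mer // 2:
        raise ValueError(f"separation must be in 1..{n_mer // 2} for an {n_mer}-mer")
    return diameter * math.sin(math.pi * sep / n_mer)


def diameter_from_adjacent(r_n: float, n_mer: int) -> float:
    """Circumcircle diameter from the adjacent-subunit distance (exact inverse)."""
    if r_n <= 0:
        raise ValueError("adjacent distance must be positive")
    return r_n / math.sin(math.pi / n_mer)


def oligomer_scaling(n_assumed: int, n_true: int) -> float:
    """Relative bias of the inferred diameter when the oligomer size is wrong.

    If every molecule is an ``n_true``-mer but distances are converted to a
    diameter assuming an ``n_assumed``-mer, the diameter is off by
    sin(pi/n_assumed)/sin(pi/n_true) - 1 (e.g. +17.6% for hexamers analysed
    as pentamers).
    """
    if n_assumed < 3 or n_true < 3:
        raise ValueError("oligomer sizes must be >= 3")
    return math.sin(math.pi / n_assumed) / math.sin(math.pi / n_true) - 1.0


@dataclass(frozen=True)
class RingModel:
    """Regular-polygon model of one residue's circumcircle."""

    n_mer: int
    diameter: float  # nm

    def __post_init__(self) -> None:
        if self.n_mer not in (5, 6):
            raise ValueError("only pentamers and hexamers are modelled")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def pair_distances(self) -> dict[int, float]:
        """Chord distance for every distinct subunit separation."""
        return {
            sep: ring_pair_distance(self.diameter, self.n_mer, sep)
            for sep in range(1, self.n_mer // 2 + 1)
        }


@dataclass
class ResidueGeometry:
    """Distance chain for one residue: efficiencies -> movements with bounds.

    Bounds are the maximum possible errors inherited from the orientation
    factor through R0; upper/lower are stored as positive offsets.
    """

    residue: str
    helix: str
    e_nc: float
    e_no: float
    r0: float
    n_mer: int = 5
    r_nc: float = 0.0
    r_no: float = 0.0
    delta_r_n: float = 0.0
    delta_d: float = 0.0
    delta_r: float = 0.0
    r_nc_bounds: tuple[float, float] = (0.0, 0.0)  # (minus, plus) offsets, nm
    r_no_bounds: tuple[float, float] = (0.0, 0.0)
    delta_r_n_bounds: tuple[float, float] = (0.0, 0.0)
    delta_d_bounds: tuple[float, float] = (0.0, 0.0)
    delta_r_bounds: tuple[float, float] = (0.0, 0.0)


def residue_movement(
    e_nc: float,
    e_no: float,
    r0: float,
    n_mer: int = 5,
    r0_lower: float | None = None,
    r0_upper: float | None = None,
    residue: str = "",
    helix: str = "",
) -> ResidueGeometry:
    """Convert closed/open near-pair efficiencies into a residue movement.

    ``e_nc`` and ``e_no`` are the highest-mean mixture components of the
    closed-enriched and open conditions.  Opening moves subunits apart, so
    the near-pair efficiency must drop: ``e_no < e_nc`` is enforced and a
    violation raises with a "no opening signal" diagnostic.

    Error bounds on R0 (from the dye-orientation factor) propagate linearly
    into each distance and are combined in quadrature for the difference
    dR_n = R_no - R_nc; dD and dr scale exactly.
    """
    for name, e in (("e_nc", e_nc), ("e_no", e_no)):
        if not 0.0 < e < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {e}")
    if e_no >= e_nc:
        raise ValueError(
            "no opening signal: open-state efficiency must be below the "
            f"closed-state value (e_no={e_no} >= e_nc={e_nc})"
        )
    r0_lower = r0 if r0_lower is None else r0_lower
    r0_upper = r0 if r0_upper is None else r0_upper
    if not r0_lower <= r0 <= r0_upper:
        raise ValueError("require r0_lower <= r0 <= r0_upper")

    r_nc = fret_distance(e_nc, r0)
    r_no = fret_distance(e_no, r0)
    # distances are linear in R0, so bounds scale multiplicatively
    up = r0_upper / r0 - 1.0
    lo = 1.0 - r0_lower / r0
    r_nc_b = (r_nc * lo, r_nc * up)
    r_no_b = (r_no * lo, r_no * up)

    delta_r_n = r_no - r_nc
    drn_b = (
        math.hypot(r_nc_b[0], r_no_b[0]),
        math.hypot(r_nc_b[1], r_no_b[1]),
    )
    s = math.sin(math.pi / n_mer)
    delta_d = delta_r_n / s
    delta_r = delta_d / 2.0

    return ResidueGeometry(
        residue=residue,
        helix=helix,
        e_nc=e_nc,
        e_no=e_no,
        r0=r0,
        n_mer=n_mer,
        r_nc=r_nc,
        r_no=r_no,
        delta_r_n=delta_r_n,
        delta_d=delta_d,
        delta_r=delta_r,
        r_nc_bounds=r_nc_b,
        r_no_bounds=r_no_b,
        delta_r_n_bounds=drn_b,
        delta_d_bounds=(drn_b[0] / s, drn_b[1] / s),
        delta_r_bounds=(drn_b[0] / s / 2.0, drn_b[1] / s / 2.0),
    )


@dataclass(frozen=True)
class PoreEstimate:
    phi_close: float  # nm
    delta_d: float  # nm, at the gating residue
    phi_open: float = field(init=False)

    def __post_init__(self) -> None:
        if self.phi_close < 0 or self.delta_d < 0:
            raise ValueError("pore diameter terms must be non-negative")
        object.__setattr__(self, "phi_open", self.phi_close + self.delta_d)


def pore_diameter(phi_close: float, delta_d: float) -> PoreEstimate:
    """Open-pore diameter: phi_open = phi_close + dD at the gating residue."""
    return PoreEstimate(phi_close=phi_close, delta_d=delta_d)


def expected_far_efficiency(d_open: float, r0: float, n_mer: int = 5) -> float:
    """Predicted non-neighbouring-pair efficiency for an open diameter.

    Consistency check: the open model fixes R_f = D_open * sin(2pi/n), whose
    efficiency should agree with the measured far-pair peak.
    """
    r_f = ring_pair_distance(d_open, n_mer, 2 if n_mer >= 5 else 1)
    return float(efficiency_at_distance(r_f, r0))


def helix_tilt_indicator(
    delta_r_top: float, delta_r_bottom: float, axial_separation: float
) -> float:
    """Rigid-rod tilt-change indicator in degrees.

    arctan((dr_top - dr_bottom)/axial_separation): positive when the
    periplasmic end of a helix moves radially further than the cytoplasmic
    end, i.e. the helix tilts toward the membrane plane on opening.  This is
    a first-order indicator only; it ignores helix bending.
    """
    if axial_separation <= 0:
        raise ValueError("axial separation must be positive")
    return math.degrees(
        math.atan((delta_r_top - delta_r_bottom) / axial_separation)
    )


def simulate_oligomer_mixture(
    f_hex: float,
    r_n: float,
    r0: float,
    n_molecules: int = 450,
    noise_sd_e: float = 0.04,
    seed: int = 0,
):
    """Monte-Carlo effect of hexamer contamination on the efficiency peak.

    Each molecule is a hexamer with probability ``f_hex``, else a pentamer.
    The adjacent-subunit chord ``r_n`` is held fixed between oligomer sizes
    (same subunit packing), so a hexamer's circumcircle is wider.  One donor
    and one acceptor are placed uniformly on distinct subunits; the pair's
    efficiency follows from its chord distance, with Gaussian measurement
    noise ``noise_sd_e``.  A single Gaussian is fitted to the pooled sample.

    Because the adjacent chord is conserved, the near-pair efficiency is
    *identical* between oligomer sizes; contamination only redistributes
    weight among the chord classes (hexamers add longer sep-2/sep-3
    chords).  The fitted width therefore grows with ``f_hex`` while the
    fitted centre moves much less than the class separations — the main
    effect is broadening, not a peak shift.  Converting the (unchanged)
    adjacent chord to a diameter under the wrong oligomer assumption is
    biased by exactly :func:`oligomer_scaling`.

    Returns ``(e_values, (mean, sd))`` of the fitted Gaussian.
    """
    if not 0.0 <= f_hex <= 1.0:
        raise ValueError("f_hex must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes = np.where(rng.random(n_molecules) < f_hex, 6, 5)
    e_values = np.empty(n_molecules)
    for i, n in enumerate(sizes):
        d = diameter_from_adjacent(r_n, int(n))
        pos = rng.choice(n, size=2, replace=False)
        sep = int(min(abs(pos[0] - pos[1]), n - abs(pos[0] - pos[1])))
        r = ring_pair_distance(d, int(n), sep)
        e_values[i] = efficiency_at_distance(r, r0)
    e_values = e_values + rng.normal(0.0, noise_sd_e, n_molecules)
    return e_values, (float(np.mean(e_values)), float(np.std(e_values)))
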