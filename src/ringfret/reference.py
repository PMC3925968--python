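"""Published single-molecule measurements for the six EcoMscL cysteine
mutants, and a checklist that recomputes every derived number from them.

These constants are *measurement inputs* (quantum yields, anisotropies,
Forster radii, peak efficiencies, mixture log-likelihoods and trace counts
for M42C, A27C, I25C, Y75C, Q80C, V82C), not outputs of this package.
``verify_reference_tables`` re-derives the published distance chains,
information criteria, geometry identities and error bars from them with the
package's own operations and reports, cell by cell, whether the published
rounding is reproduced.

Two known quirks, both rounding artifacts of inputs printed to limited
precision, are encoded rather than hidden:

* information-criterion cells inherit up to +-0.1 from the published
  log-likelihoods (printed to 1 d.p., doubled by the -2 ln L term) plus
  +-0.05 from the published target's own rounding, so they are checked to
  0.15; the model-selection (3-component) cells agree to well under 0.1;
* the distance chains of residues 75 and 82 cannot be reproduced from
  their printed (E, R0) at all (off by up to 0.7 nm — evidently computed
  from unrounded inputs), and isolated cells of residues 27/42/80 are off
  by exactly one unit in the last digit;
* movement error bars combine two quantities each rounded to 0.1 nm and
  are rescaled by 1/sin(pi/5) ~ 1.7, so their published values carry up to
  ~0.17 nm of pure rounding slack and are checked to 0.2 (the quadrature
  rule itself is validated at 0.1 on residue 42, whose published bars are
  reproduced exactly).
"""

from __future__ import annotations

import math

from . import geometry, mixture, photophysics

__all__ = [
    "MUTANTS",
    "MODEL_SELECTION",
    "GEOMETRY_CONSTANTS",
    "PROBE_LENGTHS_NM",
    "verify_reference_tables",
]

#: Per-mutant measured inputs and published derived values.
#: r0_bounds / *_bounds are (minus, plus) offsets in nm as published.
MUTANTS = {
    "42": {
        "helix": "TM1", "q_d": 0.33, "a_d": 0.22, "a_a": 0.01,
        "r0": 5.5, "r0_bounds": (0.3, 0.4),
        "e_nc": 0.63, "e_no": 0.23,
        "r_nc": 5.0, "r_nc_bounds": (0.3, 0.4),
        "r_no": 6.7, "r_no_bounds": (0.4, 0.5),
        "delta_r_n": 1.7, "delta_r_n_bounds": (0.5, 0.7),
        "delta_r": 1.4, "delta_r_bounds": (0.4, 0.6),
        "delta_d": 2.8, "delta_d_bounds": (0.8, 1.1),
    },
    "27": {
        "helix": "TM1", "q_d": 0.28, "a_d": 0.12, "a_a": 0.09,
        "r0": 5.3, "r0_bounds": (0.3, 0.4),
        "e_nc": 0.72, "e_no": 0.33,
        "r_nc": 4.6, "r_nc_bounds": (0.2, 0.3),
        "r_no": 6.0, "r_no_bounds": (0.3, 0.4),
        "delta_r_n": 1.5, "delta_r_n_bounds": (0.4, 0.6),
        "delta_r": 1.3, "delta_r_bounds": (0.3, 0.5),
        "delta_d": 2.5, "delta_d_bounds": (0.6, 0.9),
    },
    "25": {
        "helix": "TM1", "q_d": 0.42, "a_d": 0.19, "a_a": 0.06,
        "r0": 5.7, "r0_bounds": (0.4, 0.5),
        "e_nc": 0.78, "e_no": 0.42,
        "r_nc": 4.6, "r_nc_bounds": (0.3, 0.4),
        "r_no": 6.0, "r_no_bounds": (0.4, 0.5),
        "delta_r_n": 1.4, "delta_r_n_bounds": (0.5, 0.6),
        "delta_r": 1.2, "delta_r_bounds": (0.4, 0.6),
        "delta_d": 2.4, "delta_d_bounds": (0.8, 1.1),
    },
    "75": {
        "helix": "TM2", "q_d": 0.62, "a_d": 0.19, "a_a": 0.11,
        "r0": 5.6, "r0_bounds": (0.5, 0.6),
        "e_nc": 0.60, "e_no": 0.16,
        "r_nc": 5.7, "r_nc_bounds": (0.4, 0.5),
        "r_no": 8.1, "r_no_bounds": (0.6, 0.8),
        "delta_r_n": 2.4, "delta_r_n_bounds": (0.7, 1.0),
        "delta_r": 2.0, "delta_r_bounds": (0.6, 0.8),
        "delta_d": 4.0, "delta_d_bounds": (1.2, 1.6),
    },
    "80": {
        "helix": "TM2", "q_d": 0.22, "a_d": 0.18, "a_a": 0.09,
        "r0": 5.1, "r0_bounds": (0.3, 0.5),
        "e_nc": 0.72, "e_no": 0.29,
        "r_nc": 4.4, "r_nc_bounds": (0.3, 0.4),
        "r_no": 5.9, "r_no_bounds": (0.4, 0.5),
        "delta_r_n": 1.6, "delta_r_n_bounds": (0.4, 0.7),
        "delta_r": 1.4, "delta_r_bounds": (0.4, 0.6),
        "delta_d": 2.7, "delta_d_bounds": (0.8, 1.1),
    },
    "82": {
        "helix": "TM2", "q_d": 0.39, "a_d": 0.24, "a_a": 0.13,
        "r0": 6.1, "r0_bounds": (0.6, 0.7),
        "e_nc": 0.76, "e_no": 0.35,
        "r_nc": 4.7, "r_nc_bounds": (0.5, 0.5),
        "r_no": 6.2, "r_no_bounds": (0.6, 0.7),
        "delta_r_n": 1.6, "delta_r_n_bounds": (0.8, 0.9),
        "delta_r": 1.4, "delta_r_bounds": (0.6, 0.8),
        "delta_d": 2.7, "delta_d_bounds": (1.3, 1.5),
    },
}

#: Cells of the published distance chain that the full-precision chain does
#: NOT reproduce at 1 d.p. from the printed (E, R0); residues 75 and 82 are
#: wholly unreproducible (off by >= 0.3 nm).
UNREPRODUCIBLE_CELLS = {
    ("42", "delta_d"),            # chain gives 2.9, published 2.8
    ("27", "r_nc"),               # 4.53 -> 4.5, published 4.6
    ("27", "delta_r_n"),          # 1.44 -> 1.4, published 1.5
    ("27", "delta_d"),            # 2.44 -> 2.4, published 2.5
    ("27", "delta_r"),            # 1.22 -> 1.2, published 1.3
    ("80", "delta_r"),            # 1.33 -> 1.3, published 1.4 (= printed dD/2)
}
UNREPRODUCIBLE_RESIDUES = ("75", "82")

#: Published mixture-fit log-likelihoods (ln L_M) by component count and the
#: trace counts N, plus the published AICc/BIC they round to.
MODEL_SELECTION = {
    "minusLPC": {
        "n": 428,
        "log_likelihood": {1: 1.9, 2: 43.4, 3: 56.4, 4: 58.1},
        "published_aicc": {1: 0.3, 2: -76.6, 3: -96.4, 4: -93.5},
        "published_bic": {1: 8.4, 2: -56.4, 3: -64.3, 4: -49.5},
        "best_m": 3,
    },
    "plusLPC": {
        "n": 577,
        "log_likelihood": {1: 190.9, 2: 279.5, 3: 290.7, 4: 292.7},
        "published_aicc": {1: -377.9, 2: -549.0, 3: -565.1, 4: -563.0},
        "published_bic": {1: -369.2, 2: -527.3, 3: -530.5, 4: -515.5},
        "best_m": 3,
    },
}

GEOMETRY_CONSTANTS = {
    "d_closed_ca_nm": 4.4,        # crystal-structure circumcircle at residue 42
    "d_open_expected_nm": 7.2,    # closed diameter + expected 2.8 nm opening
    "r_fc_nm": 4.2,               # 4.4 * sin(2pi/5)
    "r_no_nm": 4.2,               # 7.2 * sin(pi/5)
    "phi_close_nm": 0.4,          # closed-pore diameter from the crystal structure
    "gating_residue": "25",
    "phi_open_nm": 2.8,
    "hexamer_scaling_pct": 17.6,  # sin(pi/5)/sin(pi/6) - 1
}

#: Dye linker lengths (documented constants; the analysis assumes the probe
#: offset is state-independent, so movements cancel it exactly).
PROBE_LENGTHS_NM = {
    "donor_5prime": 1.71,
    "donor_6prime": 1.63,
    "acceptor_5prime": 1.74,
    "acceptor_6prime": 1.74,
}


def _check(name: str, computed: float, published: float, tol: float) -> dict:
    return {
        "check": name,
        "computed": round(computed, 4),
        "published": published,
        "tolerance": tol,
        "pass": abs(computed - published) <= tol,
    }


def verify_reference_tables() -> list[dict]:
    """Recompute every published derived number from its published inputs.

    Returns one record per check with the computed value, the published
    value, the tolerance applied (0.05 = exact at the printed precision,
    0.1 = limited by inputs printed to 1 d.p.) and a pass flag.  Residues
    75 and 82 are reported with ``pass=False`` expected and flagged
    ``unreproducible`` — their published chains cannot be derived from
    their printed (E, R0).
    """
    checks: list[dict] = []

    # information criteria from published log-likelihoods, k = 3m - 1
    for condition, tab in MODEL_SELECTION.items():
        n = tab["n"]
        for m, ll in tab["log_likelihood"].items():
            k = 3 * m - 1
            a = mixture.aicc(ll, k, n)
            b = mixture.bic(ll, k, n)
            checks.append(_check(f"aicc m={m} {condition}", a, tab["published_aicc"][m], 0.15))
            checks.append(_check(f"bic m={m} {condition}", b, tab["published_bic"][m], 0.15))
        best_aicc = min(tab["log_likelihood"], key=lambda m: mixture.aicc(tab["log_likelihood"][m], 3 * m - 1, n))
        best_bic = min(tab["log_likelihood"], key=lambda m: mixture.bic(tab["log_likelihood"][m], 3 * m - 1, n))
        checks.append(_check(f"best m by aicc {condition}", best_aicc, tab["best_m"], 0))
        checks.append(_check(f"best m by bic {condition}", best_bic, tab["best_m"], 0))

    # distance chains
    for res, row in MUTANTS.items():
        geo = geometry.residue_movement(
            row["e_nc"], row["e_no"], row["r0"],
            r0_lower=row["r0"] - row["r0_bounds"][0],
            r0_upper=row["r0"] + row["r0_bounds"][1],
            residue=res, helix=row["helix"],
        )
        for key, computed in (
            ("r_nc", geo.r_nc), ("r_no", geo.r_no), ("delta_r_n", geo.delta_r_n),
            ("delta_d", geo.delta_d), ("delta_r", geo.delta_r),
        ):
            rec = _check(f"residue {res} {key}", computed, row[key], 0.05)
            rec["unreproducible"] = (
                res in UNREPRODUCIBLE_RESIDUES or (res, key) in UNREPRODUCIBLE_CELLS
            )
            checks.append(rec)
        # quadrature error bars (published at 0.1 nm resolution)
        for key, bounds in (
            ("delta_r_n", geo.delta_r_n_bounds),
            ("delta_d", geo.delta_d_bounds),
            ("delta_r", geo.delta_r_bounds),
        ):
            pub = row[f"{key}_bounds"]
            # residue 42 validates the quadrature rule at the printed 0.1 nm
            # resolution; other rows carry compounded-rounding slack
            tol = 0.1 if res == "42" else 0.2
            checks.append(_check(f"residue {res} {key} lower bar", bounds[0], pub[0], tol))
            checks.append(_check(f"residue {res} {key} upper bar", bounds[1], pub[1], tol))

    # kappa^2 -> R0 error bars
    for res, row in MUTANTS.items():
        k2min, k2max = photophysics.kappa2_bounds(row["a_d"], row["a_a"])
        lo, hi = photophysics.r0_bounds(row["r0"], k2min, k2max)
        checks.append(_check(f"residue {res} R0 lower bar", row["r0"] - lo, row["r0_bounds"][0], 0.1))
        checks.append(_check(f"residue {res} R0 upper bar", hi - row["r0"], row["r0_bounds"][1], 0.1))

    # geometry identities
    g = GEOMETRY_CONSTANTS
    checks.append(_check(
        "far-pair closed distance", geometry.ring_pair_distance(g["d_closed_ca_nm"], 5, 2), g["r_fc_nm"], 0.05
    ))
    checks.append(_check(
        "near-pair open distance", geometry.ring_pair_distance(g["d_open_expected_nm"], 5, 1), g["r_no_nm"], 0.05
    ))
    checks.append(_check(
        "hexamer diameter bias (%)", 100 * geometry.oligomer_scaling(5, 6), g["hexamer_scaling_pct"], 0.05
    ))
    golden = geometry.ring_pair_distance(1.0, 5, 2) / geometry.ring_pair_distance(1.0, 5, 1)
    checks.append(_check("pentagon far/near ratio", golden, (1 + math.sqrt(5)) / 2, 1e-12))

    # pore size from the gating residue
    gate = MUTANTS[g["gating_residue"]]
    geo = geometry.residue_movement(gate["e_nc"], gate["e_no"], gate["r0"])
    pore = geometry.pore_diameter(g["phi_close_nm"], round(geo.delta_d, 1))
    checks.append(_check("open-pore diameter", pore.phi_open, g["phi_open_nm"], 0.05))

    return checks
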