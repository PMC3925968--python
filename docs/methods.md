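# Methods

`ringfret` implements the analysis chain for single-molecule FRET (smFRET)
measurements of a homo-pentameric membrane channel — the mechanosensitive
channel of large conductance (MscL) reconstituted into immobilised
liposomes — from raw two-channel intensity traces to the diameter of the
open pore. This note records the models, the parameter choices, and the
places where the design was genuinely open.

## Trace model and virtual sorting

A molecule carries stochastic numbers of donor (AF488-like) and acceptor
(AF568-like) dyes on an engineered cysteine present once per subunit. Each
subunit independently carries a donor with probability `mean_donors/n`, an
acceptor with probability `mean_acceptors/n`, or nothing (at most one dye
per subunit), so the marginal donor count is Binomial(n, p) with the
configured means (defaults 1.7 donors, 1.3 acceptors per pentamer).

Per frame, each surviving donor of brightness *B* transfers to the
surviving acceptors with combined efficiency `E = K/(1+K)`,
`K = Σ E_ij/(1−E_ij)` (rate competition). The donor channel carries
`B(1−E)` per donor; the acceptor channel carries sensitized emission plus
a leakage fraction ℓ of the donor-channel signal. Bleach times are
exponential, donors faster than acceptors (defaults 8 s vs 16 s over a
30 s window at 10 Hz), so donors usually bleach first. Noise is Gaussian
per frame (default 5 % of brightness); the analysis uses level
*differences*, which are insensitive to the exact noise family.

**The γ convention.** γ is defined as the *measured* ratio ΔI_A/ΔI_D at an
acceptor bleach. Because the leakage contribution to the acceptor channel
rises by ℓ·ΔI_D at exactly that event, the physical sensitized-emission
scaling is γ+ℓ. With this convention the corrected efficiency

    E = (I_A − ℓ·I_D) / (I_A + γ·I_D)

is an exact algebraic inverse of the trace model: on noiseless traces the
round trip recovers the generating E, ℓ and γ to machine precision, which
the tests assert.

**Step detection** is penalized least-squares change-point segmentation
(exact optimal partitioning, penalty 2σ̂²·log n per change point, σ̂ from
the median absolute deviation of first differences), followed by merging
of level changes below 3σ̂. It is deterministic and training-free. Segment
levels exclude 2 guard frames around each change point. A molecule is kept
for FRET only if both channels show a single simultaneous (±1 frame)
terminal drop and both end at background; acceptor-first traces (acceptor
drop coincident with a donor rise) calibrate γ, and donor-only labelled
samples calibrate ℓ. Bleach events closer than 6 frames to each other or
to the trace start are rejected — no guarded averaging window exists.

**Identifiability limit.** An acceptor that outlives the donor leaves no
signature (after the donor dies nothing excites it), so a molecule with a
silent second acceptor is indistinguishable *in principle* from a
single-pair molecule — in this simulation and in the real experiment
alike. Sorting is exact on molecules whose every dye produces an
observable step; the tests condition on that subset. For the same reason
the pipeline's default dataset models the virtually-sorted single-pair
population directly; full stochastic labelling is used in the
sorting-specific studies.

## Mixture inference

Corrected efficiencies are fitted unbinned by maximum likelihood with
1–4 Gaussian components (EM, best of 20 seeded restarts, quantile-spread
initialisation, convergence at ΔlogL < 1e−8). The parameter count is
k = 3m−1 (m means, m standard deviations, m−1 free weights). Component
standard deviations are constrained to ≥ 0.015 — the shot-noise resolution
of a per-molecule efficiency — because the unconstrained mixture
likelihood is unbounded and an aggressive multi-start search otherwise
converges to spike components holding a handful of points. Maximizers with
a component pinned at the floor or holding fewer than 3 effective points
are classed as spurious and only used if no interior solution exists
(McLachlan–Peel practice).

The component count is selected by the corrected Akaike criterion
AICc = −2 ln L + 2k + 2k(k+1)/(N−k−1), with BIC = −2 ln L + k ln N
reported alongside; when they disagree AICc decides and the disagreement
is flagged in the report. On three-component samples at the separations
and widths of the M42C data (means 0.10/0.28/0.63, sds 0.04/0.05/0.08,
N = 450) BIC recovers m = 3 in 30/30 seeded replicates; AICc, whose
small-sample penalty is more liberal, agrees in roughly three quarters —
a property of the criterion, not of the optimizer, since the likelihood
gains of the m = 4 fits (3–4.5) straddle the AICc penalty (≈3.2).

E values are not clipped to [0,1] before fitting (clipping would bias the
low-E component); clipping into edge bins happens only when histograms are
built for display and for ΔP² = Σ(P_i⁺ − P_i⁻)², computed on bins of width
0.05 over [−0.1, 1.1].

Peak-to-state assignment: the highest-mean component of the closed-
enriched condition is E_nc; in the opened condition any component within
0.1 of E_nc is treated as residual closed channels and the highest
remaining mean is E_no.

## Photophysics

Quantum yield follows the fluorescein-in-0.1 M-NaOH standard protocol
(Q_S = 0.925, literature value) with the (A, F, n²) ratio formula;
absorbances above 0.1 trigger an inner-filter warning. Anisotropy
A = (I∥−I⊥)/(I∥+2I⊥) assumes instrument- and NA-corrected inputs. The
orientation factor is bracketed as κ²_max = ⅔(1+2.5A_d+2.5A_a),
κ²_min = ⅔(1−1.25A_d−1.25A_a), and R0 (computed as
0.02108·(κ²n⁻⁴Q_D J)^{1/6} nm with J in M⁻¹cm⁻¹nm⁴) inherits the bracket
through the sixth root. These are *maximum possible* orientation errors,
not standard errors.

The synthetic spectra are single Gaussians whose widths are set so the
overlap integral lands at the literature magnitude for this dye pair
(~2×10¹⁵ M⁻¹cm⁻¹nm⁴); they carry spectral shape, not absolute brightness.
Worth recording: the published per-mutant radii for residues 42/27/25/80
are mutually consistent under R0 ∝ Q^{1/6}, but those of residues 75/82
are not, and the absolute published R0 (5.5 nm at Q_D = 0.33) implies an
overlap integral about twice the literature value. The distance analysis
therefore treats the measured per-mutant radii as inputs in their own
right rather than re-deriving them from spectra.

## Ring geometry

A labelled residue defines a regular n-gon on a circumcircle of diameter
D; subunits `sep` apart sit at chord distance `D·sin(π·sep/n)`, so the
pentamer far/near ratio is the golden ratio exactly. Efficiency converts
to distance via `R = R0(1/E−1)^{1/6}`. Because the dye adds an unknown but
state-independent radial offset, only *changes* are structural:
ΔR_n = R_no − R_nc, ΔD = ΔR_n/sin(π/n), Δr = ΔD/2, and the open pore is
Φ_open = Φ_close + ΔD at the gating residue (I25, Φ_close = 0.4 nm from
the closed crystal structure). Probe lengths (1.63–1.74 nm) are shipped as
documented constants only; the analysis assumes Δr_probe = 0 on opening.

R0 bounds enter each distance multiplicatively; the bounds of ΔR_n combine
the two distance bounds in quadrature (this reproduces the published
residue-42 error bars to 0.1 nm; the rule is not stated in the source
tables and is validated on that row). Reported values are rounded to
0.1 nm after the full-precision chain.

**Oligomer impurity.** Hexamers assembled from the same subunits conserve
the adjacent-subunit chord, so the near-pair efficiency is *identical* and
contamination cannot shift it; what changes is the weight distribution
over chord classes (hexamers add longer sep-2 and sep-3 chords). A single
Gaussian fitted to the pooled efficiency sample therefore broadens with
the hexamer fraction while its centre moves within replicate scatter — the
simulation quantifies exactly this. Converting the (unchanged) adjacent
chord to a diameter under the wrong oligomer assumption is biased by
sin(π/5)/sin(π/6)−1 ≈ 17.6 %.

The helix-tilt indicator arctan((Δr_top−Δr_bottom)/axial separation) is a
rigid-rod first-order statistic: a positive value (periplasmic residue
moves radially further) indicates tilting toward the membrane plane. It
ignores helix bending and is reported as an indicator, not an angle
measurement.

## Default study conditions

The default dataset emulates the M42C measurement: 450 molecules per
condition, closed fractions 0.6 (immobilisation tension only) and 0.05
(with the conical-lipid opening agent); state efficiencies
(closed, near) = 0.63, (closed, far) = (open, near) = 0.28,
(open, far) = 0.10 — the equality implements the finding that the middle
peak is the overlap of the closed far-pair with the open near-pair, making
the generating mixture genuinely three-component; per-pair heterogeneity
sd 0.05, matching the observed peak widths. Trace length (30 s), frame
rate (10 Hz) and brightness (500 counts/frame) are not dictated by any
published value and are plain configuration.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
stochastic labelling, staircase bleaching, leakage and detection
asymmetry, a state mixture, shot-like noise. It does not emulate camera
PSFs, background drift, blinking, liposome-to-liposome variability,
inter-channel FRET between neighbouring proteins, or membrane-tension
mechanics (the opening fraction is a direct parameter). Passing recovery
tests therefore validate the estimators under the assumed model, not the
model's adequacy for any particular microscope.

## Known limitations

- Silent multi-acceptor molecules (above) contaminate the kept population
  under full stochastic labelling; their combined-efficiency tail is a
  real feature of the experiment that the peak-based analysis absorbs.
- AICc alone over-selects m = 4 in roughly a quarter of replicates at
  N ≈ 450; BIC is the consistent criterion at this sample size, and the
  pipeline reports both.
- The published distance chains of residues 75 and 82 are not derivable
  from their printed inputs (evidently computed from unrounded values);
  the package flags rather than reproduces them.
- Problem sizes in the tests (450 molecules/condition, 300-frame traces,
  5–100 Monte-Carlo replicates) were chosen to make the statistical
  assertions decisive at interactive runtimes.
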