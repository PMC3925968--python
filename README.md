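# ringfret

Single-molecule FRET analysis of homo-oligomeric ring channels: from
two-channel intensity traces to corrected efficiencies, mixture-model peak
inference, Förster-radius photophysics, and the ring geometry that turns
efficiency changes into subunit movements and an open-pore diameter.

The scientific problem: the mechanosensitive channel of large conductance
(MscL) is a bacterial pentamer whose closed structure is known but whose
open-pore size and opening mechanism (barrel-stave vs helix-tilt) were
not. smFRET on liposome-reconstituted channels measures, per labelled
residue, the donor–acceptor distance between neighbouring subunits in the
closed and open states. Because labelling is stochastic on a five-fold
symmetric ring, molecules with exactly one donor and one acceptor are
selected *after the fact* by counting photobleaching steps per channel
("virtual sorting"). The package implements that pipeline and a seeded
synthetic-trace generator with full ground truth, so every estimator is
testable without raw microscope data.

The core quantities, in the field's standard notation:

- corrected efficiency `E = (I_A − ℓI_D)/(I_A + γI_D)`, with leakage
  ℓ ≈ 0.09 from donor-only samples and detection factor γ = ΔI_A/ΔI_D
  ≈ 0.89 from acceptor-first bleaching events;
- unbinned Gaussian-mixture MLE over per-molecule E, component count by
  `AICc = −2lnL + 2k + 2k(k+1)/(N−k−1)` and `BIC = −2lnL + k lnN`,
  k = 3m−1;
- `R = R0(1/E − 1)^{1/6}`, with `R0 = 0.02108(κ²n⁻⁴Q_D J)^{1/6}` nm and
  κ² bracketed from anisotropies;
- pentamer ring geometry `R_sep = D·sin(π·sep/5)`, so
  `ΔD = ΔR_n/sin(π/5)`, `Δr = ΔD/2`, and `Φ_open = Φ_close + ΔD` at the
  gating residue.

## Worked example

Run the numbered analyses in order (each is a thin driver over the
library; traces land in `scratch/`, tables in `results/`):

```
python analysis/01_simulate_dataset.py
python analysis/02_virtual_sorting.py
python analysis/03_mixture_fits.py
python analysis/05_residue_movements.py
```

`02` prints the sorting tally and calibration factors recovered from the
synthetic data (generated with ℓ = 0.09, γ = 0.89):

```
sorting tally: {'kept_donor_first': 508, 'kept_acceptor_first': 170, 'discarded': 222}
leakage  l = 0.0889 +- 0.0015  (n=56 donor-only molecules)
detection gamma = 0.8909 +- 0.0056  (n=170 acceptor-first traces)
```

`03` fits the efficiency mixtures per condition; three components win in
both, and the closed/open near-pair peaks land on the generating values
(0.63 and 0.28):

```
minusLPC: N = 266 analysed molecules
  m=3: logL=   173.3  AICc=  -330.0  BIC=  -301.9 <- best (AICc)
  chosen m=3 (BIC minimum m=3); means=[0.124, 0.285, 0.631] weights=[0.134, 0.498, 0.369]
...
state efficiencies: E_nc = 0.631, E_no = 0.271
```

`05` runs the distance chain for the six labelled residues from their
published inputs and prints the pore estimate from the gating residue:

```
gating residue I25: dr = 1.2 nm, dD = 2.4 nm
open pore: phi_open = 0.4 + 2.4 = 2.8 nm
```

meaning residue I25 moves 1.2 nm away from the pore axis on opening, the
protein diameter at that residue grows by 2.4 nm, and the open pore
reaches 2.8 nm. All residues move outward, and the periplasmic ends move
further than the cytoplasmic ends — the helix-tilt signature. `06` and
`07` reproduce the histogram-variance series (ΔP² falls by 99 % as the
tension-only condition approaches the opened one) and the
hexamer-contamination study (peak broadening without a centre shift;
+17.6 % diameter bias for pure hexamers analysed as pentamers).

An end-to-end run with a single command (simulate → sort → fit →
photophysics → geometry, reproducible under `--seed`):

```
ringfret run --seed 1 --out-dir results/run
ringfret verify          # recompute the published tables from printed inputs
```

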