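"""Corrected FRET efficiencies and Gaussian-mixture peak inference.

Takes the sorted pair intensities from 02_virtual_sorting.py, applies the
corrected-efficiency formula with the estimated l and gamma, fits 1-4
component mixtures by unbinned maximum likelihood per condition, selects
the component count by AICc/BIC, and assigns the closed/open near-pair
peak efficiencies.  Writes a model-selection table, the histogram table
and the chosen peaks to results/.
"""

import json
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from ringfret import mixture  # noqa: E402

SEED = 1


def main() -> None:
    results = ROOT / "results"
    pairs_csv = results / "pair_intensities.csv"
    corr_json = results / "corrections.json"
    if not pairs_csv.exists() or not corr_json.exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_virtual_sorting.py")], check=True)
    pairs = pd.read_csv(pairs_csv)
    corr = json.loads(corr_json.read_text())
    leak, gamma = corr["leakage"]["value"], corr["gamma"]["value"]

    table_rows = []
    chosen = {}
    samples = {}
    for condition, grp in pairs.groupby("condition"):
        e = mixture.fret_efficiency(grp["I_A"].to_numpy(), grp["I_D"].to_numpy(), leak, gamma)
        sample = mixture.EfficiencySample(e, str(condition))
        samples[condition] = sample
        models = [mixture.fit_gmm_mle(sample, m, seed=SEED + 7 * m) for m in (1, 2, 3, 4)]
        best, selection = mixture.select_model(models)
        chosen[condition] = (best, selection)
        print(f"\n{condition}: N = {sample.n} analysed molecules")
        for mod in models:
            mark = " <- best (AICc)" if mod.m == best.m else ""
            print(f"  m={mod.m}: logL={mod.log_likelihood:8.1f}  "
                  f"AICc={mod.aicc:8.1f}  BIC={mod.bic:8.1f}{mark}")
            table_rows.append({
                "condition": condition, "m": mod.m, "logL": mod.log_likelihood,
                "k": mod.k, "AICc": mod.aicc, "BIC": mod.bic,
            })
        print(f"  chosen m={best.m} (BIC minimum m={selection['m_bic']}); "
              f"means={np.round(best.means, 3).tolist()} "
              f"weights={np.round(best.weights, 3).tolist()}")

    e_nc, e_no = mixture.assign_state_efficiencies(
        chosen["minusLPC"][0], chosen["plusLPC"][0]
    )
    p_plus = mixture.histogram_probability(samples["plusLPC"].values, condition="plusLPC")
    p_minus = mixture.histogram_probability(samples["minusLPC"].values, condition="minusLPC")
    dp2 = mixture.delta_p2(p_plus, p_minus)
    print(f"\nstate efficiencies: E_nc = {e_nc:.3f}, E_no = {e_no:.3f}")
    print(f"histogram variance between conditions: dP^2 = {dp2:.4f}")

    pd.DataFrame(table_rows).to_csv(results / "model_selection.csv", index=False)
    hist_rows = [
        {"condition": c, "bin_lo": lo, "probability": p}
        for c, h in (("minusLPC", p_minus), ("plusLPC", p_plus))
        for lo, p in zip(h.bin_edges[:-1], h.probabilities)
    ]
    pd.DataFrame(hist_rows).to_csv(results / "efficiency_histograms.csv", index=False)
    (results / "state_efficiencies.json").write_text(json.dumps({
        "e_nc": e_nc, "e_no": e_no, "delta_p2": dp2,
        "selection": {c: chosen[c][1] for c in chosen},
    }, indent=2))


if __name__ == "__main__":
    main()
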