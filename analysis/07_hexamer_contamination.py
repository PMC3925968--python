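"""Effect of hexamer contamination on the efficiency peak and the diameter.

Sweeps the hexamer fraction, fitting a single Gaussian to each simulated
efficiency sample (100 replicates per fraction).  With the adjacent-
subunit chord conserved between oligomer sizes, contamination broadens
the fitted peak while barely moving its centre; analysing a pure-hexamer
sample under the pentamer assumption misstates the diameter by the
geometric factor sin(pi/5)/sin(pi/6) - 1 = 17.6%.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from ringfret.geometry import oligomer_scaling, simulate_oligomer_mixture  # noqa: E402

SEED = 1
R_N = 5.0  # nm, apparent adjacent chord (dye to dye), closed state
R0 = 5.5


def main() -> None:
    rows = []
    for f_hex in (0.0, 0.1, 0.2, 0.3, 0.5, 1.0):
        stats = [
            simulate_oligomer_mixture(f_hex, R_N, R0, seed=SEED + 1000 * int(10 * f_hex) + r)[1]
            for r in range(100)
        ]
        centers = [s[0] for s in stats]
        widths = [s[1] for s in stats]
        rows.append({
            "f_hex": f_hex,
            "peak_center": np.mean(centers),
            "center_replicate_sd": np.std(centers),
            "peak_width": np.mean(widths),
        })
    table = pd.DataFrame(rows)
    print("fitted efficiency peak vs hexamer fraction (100 replicates each):")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    shift = abs(table["peak_center"].iloc[3] - table["peak_center"].iloc[0])
    broad = table["peak_width"].iloc[3] - table["peak_width"].iloc[0]
    print(f"\nat 30% hexamers: centre shift {shift:.4f} "
          f"(replicate sd {table['center_replicate_sd'].iloc[0]:.4f}), "
          f"width increase {broad:+.4f} -> broadening, not a shift")
    print(f"pure-hexamer diameter bias under the pentamer assumption: "
          f"{100 * oligomer_scaling(5, 6):.1f}%")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "hexamer_broadening.csv", index=False)


if __name__ == "__main__":
    main()
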