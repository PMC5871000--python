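#!/usr/bin/env python
"""Extract the inhomogeneous distribution function (IDF) per pressure.

Loads the manifest written by 01_simulate.py, runs the spectral
evaluation (baseline correction, line detection, vibronic assignment,
amplitude tracking, trace normalization, pooled Gaussian fit) for every
pressure group, and writes the IDF-versus-pressure table to
results/idf_beta_none.tsv.
"""

from pathlib import Path

import pandas as pd

from fln_kappa import ExtractionParams, extract_idf_series
from fln_kappa.io import config_hash, load_experiment, write_results_table
from fln_kappa.simulator import default_modes

ROOT = Path(__file__).resolve().parent.parent
MANIFEST = ROOT / "scratch" / "demo_experiment" / "manifest.json"
OUT = ROOT / "results" / "idf_beta_none.tsv"


def main() -> None:
    groups = load_experiment(MANIFEST)
    print(f"loaded {sum(len(v) for v in groups.values())} spectra "
          f"in {len(groups)} pressure groups")
    modes = [m.vib_energy for m in default_modes()]
    estimates, skipped = extract_idf_series(groups, modes, ExtractionParams())
    for pressure, reason in skipped:
        print(f"skipped p = {pressure:.2f} GPa: {reason}")
    df = pd.DataFrame(
        {
            "pressure_gpa": [e.pressure for e in estimates],
            "center_cm1": [e.center for e in estimates],
            "center_se": [e.center_se for e in estimates],
            "sigma_cm1": [e.sigma for e in estimates],
            "sigma_se": [e.sigma_se for e in estimates],
            "n_points": [e.n_points for e in estimates],
        }
    )
    OUT.parent.mkdir(exist_ok=True)
    write_results_table(df, OUT, config_hash({"manifest": str(MANIFEST)}))
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
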