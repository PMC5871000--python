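#!/usr/bin/env python
"""Generate one synthetic pressure-tuning FLN experiment on disk.

Simulates the beta-Zn-HbA (no effector) condition -- 8 pressures spanning
0-1.2 GPa x 25 excitation frequencies, 5% detector noise, broad background
-- and writes the spectrum files, the experiment manifest, and the
ground-truth sidecar under scratch/demo_experiment/.  The downstream
scripts (02, 03) evaluate this dataset without touching the sidecar.
"""

from pathlib import Path

from fln_kappa import default_config, generate_experiment

OUT = Path(__file__).resolve().parent.parent / "scratch" / "demo_experiment"


def main() -> None:
    cfg = default_config(kappa_true=0.36, seed=42, sample="beta-Zn-HbA")
    manifest = generate_experiment(cfg, OUT)
    n = len(cfg.pressures) * len(cfg.excitations)
    print(f"wrote {n} spectra ({len(cfg.pressures)} pressures x "
          f"{len(cfg.excitations)} excitations)")
    print(f"manifest: {manifest}")
    print(f"generative truth (sidecar only): kappa = {cfg.kappa_true}/GPa")


if __name__ == "__main__":
    main()
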