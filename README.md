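# fln-kappa

Pressure-tuning fluorescence line narrowing (FLN) analysis: infer the local
compressibility of a protein matrix around a fluorescent chromophore from
the pressure dependence of its inhomogeneous distribution function (IDF).

## The problem

In FLN spectroscopy a frozen protein sample (10 K, diamond anvil cell) is
excited with a narrow laser line. Only the chromophores whose vibronic
absorption is resonant with the laser emit, so the sharp (0,0) emission
lines select a narrow slice of the ensemble. Reading the intensity of one
vibronic line while stepping the excitation frequency traces out the IDF —
the distribution of (0,0) transition energies over the frozen conformational
ensemble. Hydrostatic pressure shifts and broadens a Gaussian IDF linearly:

    nu00(p)  = nu00 + 2 kappa p nu0s          (center)
    sigma(p) = (1 + 2 kappa p) sigma0         (width)

where `nu0s = nu00 - nu_vac` is the matrix (solvent) shift and `kappa` is
the isothermal compressibility of the matrix around the chromophore. Through
the fluctuation relation `<(V-<V>)^2> = kappa kB T <V>`, kappa measures the
equilibrium volume fluctuations — the conformational flexibility — of the
protein in a shell of roughly one subunit around the chromophore.

The scientific application is hemoglobin: replacing the heme of either the
alpha or the beta subunits with fluorescent Zn-protoporphyrin IX makes the
two subunits separately observable, and the recovered kappa quantifies
their dynamic asymmetry and how heterotropic allosteric effectors (Cl-,
IHP, BZF) change it.

This package provides the whole chain as tested, reusable code:

- `fln_kappa.core_model` — the closed-form physics (line shift, IDF
  transform, volume fluctuations);
- `fln_kappa.simulator` — a generative model of full pressure-series FLN
  experiments (vibronic lines, background, detector noise);
- `fln_kappa.io` — the plain-text spectrum dialect, manifests, TSV tables;
- `fln_kappa.extraction` — baseline correction, line detection, vibronic
  assignment, amplitude tracking, and the pooled Gaussian IDF fit;
- `fln_kappa.inference` — kappa from weighted straight-line fits of the IDF
  trends, with uncertainties, plus condition comparison;
- `fln_kappa.radius` — the chromophore interaction-radius calculator;
- `fln_kappa.pipeline` — end-to-end orchestration.

## Worked example

The numbered scripts under `analysis/` run the study end to end on
synthetic data. `analysis/01_simulate.py` writes a full experiment
(8 pressures x 25 excitations, 5% noise, generative kappa = 0.36/GPa for
beta-Zn-HbA) under `scratch/`; `02` extracts the IDF per pressure; `03`
fits the compressibility:

```
$ python analysis/01_simulate.py
wrote 200 spectra (8 pressures x 25 excitations)
$ python analysis/02_extract_idf.py
 pressure_gpa  center_cm1  center_se  sigma_cm1  sigma_se  n_points
         0.00    17001.15       1.38      59.01      1.40        37
         0.17    16972.86       1.88      66.25      1.88        49
         ...
         1.20    16827.27       5.44     110.16      6.30        49
$ python analysis/03_fit_kappa.py
kappa        = 0.368 +/- 0.035 /GPa
sigma0 (fit) = 58.8 cm^-1, width slope 43.3 cm^-1/GPa (R^2 0.971)
center slope = -143.1 cm^-1/GPa -> solvent shift estimate -195 +/- 19 cm^-1
```

The width grows and the center red-shifts linearly with pressure; the
fitted kappa (0.368/GPa) recovers the generative truth (0.36/GPa) and the
solvent-shift estimate recovers the generative -200 cm^-1.
`analysis/04_condition_survey.py` repeats this for twelve
subunit/effector conditions and contrasts them pairwise (the no-effector
alpha/beta contrast comes out at z ~ 4), and `analysis/05_interaction_radius.py`
prints the interaction-radius numbers (R0 = 4.2 A from a 300 A^3
chromophore, R_98% = 15 A, R_99% = 19 A).

The same stages are scriptable through the CLI:

```sh
fln-kappa simulate --config cfg.json --out exp/ --seed 1
fln-kappa extract  --manifest exp/manifest.json --out idf.tsv
fln-kappa fit-kappa --idf idf.tsv --out results.tsv
fln-kappa compare  --results results.tsv
fln-kappa radius   --volume 300 --error 0.02
```

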