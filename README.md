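# semil

**Sparse Estimation of Mutual Information Landscapes** for cellular
biochemical reaction networks (BRNs).

Engineered gene circuits are sensors: they transmit information about an
input stimulus (inducer concentration, temperature, …) into a distribution
of single-cell gene-expression outputs.  The natural performance metric is
the mutual information I(X; g) between input and output — the log2 count of
distinguishable response levels — but conventional estimators need output
data at densely spaced inputs or a parametric response model.  Real
experiments (flow cytometry, single-cell microscopy) measure output
distributions at only ~5–20 input values.

`semil` closes that gap.  For every continuous input distribution in a
bounded two-parameter *design space* — beta distributions in log
concentration, indexed by geometric mean E and geometric SD σ — it finds
the best sparse discrete approximation on the measured input values
(minimising squared CDF + moment mismatch on the probability simplex),
estimates the output channel model-free from binned single-cell
frequencies, computes

    I(X; g) = H(g) − Σᵢ P(xᵢ) H(g | xᵢ)      [bits]

and removes the finite-sample plug-in bias by subsampling each input group
and extrapolating linearly in 1/N to infinite data.  The result is a
mutual information **landscape** I(E, σ) with its optimal input
distribution, near-optimal contour (within 0.05 bits of the maximum) and,
when a ground truth exists, per-cell error maps.  A Blahut–Arimoto
baseline gives the unconstrained channel capacity that upper-bounds every
landscape.

Validation machinery is included as first-class code: a gamma-noise Hill
dose–response model with *exact* mutual information by numerical
integration, and an exact Gillespie simulator of a lactose-operon-like
induction circuit (with an optional lacY-style positive-feedback variant).

## Worked example

Generate mock flow-cytometry data from the packaged dose–response model
(5 input values, 20 000 cells each), then compute the landscape:

```
$ semil simulate --kind gamma --n-inputs 5 --n-cells 20000 --seed 1 --out demo.csv
wrote 100000 cells at 5 inputs to demo.csv

$ semil landscape --config run.yaml      # run.yaml points at the same generator
{
  "E": 27.6551,
  "sigma": 24.0709,
  "I": 0.8827,
  "on_boundary": false
}
```

The optimal input environment for this circuit is centred at a geometric
mean of ≈ 28 concentration units with a wide geometric SD of ≈ 24, and
transmits 0.88 bits — the circuit resolves just under two input levels.
`landscape.csv` (one row per (E, σ) cell; infeasible cells blank, not 0)
and `summary.json` are written next to it.

Compare against the validation ground truth and the capacity baseline:

```
$ semil validate --n-inputs 5 --n-cells 20000 --grid-size 15 --seed 1
{
  "n_inputs": 5,
  "n_cells_per_input": 20000,
  "median_abs_error_high_mi_bits": 0.0105,
  "max_abs_error_bits": 0.5901,
  "true_max_bits": 0.8914,
  "high_mi_cells": 92
}

$ semil capacity --dataset demo.csv
{
  "capacity_bits": 1.6791,
  ...
  "optimal_masses": { "1.0": 0.266, "6.73": 0.254, "45.25": 0.244,
                      "304.44": 0.0000065, "2048.0": 0.235 }
}
```

In the high-information region of the design space the estimate is within
~0.01 bits of exact numerical integration, even though the data cover only
five input values.  The landscape maximum (0.88 bits) stays below the
unconstrained capacity (1.68 bits), whose optimal input is the typical
spiky Blahut–Arimoto solution — note the input with mass 6.5e-6 — that the
smooth design space is built to avoid.  Errors are largest near the edge
of the design space where the input distribution's geometric mean
approaches the lowest measured input value.

The same pipeline runs on experimental data: export gated single-cell
events to a CSV with columns `input,output` (one row per cell), set
`dataset:` instead of `generator:` in the YAML config, and map uninduced
(zero-concentration) wells with `zero_input_value`.

## Library layout

| module | contents |
|---|---|
| `semil.design_space` | bounded log-beta input family, (E, σ) ↔ (α, β) map, feasibility-masked grids |
| `semil.srom` | sparse discrete approximation: CDF/moment errors, simplex fit |
| `semil.mi_core` | binning, model-free conditional model, entropies, MI, subsampling bias correction |
| `semil.landscape` | landscape evaluation, optimum, near-optimal contour, error maps, writer/plotter |
| `semil.synthetic_models` | gamma response model + exact MI quadrature, Gillespie SSA, lac-like networks |
| `semil.capacity` | Blahut–Arimoto capacity baseline |
| `semil.io` / `semil.cli` | dataset reader/writer, YAML run config, `semil` subcommands |

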