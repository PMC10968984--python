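# phasordr

Phasor-FLIM NAD(P)H drug-response scoring for patient-derived tumor
organoids.

## The problem

Label-free metabolic imaging can read out whether a tumor organoid responds
to a drug.  The cofactor NAD(P)H fluoresces with a short lifetime when free
in solution and a long lifetime when protein-bound; treatments that push
cells toward oxidative, less proliferative metabolism raise the bound
fraction.  Fluorescence-lifetime imaging (FLIM) with time-correlated
single-photon counting (TCSPC) records, per pixel, a histogram of photon
arrival times, and the *phasor* transform turns each histogram — fit-free —
into a point

    g = Σ c_k cos(ω t_k) / Σ c_k,   s = Σ c_k sin(ω t_k) / Σ c_k,

at the angular frequency ω = 2π · f_rep · harmonic of the pulsed laser.
Mono-exponential decays of lifetime τ land on the universal semicircle at
g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); two-component mixtures land on the chord
between their component phasors, at the bound component's photon fraction.
Orthogonal projection of a calibrated pixel phasor onto the free↔bound
chord therefore yields the pixel's bound fraction f_b ∈ [0, 1].

This package implements the full analysis chain:

1. **Simulation** (`phasordr.synthetic`) — ground-truthed TCSPC decay cubes:
   bi-exponential free/bound mixtures, Gaussian IRF jitter and timing
   offset, wrapping at the repetition period, Poisson photon noise, flat
   background dark counts, multi-FOV control/treated experiments, and a
   4 ns mono-exponential calibration standard (fluorescein).
2. **I/O** (`phasordr.io`) — HDF5 decay cubes (TIFF+JSON fallback), CSV
   sample sheets and curves, JSON results; deterministic writers,
   validating readers.
3. **Phasor transform and referencing** (`phasordr.phasor`) — per-pixel
   (g, s), intensity masking, derivation of the rotation+scale correction
   from the standard of known lifetime, median smoothing.
4. **Free/bound unmixing** (`phasordr.fractions`) — chord projection to
   per-pixel f_b, per-FOV normalized fractional distributions, and
   condition-level mean ± sd curves across 12–20 fields of view.
5. **Drug-response scoring** (`phasordr.scoring`) — the %DR statistic:
   a one-sided Welch gate on per-FOV mean bound fractions (treated >
   control), then per-bin Welch tests; %DR is 100× the area of the treated
   mean curve inside the significantly bound-shifted region.  Samples are
   non-responders (NR) when %DR < 5 and responders (Resp) when %DR ≥ 5.
6. **Cohort reporting** (`phasordr.cohort`) — per-sample stratification
   tables sorted by %DR and cross-treatment NR/Resp concordance.

## Worked example

```python
from phasordr import (AnalysisConfig, ExperimentTruth, SimParams,
                      score_cubes, simulate_experiment)

base = SimParams(image_height=32, image_width=32,
                 mean_photons_per_pixel=500, seed=11)
truth = ExperimentTruth(control_bound_fraction=0.40,
                        treated_bound_fraction=0.45,
                        n_fov_control=15, n_fov_treated=15)
exp = simulate_experiment(truth, base, sample_id="Gb1", treatment="REGO")
result = score_cubes(exp.control_cubes, exp.treated_cubes,
                     exp.calibration_cube, AnalysisConfig())
print(f"%DR = {result.percent_dr:.1f}  label = {result.label}  "
      f"gate p = {result.shift_direction_p:.3g}  "
      f"significant bins = {int(result.significant_bins.sum())}")
```

prints

```
%DR = 97.9  label = Resp  gate p = 1.33e-38  significant bins = 9
```

A true bound-fraction shift of +0.05 across 15 fields of view per arm is
highly significant (gate p ≈ 1e-38): 9 of the 100 fraction bins show a
significant bound-ward excess, and because nearly all of the treated
distribution mass lies inside that shifted region, %DR ≈ 98 and the sample
is classified a responder.  With `treated_bound_fraction=0.40` (a null
experiment) the gate is not significant, %DR = 0, and the label is NR —
note that %DR measures how much of the treated curve sits in the
significantly shifted region, not the size of the metabolic shift itself.

The same pipeline is scriptable from the shell:

```bash
phasordr simulate --out-dir data --seed 11 --image-size 32 --photons 500 \
    --treated-fb 0.45 --sample-id Gb1 --treatment REGO
phasordr cohort --sheet data/sample_sheet.csv --data-dir data --out-dir out
cat out/report.txt
```

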