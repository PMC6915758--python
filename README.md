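# depwell

Analysis stack for dielectrophoresis (DEP) well-plate cytometry: recover
the electrical phenotype of cells — specific membrane capacitance C_m,
specific membrane conductance G_m, cytoplasm conductivity σ_cyt and
permittivity ε_cyt — from label-free DEP spectra, and everything around
that core: well-image densitometry, subpopulation mixture decomposition,
whole-cell parameter conversion, interleaved high-resolution spectrum
synthesis, and fixed-period cosinor analysis of parameter time series.

It is written for cell biophysicists and instrument developers who work
with well-based DEP readers (20 wells, each energised at one of 20
frequencies spanning 1 kHz–45 MHz, imaged once per second), and it ships a
seeded synthetic-data generator so every stage can be exercised and tested
without an instrument.

## The model

A cell in suspension is a single-shell dielectric sphere: a conducting
cytoplasm core wrapped in a thin, poorly conducting membrane.  Each
material is a lossy dielectric with complex permittivity

    ε*(f) = ε₀ε_r − j σ / (2πf)

The membrane enters through its thickness-normalised specific parameters,
ε_mem = C_m·d/ε₀ and σ_mem = G_m·d (d = 5 nm), and the shelled sphere
reduces to an effective permittivity

    ε*_cell = ε*_mem (γ³ + 2Φ) / (γ³ − Φ),   γ = r/(r−d),
    Φ = (ε*_cyt − ε*_mem) / (ε*_cyt + 2ε*_mem)

The measured quantity is proportional to the real part of the
Clausius–Mossotti factor

    f_CM = (ε*_cell − ε*_med) / (ε*_cell + 2ε*_med),   Re[f_CM] ∈ [−½, 1]

whose sign sets the direction of cell motion in the non-uniform field
(positive DEP: towards the well wall; negative: towards the axis).  A
heterogeneous sample produces the weighted superposition of its
subpopulations' factors; fitting the model to a spectrum by damped least
squares (Levenberg–Marquardt) recovers the cell parameters, mixture
weights and the instrument scale factor α.

Well images are reduced to a polarisability index by monitoring light
absorbance in ten concentric rings: the area-scaled, sign-weighted sum of
per-ring absorbance slopes over the standard 10-second window is
proportional to Re[f_CM].

Rhythms in fitted parameters (e.g. σ_cyt of whole blood sampled every 30
minutes) are tested with a fixed-period cosinor,
y(t) = M + A·cos(2πt/τ + φ), solved in closed form with the period τ taken
from behavioural observation, never fitted.

## Worked example

Simulate fifteen replicate Jurkat spectra at 3 % noise, average them, and
fit the single-shell model (the `jurkat_3dep` preset is C_m 9.96 mF/m²,
G_m 25 S/m², ε_cyt 60, σ_cyt 0.48 S/m, r = 6.5 µm in a 10 mS/m medium):

```sh
depwell simulate-spectrum --preset jurkat_3dep --noise-sd 0.03 \
    --replicates 15 --seed 7 --out reps/
python -c "
from depwell import average_spectra, read_spectrum, write_spectrum
import glob
reps = [read_spectrum(p) for p in sorted(glob.glob('reps/replicate_*.csv'))]
write_spectrum(average_spectra(reps), 'jurkat_mean.csv')"
depwell fit --spectrum jurkat_mean.csv --radius "6.5 um" \
    --medium-conductivity "10 mS/m" --seed 1
```

prints

```
DEP spectrum fit
================
population 1 (weight 1.000):
  radius                  6.5 um (fixed unless freed)
  membrane capacitance    9.89 mF/m^2
  membrane conductance    15.19 S/m^2
  cytoplasm permittivity  54.72
  cytoplasm conductivity  0.4724 S/m
scale alpha               0.9994
r^2 (Pearson, data vs model) 0.999942
convergence:
  converged  True
  evaluations 29
  residual sum of squares 0.532419
```

Membrane capacitance and cytoplasm conductivity come back within ~1 % of
the generating values; membrane conductance and cytoplasm permittivity are
weakly identifiable at this noise level for a low-conductance cell (see
`docs/methods.md`).  The r² is the squared Pearson correlation between the
averaged data and the fitted curve.  Converting to a whole-cell value,
`whole_cell_capacitance(9.96e-3, 6.5e-6)` gives 5.3 pF, the number a patch
clamp would report.

The interleave planner reproduces the chip-shift trick for synthesising
100-point spectra from five 20-point chips:

```sh
$ depwell plan-frequencies --fmin "1 kHz" --fmax "40 MHz" --points 20 --chips 5
shift factor: 1.118
chip 0: 1000 1746.68 3050.9 ...
```

Other subcommands: `mixture-fit` (up to four subpopulations),
`densitometry` (well image stack → polarisability index), `cosinor`
(fixed-period rhythm fit), `make-fixtures` (complete synthetic dataset
with a manifest).

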