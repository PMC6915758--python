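# Cell / medium parameter presets for the DEP well system.
#
# Quantities are strings with SI unit suffixes and are normalised to SI on
# load.  `source` records where each parameter set comes from; entries
# marked "synthetic" contain values back-computed from whole-cell numbers
# or assumed, not directly measured specific parameters.

jurkat_3dep:
  description: >
    Jurkat T-lymphocyte, best-fit dielectric parameters from the DEP well
    system (majority "healthy" population), measured in 10 mS/m medium.
  source: benchmark table, DEP well system column
  cell:
    radius: "6.5 um"
    mem_capacitance: "9.96 mF/m^2"
    mem_conductance: "25 S/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "0.48 S/m"
  medium:
    conductivity: "10 mS/m"
    rel_permittivity: 78

jurkat_minority:
  description: >
    Minority (~10%) Jurkat subpopulation resembling the majority set but
    with cytoplasm conductivity reduced by 85% (to 70 mS/m) and membrane
    conductance halved — consistent with damage or early apoptosis.
  source: subpopulation decomposition of the Jurkat benchmark spectra
  cell:
    radius: "6.5 um"
    mem_capacitance: "9.96 mF/m^2"
    mem_conductance: "12.5 S/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "70 mS/m"
  medium:
    conductivity: "10 mS/m"
    rel_permittivity: 78

rbc_human:
  description: >
    Human red blood cell, radius 4.1 um, measured in 43 mS/m medium.
    Specific membrane values are synthetic: back-computed from the reported
    whole-cell capacitance (1.32 pF) and conductance (201 nS) via the
    spherical surface area; cytoplasm values are literature-plausible
    assumptions.
  source: whole-cell benchmarks (specific values synthetic)
  cell:
    radius: "4.1 um"
    mem_capacitance: "6.25 mF/m^2"
    mem_conductance: "952 S/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "0.5 S/m"
  medium:
    conductivity: "43 mS/m"
    rel_permittivity: 78

platelet_hiconf_200:
  description: >
    Human platelet in 200 mS/m medium; membrane values from the
    high-conductivity measurement series, cytoplasm conductivity 150 mS/m.
  source: high-conductivity measurement series
  cell:
    radius: "0.51 um"
    mem_capacitance: "7.6 mF/m^2"
    mem_conductance: "35.7 kS/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "150 mS/m"
  medium:
    conductivity: "200 mS/m"
    rel_permittivity: 78

platelet_hiconf_400:
  description: >
    Human platelet in 400 mS/m medium; cytoplasm conductivity 250 mS/m.
  source: high-conductivity measurement series
  cell:
    radius: "0.51 um"
    mem_capacitance: "7.6 mF/m^2"
    mem_conductance: "35.7 kS/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "250 mS/m"
  medium:
    conductivity: "400 mS/m"
    rel_permittivity: 78

platelet_hiconf_800:
  description: >
    Human platelet in 800 mS/m medium; cytoplasm conductivity 400 mS/m.
  source: high-conductivity measurement series
  cell:
    radius: "0.51 um"
    mem_capacitance: "7.6 mF/m^2"
    mem_conductance: "35.7 kS/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "400 mS/m"
  medium:
    conductivity: "800 mS/m"
    rel_permittivity: 78

platelet_wholecell:
  description: >
    Human platelet parameterised from the whole-cell benchmark numbers
    (121 fF, 365 nS at radius 0.51 um): specific capacitance ~37 mF/m^2,
    conductance ~112 kS/m^2.  Kept alongside the high-conductivity set
    because the two sections imply different specific capacitances.
  source: whole-cell benchmarks (specific values synthetic)
  cell:
    radius: "0.51 um"
    mem_capacitance: "37 mF/m^2"
    mem_conductance: "112 kS/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "0.25 S/m"
  medium:
    conductivity: "43 mS/m"
    rel_permittivity: 78

hl1:
  description: >
    HL-1 murine cardiomyocyte.  Radius is an assumed literature-plausible
    10 um (synthetic; not directly reported), giving a specific membrane
    capacitance of ~6.3 mF/m^2 from the 7.9 pF whole-cell benchmark.
  source: whole-cell benchmarks (radius assumed, specific values synthetic)
  cell:
    radius: "10 um"
    mem_capacitance: "6.3 mF/m^2"
    mem_conductance: "100 S/m^2"
    cyt_rel_permittivity: 60
    cyt_conductivity: "0.4 S/m"
  medium:
    conductivity: "10 mS/m"
    rel_permittivity: 78
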