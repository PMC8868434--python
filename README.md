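# lipidqi

Fatty-acid nutritional quality analysis for GC-MS composition tables, plus
antioxidant / ACE-inhibition bioassay readout evaluation.

Given a fatty-acid profile (shorthand codes like `C20:5n3` with percentages
of total FA), `lipidqi` computes the eight standard nutritional quality
indices:

| index | meaning |
|---|---|
| PS | PUFA/SFA ratio |
| IA | index of atherogenicity |
| IT | index of thrombogenicity |
| h/H | hypo-/hypercholesterolemic ratio |
| HPI | health-promoting index (reciprocal of IA) |
| UI | unsaturation index (double-bond-weighted sum) |
| SED | EPA + DHA, % of total FA |
| TFA | total trans fatty acids, % |

It also evaluates DPPH/ABTS radical-scavenging and ACE-inhibition
percentages from plate absorbances and estimates IC50 from dose–response
series (four-parameter logistic fit with log-linear interpolation
fallback). A synthetic-data module generates compositional profiles and
noisy dose–response curves with known ground truth, and the two published
diatom reference profiles ship with the package
(`lipidqi.reference_profiles()`).

## CLI

```bash
# eight indices from a profile CSV (columns: name,code,percentage[,sd];
# "N.D." marks a not-detected entry)
lipidqi indices --input profile.csv --precision 2

# per-dose percent activity + IC50 from a plate CSV
# (columns: concentration,unit,a_control,a_sample,a_sample_blank[,a_inhibitor_blank])
lipidqi bioassay --assay dpph --input plate.csv
lipidqi bioassay --assay ace  --input plate.csv

# synthetic fixtures with known ground truth
lipidqi simulate --kind profile --seed 1 --output sim_profile.csv
lipidqi simulate --kind plate --seed 1 --ic50 0.2 --noise-sd 3 --output sim_plate.csv
```

All commands accept `--config file.yaml` supplying any flag by its
parameter name (unknown keys are rejected) and emit deterministic JSON.
Errors map to distinct nonzero exit codes (3 load/parse, 4 assay values,
5 IC50 not estimable, 6 configuration).

## Package layout

- `lipidqi.nomenclature` — shorthand parsing (`C<carbons>:<db>[n<pos>][c|t]`),
  saturation and polyene classification
- `lipidqi.profile` — profile CSV I/O and class aggregation (`GroupSums`)
- `lipidqi.indices` — the eight index equations and `compute_all`
- `lipidqi.bioassay` — activity percentages and IC50 estimation
- `lipidqi.synthetic` — simulators and the packaged reference profiles
- `lipidqi.cli` — `lipidqi` command-line entry point
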