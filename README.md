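# chpi

Quantification of CH-π interaction free energies in calix[4]pyrrole
host–guest inclusion complexes, from NMR and ITC titration data.

## The problem

Aryl-extended calix[4]pyrroles bind trimethylamine *N*-oxide (guest
**2a**) and trimethylphosphine *P*-oxide (**2b**) in acetonitrile
through four convergent NH···O hydrogen bonds. When the receptor
carries two or four *meso*-phenyl "walls", the methyl groups of the
bound guest additionally engage in CH-π contacts with those walls.
Because the octamethyl receptor (**1a**) offers the identical
hydrogen-bond array but no walls, the wall contribution can be isolated
by a reference-state subtraction — a double-difference in the spirit of
a double-mutant cycle:

    ΔΔG = ΔG(walled complex) − ΔG(reference complex)

Dividing ΔΔG over the methyl-to-ring contacts gives the energy of a
single CH-π interaction, and regressing ΔΔG against the electrostatic
surface potential (ESP) at the ring centroids — a pseudo-Hammett linear
free-energy relationship — tests whether the interaction is
electrostatically driven. A slope indistinguishable from zero indicates
a dispersion-dominated ("typical") CH-π interaction.

This package implements that entire workflow for an audience of
supramolecular and physical-organic chemists:

* **`chpi.hbond`** — Hunter's descriptor model for single hydrogen
  bonds in a competing solvent, `ΔG_HB = [−(α − α_s)(β − β_s) + 6]/4.18`
  kcal/mol, plus exact `K = exp(−ΔG/RT)` conversions;
* **`chpi.equilibrium`** — exact 1:1 speciation, fast-exchange NMR
  shift prediction, and the perfusion-cell Wiseman heat-per-injection
  model;
* **`chpi.fitting`** — global shared-K NMR fits, (n, K, ΔH) ITC fits,
  asymptotic and bootstrap uncertainties;
* **`chpi.decomposition`** — ΔΔG decomposition, per-contact energies,
  summary tables and the ΔΔG-vs-ESP regression;
* **`chpi.geometry`** — ring centroids/normals and the (d, Θ, Φ)
  parameters of CH-π contacts from XYZ/PDB coordinates;
* **`chpi.synthetic`** — generators for titrations, thermograms and
  geometry fixtures at the study conditions, plus the bundled 12-system
  scenario set;
* **`chpi.pipeline` / `chpi` CLI** — orchestration and reporting.

## Worked example

Predict the single pyrrole → *N*-oxide hydrogen bond in acetonitrile:

```sh
$ chpi predict-hb pyrrole 2a
{
  "donor": "pyrrole",
  "acceptor": "2a",
  "solvent": "acetonitrile",
  "dG_kcal_mol": -0.7727,
  "K_M": 3.6872
}
```

With α(pyrrole) = 3.0, β(**2a**) = 12.2 and CH₃CN (α_s = 1.7,
β_s = 5.1), a single hydrogen bond is worth −0.77 kcal/mol, i.e. an
association constant of only 3.7 M⁻¹ — the four-fold NH···O array plus
the CH-π contacts must account for the much larger measured
stabilities.

Simulate a titration of the two-wall OMe host (true K = 5150 M⁻¹,
1.6 mM host, 14 points to 12 equivalents, 0.005 ppm shift noise) and
fit it back:

```sh
$ chpi simulate-nmr titration.csv --k 5150 --seed 1
$ chpi fit-nmr titration.csv
```

returns K = 5191 ± 71 M⁻¹ (ΔG = −5.066 ± 0.008 kcal/mol), with fitted
NH limits δ_free = 7.402, δ_bound = 9.400 ppm — the true parameters
recovered well within the uncertainty of the tabulated 5.15 ± 1.3 × 10³
M⁻¹.

Rebuild the full summary table from the tabulated constants:

```sh
$ chpi reproduce-table1
```

emits one row per host × guest with K ± σ, −ΔG, −ΔΔG and per-contact
energies: the four-wall *N*-oxide complexes give −ΔΔG = 4.49 and 4.32
kcal/mol (≈ 1.1 kcal/mol per contact over four contacts), roughly
double the two-wall values (2.53, 2.36, 2.48), while

```sh
$ chpi lfer -- -20.7,2.51 -12.9,2.36 -2.0,2.52
```

gives slope = 0.0014 ± 0.0094 kcal/mol per kcal/mol of ESP (p = 0.90):
tuning the ring electrostatics from −20.7 to −2.0 kcal/mol leaves the
CH-π energy unchanged, the signature of a dispersion-dominated
interaction.

The full pipeline (simulate → fit → decompose → LFER, writing
`table1.csv`, `lfer.json` and a run log) runs from a YAML config:

```sh
$ chpi run config.yaml
```

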