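# nativemet

Data analysis for **native-metabolomics screens**: LC-MS experiments in
which an intact protein is infused post-column under near-native buffer
conditions, so that metabolites binding the protein show up as transient
mass shifts of its charge envelope at their elution time. Pairing the
native run with a conventional LC-MS/MS run over the same gradient links
each binding event to a precursor mass and fragment spectrum — binding
information for an entire crude extract from a single gradient, before any
compound is purified.

The package is aimed at mass spectrometrists and natural-product chemists
running (or simulating) such screens. It provides:

- **Charge-state deconvolution** of multiply protonated protein spectra
  into neutral-mass species and chromatographic mass traces, via a
  charge-series-consistency algorithm (`nativemet.deconvolution`). For an
  ion of charge z, `m/z = (M + z·m_p)/z` with the proton mass
  `m_p = 1.00727646677 Da`; a species is accepted only when several
  consecutive charge states agree on M.
- **Feature detection** on both the deconvoluted protein traces and the
  metabolomics MS1 traces, with MS/MS linking (`nativemet.features`).
- **Δmass/RT matching** — the screen's core inference: protein feature P
  and ligand L match at stoichiometry n iff
  `|(mass(P) − apo) − n·neutral(L)| ≤ 4 Da` and
  `|rt(P) − rt(L)| ≤ 0.2 min` (`nativemet.matching`).
- **Molecular networking** with the modified cosine (fragments pair at
  equal m/z or offset by the precursor mass difference) plus typed
  protein-binding edges (`nativemet.networking`).
- **Quantification**: apparent-Kd titration fits
  `ratio(c) = Rmax·c/(Kd+c)`, detection-limit summaries, and 4PL IC50
  fits `y = bottom + (top−bottom)/(1+(c/ic50)^hill)`
  (`nativemet.quant`).
- **Synthetic paired runs with planted ground truth** so every stage is
  testable without instrument data (`nativemet.simulate`), and mzML / MGF
  / feature-CSV (native and MZmine-style dialects) / GraphML I/O
  (`nativemet.io`).

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Deconvolve a synthetic native-MS scan containing the apo protein
(25232.6 Da) and a protein–ligand complex (26195.1 Da):

```python
from nativemet.deconvolution import deconvolve_scan
from nativemet.simulate import proof_of_concept_scan

scan = proof_of_concept_scan(apo_mass=25232.6, complex_mass=26195.1)
species = deconvolve_scan(scan)
for sp in species:
    print(f"{sp.neutral_mass:10.1f} Da  z={list(sp.supporting_charges)}  "
          f"I={sp.total_intensity:.2e}")
print(f"delta mass: {species[1].neutral_mass - species[0].neutral_mass:.1f} Da")
```

prints

```
   25232.6 Da  z=[7, 8, 9, 10]  I=5.54e+05
   26195.1 Da  z=[7, 8, 9, 10]  I=3.69e+05
delta mass: 962.5 Da
```

Both envelopes are recovered from their four in-window charge states, and
the 962.5 Da mass difference is the neutral mass of the bound ligand — the
readout that identifies a binder without purifying it.

The same works from the shell for a complete screen:

```sh
nativemet simulate --n-binders 4 --n-decoys 2 --seed 3 --out-dir screen
printf 'native_mzml: screen/native.mzML\nmetabolomics_mzml: screen/metabolomics.mzML\napo_mass: 25232.6\n' > cfg.yaml
nativemet run --config cfg.yaml --output-dir out
```

which ends with a QC summary such as

```json
{
  "apo_mass": 25232.6,
  "n_matches": 4,
  "n_metabolite_features": 6,
  "n_binding_edges": 4,
  "n_msms_edges": 6,
  "network_components": [4, 1, 1]
}
```

all four planted binders are matched and networked into one family of
four, the two decoys stay singletons, and `out/` holds the feature tables,
match table, GraphML network, apo XIC and depletion calls. Stage-level
subcommands (`deconv`, `features`, `match`, `network`, `fit-titration`,
`fit-ic50`) run the same steps on individual files.

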