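# npscreen

One-class chemometric screening of new psychoactive substances (NPS) from
UPLC-HRMS/MS spectral features.

Forensic laboratories face a stream of designer drugs — synthetic
cathinones, cannabinoids, fentanyl and nitazene analogues — that are minor
structural variations of known compounds and therefore missing from
spectral libraries. `npscreen` implements a class-level screening strategy:
instead of matching a spectrum to a library entry, it asks, for each drug
class, *is this substance consistent with the class or not?* A substance
can match one class, several structurally related classes, or none at all
(a non-drug or a genuinely new chemotype).

The package is aimed at analytical/forensic chemists and chemometricians
working with centroided tandem-MS peak lists.

## Method

1. **Feature matrix.** Each analyte is reduced to eight variables: precursor
   *m/z*, retention time, the *m/z* of its three most intense fragments at or
   above a 10% relative-intensity threshold, and the three corresponding
   neutral losses. The neutral-loss reference is configurable (base peak or
   precursor ion).
2. **Partitioning.** The matrix is autoscaled and split 75/25 into training
   and test sets with the deterministic Kennard-Stone maximin algorithm.
3. **Exploration.** PCA on the training set, with outlier diagnostics from
   Hotelling's *T*² (score distance) and the *Q* residual (orthogonal
   distance) against 95% critical limits — the numeric backing of score,
   loading and influence plots.
4. **SIMCA classification.** One PCA model per drug class (class-local
   autoscaling, classes of at least four analytes). The component count per
   class maximizes cross-validated *efficiency*, the geometric mean of
   sensitivity and specificity, using five cancellation groups for classes
   of ≥ 8 analytes and leave-one-out otherwise. A sample is accepted by a
   class when its combined distance

   d = √( N_h·T²/T²₀ + N_q·Q/Q₀ ) ≤ √( χ²₁₋α(N_h + N_q) )

   where T²₀, Q₀ are training means and N_h, N_q moment-estimated degrees
   of freedom (a data-driven SIMCA acceptance area); a classical
   "box" rule (T² ≤ T²crit and Q ≤ Qcrit) is available instead.
5. **Reporting.** Per-class sensitivity, specificity and efficiency on any
   labeled set; Coomans tables comparing two class models on the same
   samples; soft-classification verdicts for unknowns.

A seeded synthetic-panel generator emulates the statistical shape of a
multi-class screening panel (per-class precursor and retention-time
windows, characteristic neutral-loss motifs, intensity noise, occasional
missing fragments), so the whole workflow is testable without instrument
data.

## Worked example

```python
import npscreen as nps

panel = nps.generate_panel(nps.well_separated_templates(), 20, seed=7)
matrix = nps.build_matrix(panel.records, nl_reference="precursor")
print(f"panel: {matrix.n_samples} analytes x {len(matrix.columns)} variables")

_, scaled = nps.autoscale_fit(matrix)
split = nps.kennard_stone_split(scaled, train_fraction=0.75)
print(f"Kennard-Stone: {len(split.train_indices)} train / {len(split.test_indices)} test")

models = nps.fit_all_classes(matrix.subset(split.train_indices), A_max=3)
report = nps.validate(models, matrix.subset(split.test_indices), set_label="test")
print(report.rows[["class", "set", "sensitivity", "specificity", "efficiency"]]
      .round(3).to_string(index=False))

unknown = nps.generate_panel([nps.no_nps_template()], 1, seed=1)
verdict = nps.classify(models, nps.build_matrix(unknown.records, nl_reference="precursor"))
print("accepted classes for the non-NPS unknown:", verdict.accepted_classes[0])
```

prints

```
panel: 180 analytes x 8 variables
Kennard-Stone: 135 train / 45 test
               class  set  sensitivity  specificity  efficiency
                 JWH test        1.000          1.0       1.000
              PINACA test        1.000          1.0       1.000
arylcyclohexylamines test        1.000          1.0       1.000
     benzodiazepines test        1.000          1.0       1.000
          cathinones test        1.000          1.0       1.000
           fentanyls test        1.000          1.0       1.000
           nitazenes test        1.000          1.0       1.000
     phenethylamines test        0.667          1.0       0.816
         tryptamines test        1.000          1.0       1.000
accepted classes for the non-NPS unknown: []
```

Sensitivity is the fraction of true class members a model accepts,
specificity the fraction of non-members it rejects; the one imperfect
sensitivity above comes from a class with only three test samples, one of
which fell just outside the 95% acceptance boundary. The non-NPS unknown
is rejected by every class model — the screening outcome a soft classifier
should give for a substance outside the modeled chemistry.

The same workflow is available from the shell:

```sh
npscreen synth --n-per-class default --seed 7 --out panel.mgf
npscreen build-matrix --in panel.mgf --nl-reference precursor --out matrix.csv
npscreen split --matrix matrix.csv --out-train train.csv --out-test test.csv
npscreen fit --train train.csv --out models.json
npscreen report --models models.json --labeled test.csv --out report.csv \
    --coomans JWH,PINACA --coomans-out coomans.csv
npscreen predict --models models.json --in unknowns.csv --out predictions.csv
```

or all at once with `npscreen run --spectra panel.mgf --out-dir out/`, which
also writes a `manifest.json` of content hashes (a rerun on identical
inputs reproduces identical hashes).

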