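# glypheno

Genotype–phenotype severity scoring for glycine decarboxylase (GLDC)
missense disease.

Loss-of-function mutations in *GLDC* (P-protein, 1020 residues) cause
non-ketotic hyperglycinemia (NKH), a neuro-metabolic disorder whose clinical
course ranges from attenuated to severe. Plasma glycine does not predict
severity, and most of the ~250 known missense mutations are biochemically
uncharacterized. `glypheno` implements a quantitative bridge between
genotype and clinical outcome for researchers and clinical geneticists
working on NKH and similar rare enzymopathies:

* **COS (clinical outcome score)** — a 0–12 severity scale summing four
  Likert-scored symptom domains: seizures ∈ {0,1,3}, cognitive ∈ {0..3},
  brain malformation ∈ {0,3}, muscle/movement ∈ {0..3}. Unmentioned domains
  stay *missing* (distinct from a scored 0). Deceased patients and records
  with <2 scored domains are excluded. COS 0 is asymptomatic, 1–5
  attenuated, >5 severe.
* **MMS (multiparametric mutation score)** — for each missense variant, 18
  binary parameters over stability (predicted ΔΔG < −1.5 kcal/mol
  destabilizing, ≥ +1.5 stabilizing), conservation (residue grade ≥ 7 of 9;
  BLOSUM62 ≥ 0 for the substitution, weighted −1), location (helix, sheet,
  C-terminus, active site, its 7 Å shell, N-terminal PLP pocket, H-protein
  interface, dimer interface) and amino-acid property changes (polarity,
  charge, aromaticity, proline, codon availability, volume ≥ 50 Å³).
  MMS = Σᵢ sᵢ·pᵢ with unit signs sᵢ. Compound heterozygotes score 0.5 per
  allele meeting a condition, with four extra indicators for deletion,
  nonsense/frameshift, intronic/splice and mitochondrial-leader alleles.
* **WMMS (weighted MMS)** — parameter weights w are trained by ordinary
  least squares of COS on the parameter matrix (patients/mutations plus
  zero-COS healthy controls): ŵ = argmin‖y − Xw − β₀‖²; WMMS(v) = wᵀv with
  the intercept excluded. Organised statsmodels-style:
  `WmmsModel(...).fit()` returns a `WmmsResults` with `weights`,
  `rsquared`, `summary()`.
* **Cohort statistics** — hypergeometric upper-tail region enrichment,
  phi correlation of parameters, pooled two-sample t-tests of severity
  separation, MMS/COS concordance, mutation surveys.
* **Docking-decoy rescoring** — re-ranks candidate H-protein/GLDC poses by
  mean interface conservation of each chain (4 Å interface cutoff) and
  lipoyllysine-to-tunnel distance, min–max normalized across the decoy set,
  with a constrained second round.
* **Synthetic data** — generators for annotation tables, cohorts with known
  linear ground truth, and decoy sets with a planted best pose, so every
  stage is testable offline.

The published clinical tables ship as fixtures (`glypheno.io.load_fixture`):
the two clinical cohorts with domain scores, the same cohorts with their
mutation scores, the ExAC/dbGaP healthy-control variant sets, and the
trained weight table.

## Worked example

```python
from glypheno import io, features, wmms
from glypheno.cohort import classify_severity, compute_cos, filter_cohort

# clinical cohorts -> COS and severity classes
records = list(io.fixture_cohort("table4_homozygous_cos")) + \
          list(io.fixture_cohort("table5_heterozygous_cos"))
eligible, excluded = filter_cohort(records)
classes = [classify_severity(compute_cos(r)) for r in eligible]
print(len(eligible), {c: classes.count(c) for c in set(classes)})
# 74 {'attenuated': 43, 'severe': 29, 'asymptomatic': 2}

# mutation scoring
ann = features.annotations_from_frame(io.load_fixture("annotations_examples"))
v = features.derive_parameter_vector(ann["R515S"])
print(features.mms_homozygous(v))            # 5.0
print([k for k, x in v.items() if x])
# ['destabilizing', 'cons_residue', 'c_term', 'd_charge', 'd_size']

# weighted scoring with the packaged trained weights
ws = io.load_weightsets()["homozygous_trained"]
print(round(wmms.wmms_score(v, ws), 2))      # 4.35
```

R515S — the most common severe NKH mutation — triggers five parameters
(destabilizing, conserved residue, C-terminal, charge change, volume
change), scoring MMS 5 (severe band, ≥5) and WMMS 4.35 under the
homozygous-trained weights; the mild T269M triggers only the polarity
change and scores WMMS −0.82.

The same flows are scriptable from the shell:

```sh
glypheno run --seed 1 --out out/           # COS -> MMS -> train -> predict -> stats
glypheno simulate --seed 7 --out sim/      # synthetic annotations, cohort, decoys
glypheno rank-models --decoys sim/decoys.pdb --conservation sim/conservation.tsv
```

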