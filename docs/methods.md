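# Methods

## Clinical outcome score (COS)

Four major symptomatic domains are scored on Likert-like scales: cognitive
disorders 0–3 (linear), muscle/movement control 0–3 (linear), seizures
{0, 1, 3} (a non-linear step from controlled to intractable seizure
activity), and brain malformation {0, 3} (a presence/absence binary scored
high because any structural malformation seriously impacts neurological
outcome). COS is the sum of the *scored* domains (maximum 12). A domain
reported asymptomatic scores 0; a domain not mentioned in a case report is
missing and contributes nothing — COS is deliberately **not** rescaled for
missing domains, so a patient scored 3/–/3/3 has COS 9. The package keeps
the two states distinct end to end (blank TSV cells, `None` in records).

Eligibility: deceased patients are removed first (death can follow a single
acute event unrelated to multi-domain severity), then records with fewer
than two scored domains. Severity classes default to asymptomatic (COS 0),
attenuated (1–5) and severe (>5). The attenuated/severe boundary is
genuinely ambiguous in the source material (stated variously as <5, ≤5 and
1–5); we default to attenuated = 1–5 and expose `attenuated_max` in
`classify_severity`. For MMS/COS concordance counting the low-COS class is
COS ≤ 5 — the only convention that reproduces all three published
concordance counts (14/16, 27/29, 2/21) — with the boundary configurable.

A 58-term symptom vocabulary maps free-text symptoms into eleven disease
categories by exact, case-folded lookup only; no fuzzy matching is
attempted, and unknown terms return `"unclassified"`.

## Multiparametric mutation score (MMS)

Eighteen binary parameters per missense variant, each with unit weight +1
except conservation-of-substitution (−1, since an evolutionarily tolerated
substitution argues against pathogenicity). Default thresholds, all
exposed in `FeatureConfig`:

| parameter | default trigger | rationale |
|---|---|---|
| destabilizing | ΔΔG < −1.5 kcal/mol | loss-of-function mutations average ≈ −1.7 kcal/mol |
| stabilizing | ΔΔG ≥ +1.5 | excess rigidity also impairs function |
| conserved residue | grade ≥ 7 of 9 | "highly conserved" on a Consurf-style scale |
| conserved substitution | BLOSUM62 ≥ 0 | calibrated so A→V (0) triggers while R→S and T→M (−1) do not |
| helix / sheet | assigned secondary structure | mutually exclusive with loop |
| C-terminus | position ≥ 506 | spans the catalytic C-terminal region while keeping R515 C-terminal |
| active site / 7 Å shell / N-PLP pocket / H-interface / dimer interface | region flags from the annotation table | the shell excludes the site itself |
| Δpolarity / Δcharge / Δaromaticity | class change | polar set {S,T,N,Q,Y,C,D,E,K,R,H}; positive {R,K,H}, negative {D,E}; aromatic {F,W,Y} |
| Δproline | ref or alt is P | backbone geometry |
| Δcodon availability | \|Δcodons\| ≥ 4 | keeps T269M (Δ3) non-triggering |
| Δsize | \|Δvolume\| ≥ 50 Å³ (Zamyatnin) | A→V (51.4) and R→S (84.4) trigger; T→M (46.8) does not |

Predicted ΔΔG is an *input* (an external structure-based predictor
produces it); the package only bins it: < −5 very destabilizing, −5..−1.5
destabilizing, −1.5..1.5 negligible (closed band), 1.5..5 stabilizing, > 5
very stabilizing.

Homozygous genotypes score the full vector. Compound heterozygotes score
0.5 per allele meeting each condition (1 if both, 0.5 if one, 0 if
neither); a non-missense allele contributes 0 to every missense parameter
and 0.5 to one of four class indicators (deletion, nonsense/frameshift,
intronic/splice, mitochondrial leader). Consequently the composite of two
missense alleles equals the mean of their homozygous scores — a property
the tests exercise on random annotations. Whether the 7 Å shell includes
active-site residues is unstated in the source; we implement it as
exclusive. MMS bands: <1 below-scale, 1–2 mild, 3–4 moderate, ≥5 severe.

Note that several printed heterozygous MMS values in the packaged
heterozygous score table are inconsistent with the stated 0.5-per-allele
rule; the stated rule is implemented, and that table is treated as a
verbatim fixture, not a recomputation target.

## Weight training (WMMS)

Weights are fitted by unregularized ordinary least squares of COS on the
parameter matrix. Homozygous training units are unique mutations with COS
averaged over carriers; heterozygous units are patients; healthy-control
variants enter as rows with COS 0. The intercept is fitted but **excluded**
from reported WMMS — with the packaged homozygous-trained weights, T269M
(which triggers only Δpolarity) scores exactly the bare Δpolarity
coefficient, −0.82, which would be impossible if an intercept were added.
R515S scores 4.35 from the same table's rounded weights (printed elsewhere
as 4.3; the discrepancy is rounding of the printed coefficients).

Columns that are identically zero in a design cannot be estimated; their
weight is pinned to 0 and recorded (`pinned_zero`). Rank-deficient designs
are solved by the minimum-norm least-squares solution and flagged rather
than failing. R² is the in-sample 1 − SS_res/SS_tot; no cross-validation
is performed, matching the train-and-evaluate-on-the-same-rows design this
package reproduces. Severity prediction uses a configurable WMMS cutpoint
defaulting to the midpoint of the attenuated and severe class means.

## Cohort statistics

Region enrichment uses the one-sided upper-tail hypergeometric probability
P(X ≥ k), observed count included, computed by exact `math.comb` summation
— the convention that reproduces the published census p-values
(0.08/0.22/0.12). The severity t-test is two-sided pooled-variance Student
by default (Welch by flag). Phi correlation binarizes composite 0.5
entries at > 0 and returns NaN with a warning for constant vectors. No
multiple-testing correction is applied anywhere; all p-values are raw.

## Docking-decoy rescoring

Interface residues are those with any atom within 4 Å of the partner chain
(KD-tree accelerated, identical to the all-pairs definition, verified
against an O(n²) oracle in tests). Conservation per chain is aggregated by
the mean over interface residues (median by flag). The distance parameter
is measured from a configurable ligand atom to the Cα centroid of a named
site residue set; the source names neither the exact lipoyllysine atom nor
the tunnel-entry residues, so both are configuration, and the published
round totals (2.84 and 2.81 of 3) are reference examples, not automated
assertions — they would require the original decoy sets and conservation
tables. Each parameter is min–max normalized over the decoy set; ties at
the extremes share 1.0/0.0; a constant parameter is dropped with a warning
rather than divided by zero; ranking is descending by total with ties
broken by model id. The constrained second round keeps models whose
mobile-chain centroid lies within a radius (default 20 Å) of the anchor's
and recomputes the normalization on the subset — "constrained to a region"
interpreted as centroid-within-radius.

## Synthetic data

`simulate_annotations` draws unique (position, ref, alt) substitutions over
a 1020-residue protein with disjoint region sets sized as in the real
census (active site 30, 7 Å shell 40, N-PLP pocket 20, H-interface 17,
dimer interface 30), ΔΔG from the five stability bins at proportions
42/63/96/35/15 of 251, uniform conservation grades, secondary structure at
35/25/40% helix/sheet/loop, and BLOSUM62 computed from the sampled pair.
`simulate_cohort` defaults to the clinical cohort's composition (74
patients, 24/74 homozygous, 32/50 heterozygotes with one non-missense
allele mixed 15:8:8:1 splice:deletion:nonsense:leader) and generates
COS* = clip(round(w*ᵀv + ε), 0, 12) with ε ~ N(0, σ²), σ = 1 by default.
Noise enters *before* rounding and clipping so recovery tests face the same
discretization the real scale imposes. The COS is decomposed into four
legal domain scores by a deterministic greedy fill (brain first when ≥3
remains, then seizures, cognitive, muscle) — a documented convention, not
clinically derived. The latent truth (weights, vectors, noise) is returned
as a sidecar.

The decoy generator places a 5-residue radial stalk (chain B) around a
60-residue spherical shell (chain A); the pose construction guarantees the
planted decoy strictly maximizes both conservation parameters and
minimizes the ligand–site distance, so rank-1 recovery is a construction
invariant, not a statistical outcome. Decoys are geometric toys: they do
not imitate real sequence content or stereochemistry.

### What passing tests do and do not show

The generators reproduce the *statistical shape* of the study — score
scales, censoring of domains, zygosity mix, stability mixture — not real
clinical heterogeneity (reporting bias, correlated symptoms, genetic
background) or real structure geometry. Parameter-recovery results
therefore bound estimator behaviour under the model's own assumptions
only.

### Recovery calibration

A 100-replicate pilot at the default conditions (n = 200, σ = 1, study
zygosity mix) gives per-coefficient absolute recovery errors with mean max
1.75 (95th percentile 3.4) over all identifiable coefficients, mean max
0.72 (p95 1.33) over well-populated (≥20-carrier) coefficients, and RMSE
mean 0.56 (p95 0.95, max 1.18). The dominant error source is ordinary
sampling variance: region parameters covering 17–30 of 1020 residues
appear in only a handful of patients, and the error is unchanged when the
latent (unrounded) response is fitted. The tests therefore assert exact
recovery on a truly linear response, RMSE < 1.0 and ≥20-carrier
per-coefficient error < 1.5 on a fixed-seed noisy cohort, and monotone
improvement of RMSE with cohort size. Per-coefficient recovery at ±0.3 is
not attainable under these conditions and is not asserted.

## Problem sizes

The packaged fixtures are desk-scale (24–50 rows). Synthetic analyses in
tests and the acceptance script use 251-mutation annotation tables,
200-patient cohorts (1000 for the sample-size monotonicity check, 8
replicates), 15–20-model decoy sets and 1000 random normalization sets —
sizes chosen to estimate each quantity stably while keeping the whole
suite under a minute of compute.

## Known limitations

* ΔΔG prediction, conservation computation, secondary-structure assignment,
  docking pose generation and homology modelling are all upstream inputs,
  not implemented here.
* Patient identifiers drift between the clinical-score and mutation-score
  fixtures in the source material; fixtures are kept verbatim per table and
  never merged across tables.
* The regression is in-sample by design; R² values are not generalization
  estimates.
* Non-missense alleles are scored by class indicator only; the position of
  a truncation (early vs late) is known to matter clinically but is not a
  parameter.
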