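# parkdx

Quantitative-MRI decision pipeline for the differential diagnosis of
early-stage parkinsonism: Parkinson's disease (PD) versus multiple system
atrophy (MSA) versus progressive supranuclear palsy (PSP).

Distinguishing these three syndromes is hardest exactly when it matters
most — early in the disease, when the clinical picture is still
"clinically unclassifiable parkinsonism". `parkdx` implements a
decision pipeline that combines up to eleven quantitative MRI biomarkers
per patient:

* **atrophy indices** from T1-weighted imaging — the Magnetic Resonance
  Parkinsonian Index `MRPI = (pons/midbrain) × (MCP/SCP width)`, its
  third-ventricle variant `MRPI2 = MRPI × (TV width / frontal-horn width)`,
  and the plain pons-to-midbrain ratio (all elevated in PSP);
* **iron-sensitive SWI signal** in putamen, subthalamic region and red
  nucleus, normalised to white matter (reduced in MSA and PSP);
* **fractional anisotropy** (DTI) in five posterior-fossa and basal-ganglia
  regions (stored on the ×1000 reporting scale).

The pipeline, aimed at neuroimaging statisticians and methods researchers, is:

1. **Screening** — a one-way ANOVA per biomarker across the three diagnosis
   groups, computable either from patient-level data or directly from
   per-group `(n, mean, sd)` summaries:
   `F = [Σ n_g(m_g − m̄)² / (k−1)] / [Σ (n_g−1)s_g² / (N−k)]`.
   Biomarkers with `p < α` (default 0.05) are retained; with the published
   group distributions this keeps the three atrophy and three SWI markers
   and drops all five FA markers.
2. **Classification** — Gaussian naive-Bayes posteriors
   `P(c|x) ∝ π_c Π_f N(x_f; μ_cf, σ_cf)` under two topologies:
   **model I**, a single three-class posterior over {PD, MSA, PSP}; and
   **model II**, a decision tree chaining a PSP-vs-rest stage (atrophy
   markers) with an MSA-vs-PD stage, via
   `P(PSP)=p₁, P(MSA)=(1−p₁)p₂, P(PD)=(1−p₁)(1−p₂)`.
3. **Evaluation** — one-vs-rest sensitivity/specificity/accuracy and a
   class-balanced bootstrap (default 25,000 iterations, 10 patients drawn
   with replacement per class) with 95 % confidence intervals and a
   running-mean convergence trace.

The study cohort behind the published group statistics is confidential, so
the package ships a synthetic-cohort generator whose per-group marginals
match the published means and SDs exactly (moment-matched positive-truncated
normals), at the published group sizes 38 PD / 25 MSA / 10 PSP.

## Worked example

```python
import parkdx as px

# 1. recompute the ANOVA table from published per-group summaries
results = px.screen_summaries(px.PUBLISHED_MARGINALS, px.DEFAULT_GROUP_SIZES)
r = results["mrpi"]
print(f"MRPI: F = {r.f_value:.3f} (df {r.df_between},{r.df_within}), p {r.p_display}")
selected = px.select_biomarkers(results, alpha=0.05)
print("retained biomarkers:", selected)

# 2. simulate a cohort at the published group sizes and classify it
cohort = px.simulate_cohort(px.published_cohort_spec(), seed=1)
table = px.classify_cohort(cohort, model_id="I", features=selected)
print(table.head(3).to_string(index=False))
print(f"model I resubstitution: {(table['predicted'] == table['true']).sum()}/73 correct")

# 3. class-balanced bootstrap with 95% confidence intervals
rep = px.bootstrap_evaluate(cohort, "I", iterations=25_000, seed=1,
                            features=selected)
print(px.evaluation_report([rep]).to_string(index=False))
```

prints

```
MRPI: F = 10.589 (df 2,70), p <10^-4
retained biomarkers: ['mrpi', 'mrpi2', 't1_pm_ratio', 'swi_put', 'swi_stn', 'swi_rn']
 patient_id true  MSA (%)  PD (%)  PSP (%) predicted model  correct
SYN-PD-0000   PD     4.74   58.39    36.86        PD     I     True
SYN-PD-0001   PD    22.69   77.30     0.00        PD     I     True
SYN-PD-0002   PD    10.02   89.97     0.00        PD     I     True
model I resubstitution: 59/73 correct
model      metric                  PD                 MSA                 PSP
    I sensitivity 0.946 (0.945-0.947) 0.781 (0.779-0.782) 0.905 (0.904-0.906)
    I specificity 0.890 (0.889-0.891) 0.945 (0.945-0.946) 0.981 (0.980-0.981)
    I    accuracy 0.909 (0.908-0.909) 0.890 (0.890-0.891) 0.956 (0.955-0.956)
```

The `F = 10.589` line reproduces the published MRPI row to the printed
precision; the selection drops every FA biomarker. The per-patient table is
the per-case posterior report (percentages, two decimals, prediction by
highest posterior). The bootstrap block shows each metric as
`mean (95% CI)`; PSP is the best-classified class — its atrophy pattern is
the most distinct — which is the qualitative structure the method exhibits
on real data too. Absolute synthetic-cohort metrics are higher than any
real-data figures because the generator draws independent Gaussian
biomarkers (see `docs/methods.md`).

A command-line interface mirrors the same steps
(`parkdx simulate | anova | classify | evaluate | outliers | run`); e.g.

```bash
parkdx simulate --seed 1 --out cohort.csv
parkdx anova --input cohort.csv --out anova.csv
parkdx run --config config.yaml   # full pipeline -> report bundle
```

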