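# preemiegut

Longitudinal analysis of preterm-infant gut microbiome succession and its
relationship to head-circumference growth (HCG), the earliest validated
marker of neurodevelopment.

Preterm infants in the NICU are sampled weekly; 16S count tables,
taxonomy, sample metadata and a clinical table go in, and the package
answers three linked questions:

1. **When does the microbiome change?** Infants are stratified into four
   ordered HCG groups by the loss in head-circumference z-score from
   birth to 36 weeks postmenstrual age (PMA): appropriate (loss <= 0.5),
   then mildly (<= 1), moderately (<= 1.5) and severely (> 1.5)
   suboptimal. Per taxon and group, weekly mean-abundance trajectories
   are segmented by PELT with a nonparametric empirical-distribution cost
   (ED-PELT), penalties chosen by an automated Lavielle elbow, and change
   points are tallied across taxa per PMA week — the week collecting the
   most change points is the key succession time point.
2. **Which taxa differ?** Per-rank CLR-transformed abundances
   (multiplicative-simple zero imputation) are modeled with linear mixed
   models (group + PMA fixed effects, patient random intercept; LS-mean
   differences with 95% CIs and Nakagawa marginal R^2), patient-level
   prevalence is compared with Fisher / Freeman–Halton exact tests,
   clinical characteristics with Welch's ANOVA and Games–Howell post hoc,
   all under Benjamini–Hochberg control. A random-forest cascade with
   response-permutation importance ("count out of 1001") screens and
   ranks microbiome vs clinical predictors of HCG trajectory.
3. **Does delivery mode act through the microbiome?** Cumulative-link
   (proportional-odds) mixed models of the ordered HCG outcome test the
   delivery-mode x moderator interaction (Wald, cluster-robust), with
   McFadden's R^2 and a Cohen's-D consistency screen within vaginally
   delivered infants.

Because the raw cohort data live in a sequence archive, the package
ships a first-class synthetic cohort generator (`preemiegut.synthetic`)
that reproduces the study's statistical skeleton — 58 patients in groups
of 28/16/8/6, weekly sampling with dropout over PMA 24–36,
Dirichlet-multinomial counts over a 4-phylum mock taxonomy, a -2
log-scale depletion of Bacteroidota and Lachnospiraceae planted at week
30 in the suboptimal-growth groups, Table-2-style clinical covariates,
and diverging z-score trajectories — so every stage is testable end to
end with known ground truth.

## Worked example

```python
import preemiegut as pg
from preemiegut.pipeline import run_succession, abundance_panel

cohort = pg.simulate_cohort(seed=7)   # 58 patients, 338 samples
out = run_succession(cohort.count_matrix, cohort.sample_records,
                     cohort.groups, rank="genus")
print(out.tally.counts)
print("key succession week:", out.tally.key_week)
```

prints the per-week change-point tally at the genus rank:

```
24     0
25     1
26     0
27     3
28     2
29     5
30    18
31     1
32     2
33     2
34     0
35     0
36     0
key succession week: 30
```

18 of the 34 change points across the 13 PMA-varying genera land on week
30 — the generator's planted succession week, recovered as the tally
argmax. The late-window (31–36) phylum contrast panel on the same cohort:

```python
panel = abundance_panel(cohort.count_matrix, cohort.sample_records,
                        cohort.groups, "phylum", window="late")
print(panel[panel.significant])
```

```
           taxon  ls_mean_diff  ci_low  ci_high   q
    Bacteroidota        -1.364  -1.591   -1.137 0.0
Actinobacteriota         0.744   0.538    0.950 0.0
  Proteobacteria         0.814   0.653    0.975 0.0
```

Bacteroidota is depleted in suboptimal-growth infants (LS-mean CLR
difference -1.36, 95% CI [-1.59, -1.14]); the positive entries are the
compositional counterweight (CLR values per sample sum to zero, so a
planted depletion must surface elsewhere as enrichment).

A thin CLI mirrors the pipeline stages:

```bash
preemiegut simulate --seed 7 --outdir demo
preemiegut changepoint --counts demo/counts.tsv --taxonomy demo/taxonomy.tsv \
    --metadata demo/metadata.tsv --clinical demo/clinical.tsv \
    --outdir demo/out --rank genus
# -> key succession week at genus rank: 30
```

Subcommands: `simulate`, `preprocess`, `stats`, `changepoint`, `rf`,
`moderate`.

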