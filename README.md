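# matemeta

Phylogenetically controlled multilevel meta-analysis of **state-dependent
mate choice**: how strongly an animal's choosiness during mating depends on
its own state — age, attractiveness, body size, physical condition, mating
status, or parasite load — synthesized across studies and species.

The package is aimed at behavioural ecologists and meta-analysts who have an
effect-size table (one row per extracted correlation, with raw statistics,
sample sizes, moderators and direction metadata) and a species supertree,
and want the full analysis pipeline with every stage testable against
simulated ground truth.

## The model

Each result is converted to a correlation *r* (from a reported r, a
two-group test statistic, group means ± SD via Hedges' d, or a 2×2
choice-frequency table via phi), sign-coded so that *r* > 0 means "choosier
in the high-state condition" (young / attractive / large / good condition /
mated / few parasites), and transformed to Fisher's Z with sampling variance
1/(n − 3). Effects are then modelled as

    zr_i = β0 + a_species(i) + s_species(i) + u_study(i) + e_i + m_i

with phylogenetic effects `a ~ N(0, σ²_phylo A)` (A the Brownian correlation
matrix of the Grafen-calibrated tree), independent species, study and
observation effects, and known sampling error `m_i ~ N(0, v_i)`. Variance
components are estimated by REML; summaries are back-transformed to the
correlation scale. The pipeline also provides the multilevel I² partition,
95% prediction intervals, categorical moderator meta-regressions (QM tests,
marginal R², per-level means, Holm post hocs) and publication-bias models
(time trend, Egger-type small-study test, covariate-adjusted mean).

Nonsignificant results published without a direction are coded as zeros
("directionless" points); every analysis can run on the full dataset or on a
reduced one excluding them.

See `docs/methods.md` for formulas, defaults, numerical choices and known
limitations.

## Worked example

Simulate a study set and fit the intercept-only model:

```bash
cat > cfg.yaml <<EOF
n_species: 15
n_studies: 40
effects_per_study: 2
censor_prob: 0.25
seed: 42
EOF
matemeta simulate --config cfg.yaml --out example
matemeta fit --data example/effects.csv --tree example/tree.nwk \
             --out example/fit.json
```

which prints

```json
{
  "k": 80,
  "variant": "full",
  "mean_r": 0.1381765638117008,
  "ci_r": [-0.0834915227597138, 0.3468149668499995],
  "pi_r": [-0.5205205245034741, 0.6937689494731486],
  "sigma2": {
    "phylogeny": 0.03408077200934914,
    "species": 0.014247241942171437,
    "study": 0.0186958570067853,
    "observation": 0.053557569748332846
  },
  "reml_loglik": 46.33370068926056,
  "heterogeneity": {
    "sigma2_m": 0.017765394612576365,
    "i2_total": 87.15879942494867,
    "i2_by_level": {
      "phylogeny": 24.634298233647876,
      "species": 10.29820588905992,
      "study": 13.51375834774055,
      "observation": 38.71253695450032
    }
  }
}
```

Reading: across the 80 simulated effects the mean state–choosiness
correlation is r ≈ 0.14, its 95% CI spans zero, and the 95% prediction
interval (−0.52, 0.69) says individual studies vary widely. Total I² ≈ 87%
of variance is heterogeneity rather than sampling error, split across the
four levels as shown. `matemeta moderators --moderator state_factor ...`
and `matemeta bias ...` run the meta-regression and publication-bias stages
on the same files; `--variant reduced` drops the directionless zeros.

The same pipeline runs on real data: point `--data` at a CSV following the
documented schema (`matemeta.data_io.CSV_COLUMNS`) and `--tree` at a Newick
supertree whose tips cover the species column.

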