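# sexarch

Estimation of sex-specific genetic architecture from knockout-phenotyping
panels: the between-sex genetic correlation of knockout effects (rfmK),
sexual dimorphism (SD), and sexually discordant genotype effects.

## The problem

Large mouse knockout programs phenotype every line in both sexes — typically
seven females and seven males per genotype — under standardized conditions.
Treating each knockout genotype's effect on a trait as a pair of sex-specific
effects `(u_f, u_m)` turns such a panel into an estimate of how far males and
females share the genetic architecture of that trait:

- if knockouts move both sexes alike, the correlation of `(u_f, u_m)` across
  genotypes (**rfmK**) is near 1;
- sex-limited or opposing effects pull it toward 0.

`sexarch` implements that inference as a reusable pipeline, with a synthetic
panel generator standing in for consortium data so that every stage can be
verified by parameter recovery at desk scale.

## The model

Per trait, each animal's (standardized, optionally power-transformed)
phenotype is modelled as

```
y_i ~ N( mu + beta_sex * male_i + beta_mass * mass_i
         + u[sex_i, genotype_i] + c[center_i] + g[meta_group_i] + d[date_i],
         sigma^2 )

(u_f, u_m)_j ~ N2( 0, G ),   G = [ sigma_f^2            rho sigma_f sigma_m ]
                                 [ rho sigma_f sigma_m  sigma_m^2           ]
```

i.e. `phenotype ~ mass + sex + (0 + sex | genotype) + (1 | center) +
(1 | meta_group) + (1 | date)` with weakly informative priors — N(0,1) on the
intercept, N(0,2) on the fixed effects, half-Student-t(5,1) on all standard
deviations and an LKJ(1) (uniform) prior on `rho`. The correlation `rho` *is*
rfmK. Posterior sampling uses a blocked Metropolis-within-Gibbs scheme with
collapsed updates for `G` (see `docs/methods.md`).

From the joint posterior the pipeline derives, per trait:

- **rfmK** and its Fisher z-transform `atanh(rho)`;
- the ratio of sex-specific genetic variances (ordered and male/female);
- the Riemannian distance of the scaled G matrix from the
  perfect-correlation null `[[1,1],[1,1]]` (ε-regularized);
- the **SD index** — larger-sex wild-type mean over smaller-sex mean, minus 1,
  on the original measurement scale — classified against a region of
  practical equivalence (ROPE, default [0, 0.05]) as
  dimorphic / monomorphic / unclassified;

plus a second-stage regression of each measure on the SD index that
propagates trait-level posterior uncertainty (500 resampled datasets, pooled
chains), and a cross-trait ranking of genotypes on the concordant
(`|u_f + u_m|/√2`) and discordant (`|u_f − u_m|/√2`) axes.

## Worked example

Simulate a 150-genotype panel whose true correlation is 0.65 and whose
wild-type means are 10 (female) and 11 (male) — a true SD index of 0.10 —
then fit it:

```sh
sexarch simulate --config sim.yaml --seed 42 --out panel/
#   sim.yaml:  n_genotypes: 150
#              intercept: 10.0
#              beta_sex: 1.0
sexarch fit --input panel/sim_trait.csv --config fit.yaml \
            --no-transform --out results/
#   fit.yaml:  seed: 1
```

which prints

```
rfmK median 0.683 95% CI (0.5405964139959525, 0.7832853709286085)
ROPE class: dimorphic
```

The posterior median of rfmK (0.683) brackets the generating value 0.65
within its 95% credible interval, and the trait is correctly classified as
dimorphic (its true 10% male–female difference exceeds the 5% ROPE bound).
`results/summaries.csv` carries the full set of derived measures with
50/80/95% intervals; `results/draws/` holds the posterior draws the
meta-regression (`sexarch meta`) and genotype ranking (`sexarch ranks`)
consume.

The same machinery is available as a library:

```python
from sexarch.core_data import AnalysisConfig
from sexarch.pipeline import analyze_trait
from sexarch.synthetic_data import SimulationConfig, simulate_trait

data, truth = simulate_trait(SimulationConfig(seed=42))
res = analyze_trait(data, AnalysisConfig(seed=1).desk_scale())
print(res.summaries.rfmk.median, res.summaries.rope_class)
```

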