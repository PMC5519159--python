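# seedwaste

Quantifying **wasted seed dispersal** under climate change: when a
long-distance frugivore (here, migrating Galapagos tortoises) carries
viable seeds of invasive plants (guava, passion fruit) into habitat
where those plants cannot survive — and how that waste turns into an
invasion subsidy as climate change moves the habitat toward the seeds.

The package is aimed at dispersal ecologists and invasion biologists.
It implements the full analysis chain as a reusable library:

* a **presence–background maximum-entropy suitability model** (Maxent-type)
  written from first principles, with L1-regularised fitting, raw and
  logistic outputs, jackknife predictor selection, bootstrap ensembles
  and held-out AUC evaluation;
* **survival limits** estimated from vegetation-plot occupancy (the
  minimum modelled suitability at which living plants occur) and the
  **wasted-dispersal classifier** for dung-pile seed loads;
* **range-change accounting** between binarized current and future
  suitability maps (cells gained / lost / stable);
* a **binomial occupancy GLM** (IRLS) with the **Hosmer–Lemeshow**
  goodness-of-fit test;
* **seed-flux and suitability-front projections** (seeds per year
  redirected into suitable habitat; metres per generation needed to
  keep pace with the advancing front);
* a **synthetic volcanic island generator** that produces elevation-driven
  climate layers, scenario perturbations, a known true suitability
  function and survey data (occurrences, plots, dung piles), so every
  stage is testable by parameter recovery without any external rasters.

## The model

The suitability model maximises the entropy of a distribution $q$ over
background cells subject to matching the feature means observed at
presence sites; equivalently it minimises the convex objective

$$f(\lambda) = -\tfrac{1}{m}\sum_{i\in\text{presence}} \lambda^\top f(x_i) + \log\!\!\sum_{x\in\text{background}}\!\! e^{\lambda^\top f(x)} + \sum_j \beta_j|\lambda_j|$$

with per-feature rates $\beta_j = \sqrt{s_j^2/m}$. The raw output is
$q(x)=e^{\lambda^\top f(x) - \log Z}$; the logistic output
$L(x) = e^{H}q(x)/(1+e^{H}q(x))$, with $H$ the entropy of $q$, rescales
to $[0,1]$. A dung pile containing seeds of species $s$ at location $x$
is a **wasted dispersal event** iff $L(x) < \ell_s$, where the survival
limit $\ell_s$ is the minimum of $L$ over plots occupied by $s$.

## Worked example

`python examples/04_climate_scenarios.py` runs the full pipeline on the
demo island (two species, two scenarios) and prints:

```
wasted seed percentage per scenario:
  guava         current   50 piles below limit,  48.4% of seeds wasted
  guava         wet2050   23 piles below limit,  18.7% of seeds wasted
  guava         wet2070    0 piles below limit,   0.0% of seeds wasted
  passionfruit  current   60 piles below limit,  69.1% of seeds wasted
  passionfruit  wet2050   83 piles below limit, 100.0% of seeds wasted
  passionfruit  wet2070   83 piles below limit, 100.0% of seeds wasted
```

The precipitation-limited species (guava-like) sees its wasted fraction
collapse as lowland wetting moves suitable habitat down toward where
the tortoises already deposit seeds; the cool-adapted species
(passionfruit-like) loses mid-elevation habitat to warming, so more of
its dispersal becomes wasted. `python examples/05_flux_and_front.py`
turns a 6-point drop in the wasted fraction into the invasion subsidy:

```
extra seeds landing in suitable habitat: 149,760/day = 54.7 million/year
suitability front advances 27 m/year; a plant must disperse 218 m per generation to keep pace
```

Each `examples/0*.py` script is a short, self-contained narrative for
one capability (island generation, model fitting, wasted-dispersal
classification, scenario projection, flux/front arithmetic).

A thin CLI mirrors the library (`seedwaste simulate|fit|select|project|
range-change|wasted|glm|flux|front|run`); `seedwaste run --demo
--out-dir out/` writes the full report bundle with a provenance
manifest. Outputs are plain text: ESRI ASCII grids for rasters, CSV for
tables, JSON for reports, and every run is byte-for-byte reproducible
from its seed.

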