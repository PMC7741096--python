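# paleodem

Radiocarbon-based palaeodemography for regional hunter–gatherer records:
from raw determinations (terrestrial, marine, and mixed-diet human samples)
to relative population proxies and what they correlate with.

Archaeological radiocarbon dates, treated carefully, are a population proxy:
more people leave more datable material.  `paleodem` implements the full
analysis chain a regional case study needs:

* **Calibration** against atmospheric and marine curves, including per-sample
  curve mixing for humans with partially marine diets
  (mu_mix = (1−F)·mu_atm + F·(mu_mar + ΔR), errors in quadrature);
* **Screening and site-phase binning** — complete-linkage clustering of each
  site's dates at a 30-yr (intergenerational) cut, one random representative
  per phase, so heavily dated sites do not dominate;
* **Summed probability densities (SPD)** with the Surovell power-law
  taphonomic correction for open-air sites and bootstrap confidence
  envelopes;
* **Exponential null-model testing** — fit A·exp(r·(t0−t)), simulate its SPD
  sampling distribution by back-calibration, flag spans where the two 95.4%
  bands are disjoint, and report Monte Carlo and Gaussian-tail global
  p-values;
* **Bootstrapped Gaussian KDE population models** (150-yr bandwidth) and the
  continuous annualized growth rate r(t) = −d log K/dτ (% per annum),
  with growth-phase descriptors (start, maximum rate, population maximum)
  reported as mean ± sd over bootstrap replicates;
* **Settlement-density time series** — mean pairwise inter-site distance in
  sliding 500-yr windows stepped at 50 yr, with a LOESS trend;
* **Proxy correlation** — Spearman's rho between the population proxy and
  environmental series (SST, ice-core isotopes), overall and windowed;
* **Monte Carlo LOESS palaeodietary trends** — d13C of human individuals
  regressed on calibrated age, repeated over draws from each individual's
  calibrated density so the trend carries dating uncertainty;
* **A synthetic-data generator** with known ground truth (piecewise-
  exponential population curve, taphonomic thinning, site clustering
  schedules, dietary ramp, linked proxy), so the whole pipeline is testable
  without any external data.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

Generate a synthetic record whose truth has a stadial crash and two Holocene
booms (maximum growth 0.40 %/yr from 10300 cal BP, 0.25 %/yr from 8700), and
recover the growth phases:

```python
import pathlib, tempfile
from paleodem import (PopulationScenario, make_dataset, read_dates, screen,
                      cal_medians, bin_phases, index_dates, kde_model,
                      growth_rate, extract_phases)
from paleodem.kdegrowth import reliability_floor

tmp = pathlib.Path(tempfile.mkdtemp())
scn = PopulationScenario(seed=42)
ds = make_dataset(scn, outdir=tmp)        # dates.csv, isotopes.csv, proxy.csv, curves

dates = read_dates(tmp / "dates.csv")
kept = screen(dates)                      # drops large-error / insecure dates
med = cal_medians(kept, ds.atm, ds.mar)
bins = bin_phases(kept, ds.atm, ds.mar, h=30, seed=42, medians=med)
print(f"{len(dates)} dates -> {len(kept)} screened -> {len(bins)} site phases")

kde = kde_model(bins, index_dates(dates), ds.atm, ds.mar,
                bandwidth=150, n_boot=200, seed=42)
growth = growth_rate(kde, floor=reliability_floor(len(bins), 150))
for p in extract_phases(growth, min_phase_span=200):
    if p.support < 0.9:
        continue
    print(f"growth phase: start {p.start:.0f}±{p.start_sd:.0f} cal BP, "
          f"max {p.max_rate:.2f}±{p.max_rate_sd:.2f} %/yr, "
          f"population maximum {p.t_pop_max:.0f}±{p.t_pop_max_sd:.0f} cal BP")
```

prints

```
315 dates -> 300 screened -> 260 site phases
growth phase: start 13721±126 cal BP, max 0.57±0.16 %/yr, population maximum 13133±184 cal BP
growth phase: start 10467±186 cal BP, max 0.40±0.12 %/yr, population maximum 9593±212 cal BP
growth phase: start 8635±95 cal BP, max 0.30±0.09 %/yr, population maximum 7889±111 cal BP
```

The two injected booms come back with their starts within ~170 yr and their
maximum rates within ~0.05 %/yr of truth; the first (interstadial) phase is
real but sits in the sparse end of the record, hence its larger rate
uncertainty.  The ± values are standard deviations across the 200 bootstrap
replicates.

## Command line

The same pipeline runs from a YAML config:

```yaml
# config.yaml
seed: 42
metric: projected_euclidean
paths: {outdir: out}
parameters: {n_boot: 500, n_mc: 500}
scenario: {n_dates: 300}      # present -> `simulate` generates the inputs
```

```sh
paleodem -c config.yaml -v all        # or: simulate calibrate bin spd testexp
                                      #     kde growth spatial corr diet
```

Each stage writes CSV/JSON artifacts, diagnostic figures, and a manifest
(config echo, seed, versions, input checksums) under `out/`.  To analyse real
data instead, point `paths:` at your `.14c` curve files and date/isotope/
proxy CSVs and omit `scenario:`.

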