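# switchfit

Decomposition of bimodal trait distributions into lean/heavy sub-populations,
penetrance ("on-rate") estimation, and marker-gene stratification of
expression cohorts.

## The problem

Some traits do not vary smoothly: isogenic mouse lines carrying
haploinsufficient chromatin-regulator or imprinted-gene alleles (Trim28,
Nnat, Peg3) emerge into adulthood as either normal or obese with few
intermediates, and childhood BMI surveys show the same signature — a
dominant lean mode plus a distinct heavier sub-population, rather than a
single drifting Gaussian.  The natural model is a two-component Gaussian
mixture

&nbsp;&nbsp;&nbsp;&nbsp;f(x) = (1 − π)·N(x; μ₁, σ₁²) + π·N(x; μ₂, σ₂²),&nbsp;&nbsp;μ₁ < μ₂,

where π is the *on-rate* — the penetrance of the heavy state — and
100·(μ₂ − μ₁)/μ₁ the percent effect size.  `switchfit` fits this model the
way phenotyping studies present it: nonlinear least squares of one or two
Gaussian curves to a frequency histogram, scored by R², with a raw-sample
maximum-likelihood EM fit as cross-check and model-comparison evidence
(AIC/BIC).  On the expression side it implements multi-housekeeping
2^−ΔΔCt quantification, a TRIM28-style median split into Marker_High/Low
strata, imprinted-gene-panel contrasts, and top-variable-gene PCA /
correlation / clustering summaries of sample structure.

Because the motivating datasets are clinical surveys and animal colonies,
the package ships a synthetic-data module that generates trait cohorts and
expression matrices with the same statistical structure (and known ground
truth), so every stage is testable end to end.

## Worked example

```python
import switchfit as sf

cohort = sf.simulate_cohort(sf.get_preset("nnat", n=5000), seed=1)
values = cohort["trait"].to_numpy()
binned = sf.bin_trait(values, bin_width=1.0)
report = sf.summarize(sf.fit_double_gaussian(binned),
                      sf.fit_single_gaussian(binned), binned, values)
print(f"on-rate {report.on_rate:.3f}, effect {report.effect_size_pct:.1f}%")
```

Running `python examples/fit_bimodal_cohort.py` prints:

```
single-Gaussian R^2 : 0.855
double-Gaussian R^2 : 0.997
preferred model     : k=2
on-rate (penetrance): 0.255   (generating value 0.26)
effect size         : 40.5%  (generating value 40%)
individuals classed heavy: 1263/5000
```

The double Gaussian explains the histogram (R² = 0.997) where the single
Gaussian cannot; the recovered mixing fraction and mean gap match the
generating 26% on-rate and 40% body-weight effect within sampling error;
and 1263 individuals sit above the 0.5 posterior threshold for the heavy
component.  The other scripts in `examples/` walk through the era
comparison (lean mode nearly static while the heavy fraction triples),
expression stratification (panel suppression visible only in marker-low
obese samples; transcriptome clusters following the marker, not
adiposity), and bin-width sensitivity (coarse bins masking bimodality).

A thin CLI mirrors the library:
`switchfit simulate|fit|report|stratify|era-compare|bin-scan --help`.

## Layout

- `src/switchfit/scenarios.py` — scenario types and the preset registry
- `src/switchfit/simulate.py` — cohort / expression generators
- `src/switchfit/mixfit.py` — binning, curve fits, EM, bootstrap
- `src/switchfit/polyphenism.py` — on-rate, effect size, model comparison,
  classification, tail outliers, era shifts, bin-width scans
- `src/switchfit/expression.py` — ΔΔCt, marker split, panel contrasts, PCA
- `src/switchfit/io.py`, `cli.py` — readers/writers, pipeline, CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
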