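# raygrowth

Age-and-growth estimation for elasmobranchs in data-poor situations,
built around the multi-analytical workflow used for tropical stingrays:
vertebral band-pair ages plus disc-width measurements, analysed in three
steps — Ford–Walford starting values, nonlinear least-squares comparison of
four growth models ranked by bias-corrected AIC, and Bayesian estimation of
the two-parameter von Bertalanffy growth function under informative priors.
It is aimed at fisheries scientists working with small samples (tens of
animals) of rare, protected, or hard-to-catch species, where ordinary
nonlinear regression alone gives unstable growth parameters.

## The model

Size at age is disc width \(W_D\) (cm). The package fits four curves:

| model | mean function |
|---|---|
| VBGF | \(W_D(t) = W_{D\infty}\,[1 - e^{-k(t-t_0)}]\) |
| 2VBGF | \(W_D(t) = W_{D\infty}\,(1 - b\,e^{-kt})\), \(b = (W_{D\infty}-W_{D0})/W_{D\infty}\) |
| logistic | \(W_D(t) = W_{D\infty} W_{D0} e^{kt} / [W_{D\infty} + W_{D0}(e^{kt}-1)]\) |
| Gompertz | \(W_D(t) = W_{D\infty}\exp[\ln(W_{D0}/W_{D\infty})\,e^{-kt}]\) |

where \(W_{D\infty}\) is asymptotic disc width, \(k\) the growth
coefficient (yr⁻¹), \(t_0\) the theoretical age at zero size, and
\(W_{D0}\) disc width at birth. The 2VBGF fixes \(W_{D0}\) (size at birth is
generally well documented for rays) and estimates only \((W_{D\infty}, k)\).

Models are compared by the least-squares AICc,
\(n\ln(\mathrm{RSS}/n) + 2p + 2p(p+1)/(n-p-1)\), with \(\Delta \le 2\)
denoting highest support. The AICc-preferred 2VBGF is then re-fitted in a
Bayesian framework with a Gaussian likelihood and informative priors pooled
from published dasyatid studies — lognormal \(W_{D\infty}\) with
natural-scale mean 77 cm and log-sd 0.5, \(k \sim \mathrm{Beta}(21.9,
162.3)\), \(\sigma^2 \sim \mathrm{InvGamma}(0.01, 0.01)\) — sampled by
random-walk Metropolis–Hastings (reference chain 2 M iterations, 100 k
burn-in, thinning 100; a 200k/20k/20 desk preset gives near-identical
summaries). Convergence is monitored with the Geweke diagnostic.

Ageing precision between blind readers is summarised by the
Beamish–Fournier index of average percent error (IAPE) and the Chang
percent coefficient of variation (CV), with two-or-more-reader consensus
ages and exclusion of unreadable (score 3) vertebrae.

A synthetic-data module generates size-at-age samples and reader matrices
with this statistical structure (including four built-in species presets
and the well-represented 20 × 10 design with data-poor subsampling), and a
simulation-study module compares NLS and Bayesian estimators on them.

## Worked example

```sh
python examples/03_bayesian_fit.py
```

```
n = 34 records, 9000 retained draws, acceptance 29%
   w_inf: median  44.221 cm    95% CI (42.857, 46.714)  Geweke z +1.17
       k: median   0.271 yr^-1 95% CI (0.212, 0.321)  Geweke z -1.01
  sigma2: median   3.452 cm^2  95% CI (1.889, 7.393)  Geweke z +1.00
```

The sample was generated at \(W_{D\infty} = 42\) cm, \(k = 0.38\) yr⁻¹ with
\(n = 34\): the posterior pins the asymptotic size near the truth, while
the \(k\) median sits between the generating value and the prior's centre
(≈0.12) — the informative-prior shrinkage that stabilises data-poor fits.
With a few hundred records the data dominate and both medians recover the
generating values (see `examples/05_data_poor_comparison.py` for the
replicated NLS-vs-Bayes comparison). The other examples cover the growth
curves, AICc model selection, reader precision and the end-to-end
workflow; a thin CLI (`raygrowth --help`) wraps the same functions for
shell use.

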