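# idpre

**PRE-driven maximum-entropy refinement and analysis of fuzzy-complex
conformational ensembles.**

Intrinsically disordered proteins (IDPs) often bind folded partners without
fully ordering, forming *fuzzy complexes* in which short anchor motifs dock at
defined sites while the rest of the chain remains a dynamic cloud.  Ensemble
models of such complexes — for example from molecular dynamics — typically
disagree in detail with solution NMR.  `idpre` implements the integrative
analysis that reconciles them: paramagnetic relaxation enhancement (PRE) data
are back-calculated from each ensemble member, the ensemble is reweighted by
Bayesian maximum entropy (BME) to match experiment, and the refined weights
drive every downstream statistic — state populations, conformational-landscape
clusters, contact maps, residue-wise conformational entropy, and radii of
gyration.  A synthetic-data module generates multi-state ensembles with known
ground truth so the whole chain of inference is testable end to end.

The package is aimed at structural biologists and ensemble modellers working
on IDP complexes at the desk scale: everything runs on one CPU in minutes.

## The model

**PRE back-calculation** (per frame, per spin-label site): the paramagnetic
rate for a backbone amide proton is

$$\Gamma_2 = \frac{1}{15}\Big(\frac{\mu_0}{4\pi}\Big)^2 \gamma_I^2 g^2 \mu_B^2\, S_e(S_e{+}1)\,\big[4J(0) + 3J(\omega_I)\big]$$

with spectral density
$J(\omega) = \langle r^{-6}\rangle\big[S^2\tau_c/(1+\omega^2\tau_c^2) + (1-S^2)\tau_t/(1+\omega^2\tau_t^2)\big]$,
where $r$ is the electron–proton distance averaged over Boltzmann-weighted
spin-label rotamers and $S^2 = S^2_\text{radial}S^2_\text{angular}$ is the
generalized order parameter of the electron position
($S^2_\text{radial} = \langle r^{-3}\rangle^2/\langle r^{-6}\rangle$).
Ensemble averaging is $\Gamma_{2,i} = \sum_j w_j\,\Gamma_{2,i,j}$, and HSQC
intensity ratios follow
$I_\text{ox}/I_\text{red} = R_{2,\text{red}}\,e^{-\Gamma_2 t_d}/(R_{2,\text{red}}+\Gamma_2)$.
Defaults: $\tau_c = 29$ ns (from the 0.6 ns/kDa rule at 47.8 kDa),
$\tau_i = 500$ ps, $t_d = 10$ ms, $R_{2,\text{red}} = 40\,\mathrm{s^{-1}}$,
600 MHz.  Experimental ratios are LOESS-smoothed (span 0.2), inverted, and
truncated at $\Gamma_2 = 450\,\mathrm{s^{-1}}$ where the relation flattens.

**BME reweighting**: refined frame weights take the exponential-family form
$w_j = \tfrac{1}{Z}\,w_j^0\exp(-\sum_i \lambda_i \Gamma_{2,i,j})$, with
$\lambda$ minimizing the convex dual
$C(\lambda) = \log Z(\lambda) + \sum_i\lambda_i\Gamma_{2,i}^{exp} + \tfrac{\theta}{2}\sum_i\lambda_i^2\sigma_i^2$.
The parameter $\theta$ trades fit quality ($\chi^2$) against closeness to the
prior; it is scanned on a decreasing log grid and selected by an elbow rule.
Error variances vary inversely with the observed intensity ratio.

**Downstream analyses** all consume the refined weights: segment-distance
features (2775 for a 311-residue chain) → top-50 PCA → UMAP (trained on a 10%
subsample) → Louvain clusters with weighted contributions; weighted contact
frequency maps and state-specific contacts; torsion entropy
$S = -[\sum_i P_i\ln(P_i h) + (n{-}1)/2N]$ over 35 bins, converted to energy
with $RT$ at 310 K; and per-motif $K_d$ from the quadratic single-site
depletion isotherm.

## Worked example

`examples/03_bme_reweighting.py` generates a four-state synthetic complex
with ground-truth state populations 0.4/0.3/0.2/0.1, synthesizes PRE tables
from four receptor spin labels with 5% noise, and reweights:

```
1244 PRE rows from 4 sites, 0 capped at 450.0/s
theta scan (theta, chi2):
       1e+03      5.1969
         316      4.6813 <- selected
         100      4.5875
        31.6      4.5742
        ...
state contributions (recovered vs truth):
    I: 0.314 vs 0.400
   II: 0.250 vs 0.300
  III: 0.257 vs 0.200
   IV: 0.180 vs 0.100
```

The elbow rule picks the largest θ beyond which χ² stops improving; at 150
frames per state and 5% noise the recovered populations shrink toward the
uniform prior but preserve the ordering.  With zero noise and 2000 frames per
state the populations are recovered to within ±0.011 (see the acceptance
script below).  The other examples cover ensemble generation (`01`), PRE
forward calculation (`02`), landscape clustering (`04`), contact analysis
(`05`), entropy (`06`), titration $K_d$ fitting (`07` — zero-noise recovery
is exact: 17.0/7.0/13.0 μM), and the one-call pipeline (`08`).

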