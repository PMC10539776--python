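# fadcidnp

Spin-dynamics modelling and relaxometry analysis for the light-induced
flavin–adenine biradical of FAD (flavin adenine dinucleotide).

## The problem

Blue-light excitation of the flavin moiety of FAD drives intramolecular
electron transfer from the adenine moiety, creating a short-lived,
spin-correlated triplet biradical F•⁻–A•⁺ whose two radical centres are
tethered by the ribityl phosphate linker. Spin-selective recombination of
this biradical generates chemically induced dynamic nuclear polarization
(CIDNP): non-Boltzmann nuclear polarization detectable by NMR in the
diamagnetic product. The dependence of CIDNP on the magnetic field in which
it is generated encodes the electron exchange interaction J(r) — and,
because J decays steeply with the inter-radical distance r, the end-to-end
distance distribution of the biradical.

Two experimental complications shape the analysis. First, polarization is
generated at a low field but detected at high field after mechanically
shuttling the sample through the magnet's fringe field; for fast-relaxing
protons a large fraction of the polarization is lost in transit and must be
restored by deconvolution with field-dependent relaxation rates R₁(B).
Second, those rates come from a separate fast-field-cycling experiment:
site-specific nuclear magnetic relaxation dispersion (NMRD), which also
yields per-proton rotational correlation times and thereby reports on the
rigidity of the FAD conformation.

This package implements the full analysis chain as a reusable, tested
library, with a synthetic-data layer standing in for the spectrometer:

1. **`spin_sim`** — distance-resolved stochastic-Liouville simulation of the
   geminate CIDNP field dependence (the core model, see below);
2. **`distributions`** — candidate end-to-end distance distributions
   (normal, left-half normal, truncated normal) on a radial grid;
3. **`nmrd_fit`** — inversion-recovery T₁ extraction and Lorentzian
   dispersion fitting, 1/T₁(B) = R₁/(1 + (γ_H B τ_c)²) + R₁∞;
4. **`shuttle_deconv`** — transfer-relaxation correction
   P_true = P_obs · ∏ₙ exp(Rₙ Δtₙ) over a 500-interval split of the shuttle
   field–time profile;
5. **`model_compare`** — the q statistic (sum of squared deviations between
   normalized simulated and observed curves) and distribution ranking;
6. **`synthetic_data`** — seeded generators for decay series, shuttle
   profiles and noisy observed CIDNP curves;
7. **`io_tables` / `cli`** — tab-separated text I/O and an umbrella
   command line (`fadcidnp simulate-cidnp`, `fit-nmrd`, `deconvolve`,
   `compare`, `synth`, `run-all`).

## The model

The biradical state is described by a density matrix ρ(r) resolved on a
radial grid of end-to-end distances. Its evolution couples

* coherent spin dynamics: electron Zeeman terms (g_a, g_b), the full
  isotropic hyperfine coupling A **I**·**S**_a of the observed nucleus,
  the couplings of n additional equivalent nuclei to the second electron,
  and the exchange term H_ex = −J(r)(½ + 2**S**_a·**S**_b);
* electron spin relaxation from fluctuating local fields with a Lorentzian
  spectral density (correlation times for fast internal motion and overall
  tumbling);
* radial diffusion over the distance distribution (a discrete Smoluchowski
  generator with the equilibrium distribution as stationary state);
* singlet-projected recombination (rate k_p) at contact and uniform
  scavenging (k_s).

With negative J the singlet lies below the triplet and the S/T₋ levels
cross where the electron Zeeman energy equals 2|J(r)|; hyperfine flip-flop
terms turn the crossing into an anti-crossing that converts T₋ population
into singlet while flipping the nucleus — the "J resonance". Swept across
the distance distribution, these crossings produce a single emissive CIDNP
maximum whose position reports the effective exchange (B* ≈ 2|J_eff|) and
whose shape reflects the distance distribution. The time-integrated
polarization is obtained from one resolvent solve of the full generator per
field; the additional equivalent nuclei are treated exactly via
collective-spin sectors with a zero-quantum Liouville-space reduction (a
binomially weighted semiclassical shortcut is available for comparison).
See `docs/methods.md` for assumptions, parameter provenance and numerics.

## Worked example

```python
import fadcidnp as fc
from fadcidnp.distributions import PRESETS, default_grid

model = fc.BiradicalModel()            # published parameter set
curve = fc.field_sweep(fc.default_field_grid(), model, default_grid(),
                       PRESETS["sim1"])  # normal(0.89 nm, 0.15 nm)
print(fc.curve_features(curve))
```

prints

```
CurveFeatures(extremum_field=0.004404277806098128,
              extremum_amplitude=-0.0016449257240064709,
              fwhm=0.008178981789018746, sign='emissive')
```

i.e. a single emissive CIDNP maximum at 4.40 mT with a full width at half
maximum of 8.2 mT — the low-field anti-crossing resonance of a biradical
with an effective exchange interaction of about −2 mT. The same sweep for
the other candidate distance distributions, scored against a synthetic
relaxation-corrected observation generated from the normal distribution
(2 % noise), ranks the generating distribution first:

```
$ python analysis/04_simulate_field_dependence.py
$ python analysis/05_rank_distributions.py
1. sim1: q = 7.8042e-04      # normal(0.89, 0.15) — the generating model
2. sim3: q = 8.5472e-03      # same, truncated above 1.03 nm
3. sim2: q = 6.7521e-02      # left half of the normal
4. sim4: q = 1.1908e+00      # left-half normal centred off-grid
```

The numbered scripts under `analysis/` run the study end to end
(synthesize → fit NMRD → deconvolve → simulate → rank) and write their
tables under `results/`.

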