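# Methods

This note documents the physical model, the provenance and units of every
parameter, the numerical choices, and the known limitations of the
package. It is the authoritative account of *why* the code is the way it
is; the README describes *what* it does.

## 1. The stochastic-Liouville model of the biradical

The flavin–adenine biradical is modelled as two electron spins ("a" on the
adenine cation radical, "b" on the flavin anion radical) plus one observed
spin-½ nucleus on radical a (the adenine H8 proton in the default
configuration) and n_add = 4 additional equivalent spin-½ nuclei coupled to
electron b. The joint state is a density matrix ρ_i on every node r_i of a
radial grid of end-to-end distances, evolving under the generator

L = −i[H(r), ·] + R_relax + L_diff ⊗ 1_spin + sinks.

**Coherent part.** H(r) = g_a μ_B B S_az/ħ + g_b μ_B B S_bz/ħ
+ A **I**·**S**_a + A_add Σ_k **I**_k·**S**_b − J(r)(½ + 2**S**_a·**S**_b),
with couplings quoted in mT and converted to angular frequency with the
free-electron gyromagnetic ratio. The full isotropic hyperfine coupling is
kept (its flip-flop part drives the level anti-crossing that creates the
polarization); nuclear Zeeman terms are neglected (irrelevant for both the
S/T₋ and the S/T₀ mechanism at the precision of interest). With J < 0 the
singlet lies 2|J| below the triplet, so S crosses T₋ at the field where the
electron Zeeman energy equals 2|J(r)|.

**Additional nuclei — exact by default.** The four equivalent bath nuclei
are decomposed into collective-spin sectors I = 2, 1, 0 with multiplicities
1, 3, 2 (statistical weights (2I+1)·mult/16). Within each sector every term
of the generator conserves the difference of total spin projections between
bra and ket, and the initial state and observable live entirely in the
zero-quantum block, so the Liouville space is restricted to that block
(260 + 132 + 20 = 412 dimensions instead of 64·25). This makes the exact
treatment no more expensive than the traditional semiclassical shortcut —
binomially weighted static projections m·A_add on electron b — which is
retained as `method="semiclassical"`. The shortcut is *not* the default
because its frozen z-projections generate spurious S/T₊ anti-crossing
structure at fields of order |m| A_add (absorptive spikes comparable to the
genuine extremum), which the exact treatment does not show and the
experiment rules out: the measured low-field CIDNP of this system is
smooth, emissive and single-peaked.

**Electron relaxation.** Each electron independently sees an isotropic
fluctuating local field of mean square G with *two* correlation times: the
fast internal-motion time τ_u = 1 ps and the rotational tumbling time
τ_rot = 800 ps, each channel carrying the full printed mean square G (no
weights are invented). Single-quantum flips take the summed Lorentzian
spectral density (G/3)·τ/(1+ω_e²τ²) at the electron Zeeman frequency;
z-fluctuations give the corresponding zero-frequency secular dephasing. The
generator is assembled in Lindblad form (trace preserving, rates ≥ 0).
Including the τ_rot channel is a deliberate model decision: with the fast
channel alone, electron coherence survives for microseconds, singlet–triplet
mixing saturates, and three observed behaviours fail simultaneously —
the curve acquires percent-scale ripple at sub-mT fields, its width
collapses well below the observed ~10 mT, and the high-field polarization
stops being proportional to the hyperfine coupling. With the tumbling
channel included (low-field electron T₁ of a few ns, dispersing away above
~10 mT), all three are restored at once. Nuclear relaxation inside the
biradical is neglected (its lifetime is far shorter than nuclear T₁).

**Radial diffusion.** A nearest-neighbour discrete Smoluchowski generator
with detailed-balance hop rates W(i→i±1) = (D/h²)·sqrt(p_{i±1}/p_i), which
makes the discretized equilibrium distribution exactly stationary,
conserves probability (zero column sums) and gives reflecting boundaries.
Zero-weight nodes are disconnected. D = 2×10⁻⁷ cm²/s is the effective
radial diffusion coefficient of the linker's conformational motion.

**Reaction.** Singlet-projected recombination (Haberkorn form,
−k_p/2 {Q_S, ρ}) acts at the innermost grid node only ("contact",
r = 0.49 nm); scavenging к_s acts uniformly. k_p = 2×10¹⁰ s⁻¹,
k_s = 10⁵ s⁻¹.

**Initial condition.** Equal triplet populations ⊗ maximally mixed nuclei,
distributed spatially as the equilibrium distance distribution (triplet
precursor; no initial coherences).

**Observable.** The time-integrated nuclear polarization is read from one
resolvent solve X = −L⁻¹ρ₀ per field: the geminate flux
k_p Tr[2I_z Q_S X(contact)] and the scavenged flux k_s Tr[2I_z X]. The
default reported quantity is their **sum** — the net polarization created
in the reaction. Rationale: the cw-illumination experiment accumulates
polarization over a cyclic photoreaction in which every exit channel
(including reoxidation of transiently reduced flavin) returns to the
detected FAD pool, so singlet/T₀ *sorting* polarization — equal and
opposite in the two channels — cancels, while the anti-crossing mechanism
creates genuine net polarization. Numerically the cancellation at high
field is exact to ~10⁻⁸, which is what confines the simulated curve to a
single emissive extremum over the whole 0.1 mT–9.4 T range. The
geminate-only observable remains available and is the right choice for
modelling time-resolved (flash-photolysis) CIDNP, which detects the
geminate product before the slow channels complete; the high-field
hyperfine-proportionality check therefore uses it.

## 2. The exchange law and its calibration

The published parameter table gives J_ex(r) = J₀·e^(−αr) with
J₀ = −2.3×10⁸ mT and α = "0.214 nm". These two printed values are not
mutually consistent under any literal reading (the pair would put |J| at
megatesla scale across the whole distribution, or require decay lengths for
which the distance distribution can no longer shape the field dependence —
contradicting the observed strong distribution dependence). The package
resolves the pair as follows, and records the convention in every output:

* α is read literally as printed — a decay **length** of 0.214 nm (the
  dimensionally consistent reading of its printed unit), i.e.
  J(r) = J₀·e^(−r/α);
* J₀ is treated as the one unusable entry and calibrated once against the
  published observables of the curve itself (extremum at 4 mT ≈ 2|J_eff|
  with |J_eff| ≈ 2 mT, width about 10 mT), under the constraint that the
  extremum is formed by the exchange anti-crossing swept across the
  distance distribution and not by the relaxation dispersion knee. The
  frozen result is J₀ = −25 mT (`J0_CALIBRATED_MT`), which places
  J = −2 mT near r = 0.54 nm and spans |J| ≈ 2.5 mT → 0.01 mT over the
  default grid, so crossings for the entire 0.1 mT–10 mT branch fall
  inside the distribution's support.

With this law the default simulation puts the extremum at 4.40 mT with an
8.2 mT FWHM (computed by `scripts/acceptance.py`). The residual +10 %
offset from the printed 4.0 mT is a genuine property of this model
realization: within the exchange-dominated regime the extremum cannot be
pushed below ≈4.4 mT by the amplitude alone, and we do not tune any other
printed parameter. Two alternative conventions are selectable
(`inverse_length_per_nm`, and a steep `decay_length_from_contact` variant)
but both decouple the curve from the distribution and are kept only for
comparison.

## 3. Parameters

| symbol | meaning | default | unit | provenance |
|---|---|---|---|---|
| g_a | adenine radical g factor | 2.0034 | – | published table |
| g_b | flavin radical g factor | 2.0035 | – | published table |
| A | HFC of observed nucleus (A8) | −0.7 | mT | published table |
| A_add | HFC of each additional nucleus | 1.67 | mT | published table |
| n_add | additional equivalent nuclei | 4 | – | published table |
| J₀ | exchange amplitude | −25 | mT | calibrated (§2) |
| α | exchange decay length | 0.214 | nm | published table (literal) |
| D | radial diffusion coefficient | 2×10⁻⁷ | cm²/s | published table |
| G | mean-square fluctuating field | 6.1×10¹⁷ | s⁻² | published table |
| τ_u | fast correlation time | 1 | ps | published table |
| τ_rot | tumbling correlation time | 800 | ps | published table (§1) |
| k_p | singlet recombination rate | 2×10¹⁰ | s⁻¹ | published table |
| k_s | scavenging rate | 10⁵ | s⁻¹ | published table |

Radial grid: 81 uniform nodes, 0.49–1.6 nm (amplitudes change by a few
percent on halving the spacing; extremum position and width are stable).
Field grid: 61 logarithmic points, 0.1 mT–9.4 T.

## 4. NMRD stage

Inversion-recovery decays are fitted with the three-parameter exponential
I(τ) = I_∞ + (I₀−I_∞)e^(−τ/T₁) (free plateau absorbs imperfect inversion);
non-converged fits or rate-at-bound solutions are flagged, not raised. The
dispersion model 1/T₁(B) = R₁/(1+(γ_H B τ_c)²) + R₁∞ is fitted by weighted
nonlinear least squares *in rate space*, with weights from propagated T₁
errors when available. Initial guesses: R₁∞ from the high-field plateau,
R₁ from the low-field excess, τ_c from the half-amplitude field; bounds
τ_c ∈ [1 ps, 100 ns]. Only the high-field window (default 0.56–16.44 T)
enters the fit — in the extreme-narrowing, strong-coupling low-field region
per-proton T₁ is not site-specific, so the window is a parameter, not a
hard-coded constant.

## 5. Shuttle deconvolution

R₁(B) is interpolated by a cubic spline in log₁₀B through the measured NMRD
knots (exact at the knots; clamped with a warning outside the measured
range, where the dispersion model is flat anyway). Each transfer profile is
split into 500 equal time intervals with the field held at its midpoint
value; the attenuation factor is exp(ΣRₙΔtₙ) ≥ 1. The product is
order-independent, agrees with adaptive quadrature of ∫R(B(t))dt to better
than 0.1 % for smooth profiles, and is stable under refinement beyond 500
intervals. Deconvolution multiplies each observed point (and its
uncertainty) by its factor; attenuate-then-deconvolve is the identity to
floating-point accuracy at zero noise.

## 6. Model comparison

The observed curve is normalized to unit extremum magnitude (sign kept:
emissive stays negative). Each simulated curve is interpolated onto the
observed fields with a monotone cubic (PCHIP) in log-field and given a
single free positive amplitude; q = Σ(scale·sim − obs)². A best-fit scale
that would be negative is a sign mismatch and scores the worst admissible
q. Because the published analysis did not state its normalization or point
set, q values are comparable in order of magnitude, not digit by digit;
*ranking* is the meaningful output.

## 7. Synthetic data

The generators emulate: mono-exponential inversion-recovery obeying the
dispersion model (multiplicative Gaussian noise, default 3 %); a monotone
shuttle profile from an exponential fringe field (shape length 0.35 m,
detection field 9.4 T) and a raised-cosine displacement law, duration
0.1 s — chosen so that, with the A8-like truth (low-field T₁ ≈ 0.105 s),
about one half of the polarization generated at 4 mT is lost in transit,
matching the regime the deconvolution stage exists for; and observed CIDNP
curves (attenuation + 2 % multiplicative noise). Default proton truths
(A8, A2, F6, F9, F5′,5′′) carry distinct τ_c of order 1 ns so that
site-specificity is a meaningful test. All generators are pure functions
of (config, seed), with child streams derived via CRC-stable keys.

What the synthetic layer does **not** emulate: coherent polarization
transfer between scalar-coupled protons (A8↔A2) at low field, lineshape
and radiation-damping effects, pH-dependent chemistry, and any secondary
radical pairs. Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical model, not robustness to those
physical effects.

## 8. Numerical notes

* The per-field generator is block-tridiagonal (spin blocks coupled by
  scalar hop rates × identity); it is solved by block-Thomas elimination
  with dense LAPACK factorizations per node (~0.8 s per field for the full
  quantum model on the default grids; validated to 10⁻⁸ relative against
  an independently coded dense resolvent on a 2-node grid, built from
  individual product-state nuclei with no sector decomposition or
  zero-quantum reduction).
* Zero-mechanism input (A = A_add = 0, g_a = g_b) gives |P| ≲ 10⁻¹³ in
  absolute polarization units (the exact zero is limited by LU roundoff in
  a generator whose rates span six orders of magnitude).
* Curve features: the extremum is located by a quadratic through the three
  grid points around the |amplitude| maximum, the FWHM by linear
  interpolation of the half-extremum crossings; both on the log₁₀B axis by
  default (the natural coordinate of geometric field grids), with a linear
  axis available. `count_extrema` counts interior extrema with prominence
  above 10 % of the principal extremum: the discrete equivalent-nuclei
  bath imprints percent-scale ripple on the curve that a continuous
  hyperfine manifold would smooth, and features below that scale are not
  resolved by the experiment either.
* Distribution weights are normalized in log space, so candidates whose
  bulk lies far off-grid (the printed fourth candidate, centred at
  10.2 nm — physically implausible for FAD and kept exactly as printed,
  with a warning and automatic grid extension) still discretize cleanly
  when restricted to the default grid.

## 9. Known limitations

* The exchange amplitude is calibrated, not printed (§2); conclusions
  about the absolute magnitude of J₀ should not be drawn from this code.
* The extremum position lands at 4.40 mT versus the published 4.0 mT and
  the width at 8.2 mT versus "about 10 mT"; both reflect the reconstructed
  (not fully specified) relaxation superoperator.
* The τ_rot relaxation channel amplitude is assigned the printed G for
  want of a separately printed value.
* The semiclassical additional-nuclei path is provided for comparison but
  is quantitatively unreliable below ~5 mT (§1).
* Escape-channel polarization is modelled as returning to the detected
  pool with unit efficiency; partial bleaching would sit between the "net"
  and "geminate" observables.
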