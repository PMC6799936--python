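# Methods

`spikefp` implements a dimensional reduction of the population dynamics of
recurrent integrate-and-fire (IF) networks whose spike transmission is
non-instantaneous — either because synapses low-pass filter incoming spikes
with time constant `tau_s`, or because axonal delays are distributed. This
note records the model, the numerical choices, and the limits of what the
package's tests demonstrate.

## Models and mean field

Single neurons follow `tau_m dV/dt = -f(V) + mu(t) + sigma sqrt(tau_m) xi`,
with `f(V)` selecting the model:

| model | f(V) | voltage unit | notes |
|---|---|---|---|
| VIF | 0 | threshold `v_thr = 1` | reflecting barrier at 0, reset at 0; `tau_m = 1 ms`, `C_m = 1` by convention, so drifts are in `v_thr/ms` |
| LIF | `V - E_L` | mV | reset `v_res`, threshold `v_thr` |
| EIF | `(V - E_L) - Delta_T exp((V - v_thr)/Delta_T)` | mV | spike registered at `V_peak`, reset after `tau_ref` |

Under the diffusion approximation, recurrent input at population rate `nu`
has moments `mu_I = tau_m J C nu` and `sigma_I^2 = tau_m J^2 C nu` (rates
converted Hz -> 1/ms internally); external Poisson drive adds
`tau_m J_ext C_ext nu_ext` and `tau_m J_ext^2 C_ext nu_ext`, a DC bias adds
`R I_DC` with `R = tau_m/C_m`, and an optional explicit white-noise current
adds `sigma_ext^2`.

Stationary gain functions `Phi(mu, sigma)`:

* **LIF** — Siegert formula, `1/Phi = tau_ref + tau_m sqrt(pi)
  int_{(v_res-E_L-mu)/sigma}^{(v_thr-E_L-mu)/sigma} erfcx(-u) du`, with the
  integrand written through `erfcx` to avoid overflow and adaptive
  quadrature at absolute tolerance 1e-10. For deeply subthreshold points
  (upper limit > 26) the integral is evaluated in extended precision.
* **VIF** — closed form of the stationary flux problem on [0, 1]
  (reflecting barrier at 0, absorbing at 1, reinjection at 0):
  `nu = mu / [1 - (sigma^2/2mu)(1 - e^{-2mu/sigma^2})]`, derived by solving
  `mu rho - (sigma^2/2) rho' = nu` with `rho(1) = 0` and unit mass. The
  expression is continued smoothly through `mu = 0` (series) and into
  `mu < 0` (diffusion-sustained firing); an analytic gradient is provided.
* **EIF** — steady-state threshold integration: the flux relation is
  integrated backward from `V_peak` to the lower barrier with a per-step
  exponential integrator (exact for locally constant drift), unit flux
  above `v_res`, zero below; default step 0.01 mV, converged to < 0.5% under
  refinement. `tau_ref` is added to the mean inter-spike interval for all
  models.

Self-consistent network rates solve `nu = Phi(mu(nu), sigma(nu))` by
scanning a bracket for sign changes and refining by bisection (tolerance
1e-3 Hz); when several fixed points exist the stable one with the highest
rate is returned, with stability decided by the numerical gain slope
`dPhi/dnu < 1`. Parameter identification inverts the design problem: given a
target rate and gain slope at an anchor `(mu, sigma^2)` on the iso-rate
contour, the recurrent efficacy `J` solves the quadratic
`slope = tau_m C (J dPhi/dmu + J^2 dPhi/dsigma^2)` (root giving a stable
fixed point, ties toward smaller |J|), and `(J_ext, I_DC)` follow in closed
form from the two moment equations.

## Spectral reduction

At 0-th order in the synaptic-current fluctuations, the membrane-potential
density obeys a one-dimensional Fokker-Planck equation whose drift is set
by the *filtered* mean current `mu_y(t)` (relaxing toward `mu_I(nu)` with
time constant `tau_s`) and whose diffusion carries the slice-dependent
variance `J mu_y` plus all memoryless contributions. Projection on the
biorthogonal eigenbasis `{phi_n, psi_n}` of this operator gives the reduced
rate equations

```
da_n/dt = (lambda_n + [W0 dmu_y/dt]) a + w0_n dmu_y/dt + psi0_n eta_N
tau_s dmu_y/dt = mu_I(nu_N) - mu_y
nu = Phi0(mu_y) + Re(f0 . a),    nu_N = nu + eta_N
```

with `eta_N` white, variance `nu/N` (finite-size noise), and, linearized at
a fixed point `nu*`, the finite-size power spectrum

```
P(w) = [1 + 2 Re(f0 (iwI - L)^-1 psi0)]
       / |1 - (Phi0' + iw f0 (iwI - L)^-1 w0 dmu_I/dnu) r(iw)|^2 * nu*/N .
```

`r(iw)` is the Fourier transform of the spike-transmission kernel; a
first-order synaptic filter and an exponential delay kernel with
`tau_d = tau_s` give the same `r` — the two transmission protocols are
equivalent at this level of description, and the package asserts the
bitwise identity of the two spectra.

**Discretization.** Chang-Cooper finite volumes (exponentially fitted
fluxes) on a uniform grid, default 1024 cells; absorbing boundary at
`v_thr` (half-cell ghost), reflecting at `v_min` (0 for VIF, 10 sigma below
`min(v_res, E_L)` otherwise), threshold flux reinjected as a source in the
cell containing `v_res`. The scheme conserves mass exactly, so
`lambda_0 = 0` holds to machine precision and the stationary adjoint mode
is the constant 1. Eigenpairs come from a dense nonsymmetric
eigendecomposition with bilinear biorthonormalization; the derivative
couplings `w0 = <d_y psi_n | phi_0>` and `W0` use centered differences at
`mu_y +/- h` (default `h = 1e-3 (v_thr - v_res)`), with perturbed modes
matched by optimal assignment on eigenvalue distance and gauge-aligned to
the central basis.

**When sigma_ext = 0** the absorbing boundary of the operator becomes
ill-posed; a floor of 1e-2 mV is substituted (documented, overridable), in
line with treating a vanishing white-noise current as a regularization.

**Mode truncation.** The eigenmode sums converge slowly in strongly
drift-dominated regimes (small CV): hundreds of modes are needed for the
low-frequency plateau. Two evaluations are provided:

* `theoretical_psd(basis, ...)` — explicit truncated mode sum, useful for
  mode-resolved analysis;
* `theoretical_psd_exact(...)` — the same quantities evaluated through the
  full discrete resolvent `(iw I - A)^{-1}` by sparse linear solves, with
  the stationary component removed analytically and the `mu_y`-derivative
  of the operator applied directly (`<psi_n|A' phi_0> = lambda_n w0_n`
  makes the two forms algebraically identical when summed over all modes).
  This is truncation-free at the grid level and is what the acceptance
  tests compare against simulations.

**Rate-equation integration** interpolates `(Phi0, lambda, f0, psi0, w0,
W0)` linearly on a precomputed `mu_y` lattice (modes matched and
gauge-aligned along the lattice), uses an exponential integrator for the
stiff diagonal part, clips transient negative rates at zero (counted), and
folds changes of the external mean current into the `mu_y` coordinate —
exact for the drift, approximate for the diffusion (the external variance
modulation is second order for the weak stimuli considered). Coupling
coefficients of fast modes become ill-conditioned near eigenvalue
crossings as `mu_y` varies; the default retains only slow modes (<= 8),
which the step-response test shows is sufficient — even two modes
reproduce the full density response within 10%.

## 1-D density integrator

`fp1d.integrate_density` is the reference reduced model for time-varying
stimuli: the same Chang-Cooper operator, implicit Euler in time (tridiagonal
solve per step, default `dx = span/1024`, `dt = 0.01 ms`), drift and
diffusion updated every step from the filtered feedback rate `nu_tilde`
(`tau_d d nu_tilde/dt = nu(t - delta_min) - nu_tilde`; the minimum axonal
delay shifts the feedback rate, while the neuron's own reset is immediate
up to the refractory transit, which is a FIFO buffer of absorbed flux).
Absorbed probability is measured as the exact mass deficit of the implicit
step, so total probability (grid + in transit) is conserved to round-off.

## Microscopic simulator

Clock-driven forward Euler (default `dt = 0.05 ms`), fixed in-degree
connectivity (every neuron draws exactly C presynaptic partners without
replacement), spike effects aligned to the grid step *after* arrival
(rounding up; resonance positions are delay-sensitive, so the minimum delay
is effectively `delta_min + dt`). Protocols per projection: `delays`
(delta synapses, per-edge delays sampled from the kernel clipped at
`delta_min + dt`), `filter` (per-neuron first-order current, each spike
adds `tau_m J / tau_s` so the PSP integral equals `J tau_m`, the
`J -> J/tau_s` rescaling), `cascade` (both). External drive is explicit
Poisson spikes (inverse-transform sampling per neuron and step) or the
diffusion-equivalent Gaussian increments; all randomness derives from one
seeded generator, and identical spec + seed reproduces spike output bitwise.
Population rates are binned at 0.1 ms.

Forward Euler misses sub-step threshold excursions, biasing single-neuron
rates low by O(sigma sqrt(dt/tau_m)) (about -1% for the LIF presets at
dt = 0.05 ms); in recurrent networks the loop gain amplifies this by
1/(1 - Phi0'), which together with the mean-field approximation itself
accounts for simulated rates sitting a few percent below the designed fixed
points — the same systematic overestimate the theory is known to have. The
independent Monte-Carlo oracle used to validate the gain functions applies
the standard first-passage boundary correction (threshold lowered by
0.5826 sigma sqrt(dt/tau_m)) so that its bias stays below its statistical
error.

## Spectral estimation and equivalence metric

Simulated spectra use Welch averaging (Hann, 2-s segments, 50% overlap)
after discarding the first second, converted to the two-sided-density
convention in which N independent Poisson neurons give a flat floor
`nu0/N`; normalized spectra `P N / nu0` approach 1 at high frequency (the
estimator is asserted unbiased on an exact Poisson floor). The
filter/delay equivalence metric is the per-frequency z-score of
`P_d/P_s - 1` (difference of realization means over the pooled SEM). With
few realizations the per-bin z is Student-t distributed with few degrees of
freedom, so "agreement" is asserted against that null (fraction of bins
within 3 SEM and the median |z|), not as a hard per-bin bound that even a
perfect theory would fail with ~10% probability.

## Bifurcation study

The two-population (E-I) LIF sweep that demonstrates the
AL -> AH -> GO state sequence is *designed* by the package's own
identification recipe: both populations are anchored on the 10-Hz
iso-rate contour (anchor sigma = 4 mV, subthreshold mean), the excitatory
efficacy sets the uncoupled gain slope to 1.3 (making the anchor unstable,
so low inhibition leaves only the low-rate asynchronous state), and for
each inhibitory in-degree the external parameters are re-identified to keep
the anchor moments fixed. Desk scale is N = 1000 (800 E + 200 I), 10-s
runs. The state labels: AL if the mean rate falls below 0.8 of the target;
GO if the tallest normalized spectral peak below 200 Hz exceeds a factor
over the high-frequency floor (package default 10; the acceptance sweep
uses 50, calibrated to the finite-size resonant amplification of the
stable AH state at this N, which already reaches ~20x the floor); else AH.
The transcribed multi-modular configuration from the source tables is
provided as a preset, but a mean-field audit shows its uncoupled network is
nearly silent rather than at 10 Hz, so only the self-designed sweep carries
quantitative contracts.

## Known limitations

* The reduction is 0-th order in the synaptic-current fluctuations: it does
  not track the y-resolved density, and the membrane-potential marginal of
  the reduced model differs from the microscopic one even when the rate
  dynamics matches (the filter-protocol density near threshold does not
  vanish, the delay-protocol one does).
* The mean-field fixed points overestimate microscopic rates by a few
  percent at these in-degrees (C = 100); spectra are therefore linearized
  at the measured operating rate when compared with simulations.
* The stationary variance of the filtered synaptic current is
  `tau_m sigma_I^2 / (2 tau_s)` (Campbell's theorem), which the simulator
  reproduces; summaries quoting `sigma_I^2/2` hold only for
  `tau_s = tau_m`.
* Synthetic studies use Poisson external drive and homogeneous populations;
  real recordings have neither, so passing tests validate the reduction's
  internal consistency and its match to the microscopic model, not
  biological realism.
* Problem sizes in the test suite (N = 2000 single-population, N = 1000
  E-I, 10-20 s simulations, grids of 384-512 cells, <= 256 modes) are the
  package's desk-scale defaults; all comparisons state their estimator
  noise explicitly.
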