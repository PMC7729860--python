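# Methods

## The culture model

The package models an antibody-secreting hybridoma culture through seven
state variables: viable and total cell density X_v, X_t (cells/L), glucose
GLC and glutamine GLN (mM), the inhibitory by-products lactate LAC and
ammonia AMM (mM), and the monoclonal-antibody titer mAb (mg/L), plus the
liquid volume V_L (L).

The specific growth rate multiplies two Monod saturation factors and two
inhibition factors,

    μ = μ_max · GLC/(K_glc+GLC) · GLN/(K_gln+GLN)
             · KI_lac/(KI_lac+LAC) · KI_amm/(KI_amm+AMM),

so growth stops when either substrate is exhausted and degrades smoothly as
by-products accumulate. Death is ammonia-driven with a sigmoidal dose
response, μ_d = μ_d,max/(1+(K_d,amm/AMM)²), whose AMM→0 limit (zero) is
returned explicitly rather than evaluated through the singular quotient.
Dead cells lyse at first order (K_lysis). Specific uptake is
yield-plus-maintenance, Q_glc = μ/Y_x,glc + m_glc and
Q_gln = μ/Y_x,gln + m_gln; glutamine additionally decomposes abiotically to
ammonia at rate K_d,gln·GLN, a term that appears with opposite signs in the
GLN and AMM balances (nitrogen bookkeeping). Lactate and ammonia production
are stoichiometric, Q_lac = Y_lac,glc·Q_glc and Q_amm = Y_amm,gln·Q_gln.
Antibody synthesis is partially growth-decoupled,
r_mAb = (2 − γμ)·λ·X_v: secretion continues at μ = 0 (at twice the
per-cell rate λ) and is mildly reduced by fast growth; the validity
condition γ·μ_max < 2 is enforced at parameter construction.

### Parameter notes

The default rate-constant set ships as `lgm_params.json`. Two entries
required interpretation:

* **m_gln.** The source constant is quoted as −0.00067 mmol/(cell·h),
  nine orders of magnitude larger than m_glc (4.85×10⁻¹⁴) and large enough
  to make the glutamine balance diverge at any realistic cell density. We
  read it as being expressed per 10⁹ cells and use
  m_gln = −6.7×10⁻¹³ mmol/(cell·h). Since |m_gln| is <1% of μ/Y_x,gln at
  typical growth rates, the choice perturbs Q_gln marginally; the batch
  reference simulation (peak titer within 1.1% of the reference figure)
  supports it. The loader accepts an explicit override but rejects any
  negative m_gln whose magnitude exceeds 5% of μ_max/Y_x,gln, i.e. any
  value that would drive glutamine uptake negative outside a negligible
  neighborhood of μ = 0 (this rejects the raw quoted value). Q_gln itself
  is not clamped: its tiny negative value at μ ≈ 0 is the model as stated.
* **Y_lac,glc, Y_amm,gln** are treated as dimensionless mol-per-mol yields
  (1.4, 0.427), the only reading that keeps the LAC/AMM balances in mM/h.

### Reactor balances

Every species obeys dC_i/dt = (F_L/V_L)(C_inlet,i − C_i) + r_i with
dV_L/dt = F_L and no outflow; batch operation is the F_L ≡ 0 special case.
Inlet lactate, ammonia, antibody and total cells are zero; inlet glucose,
glutamine and viable cells are the per-arc control values. Feeding viable
cells with zero total-cell inlet means X_t < X_v can occur during feeding;
this is a documented property of the model formulation, not corrected for.
As quoted, the total-cell dilution term reads (F_L/V_L)(X_t,in − X_v); we
implement the standard mass-balance form −X_t (the quoted form is most
plausibly a transcription slip) and provide a `strict_printed_xt` switch
that reproduces the quoted form for auditability. X_t feeds back into no
other balance, so the switch only affects X_t itself.

The initial condition couples to the policy: GLC₀, GLN₀ and X_v,0 equal
the first arc's inlet values (X_t,0 = X_v,0); mAb₀ = 80.6 mg/L,
AMM₀ = 0.31 mM, LAC₀ = 0 and V_L0 = 1 L by default.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  rtol = 10⁻⁷ and atol = 10⁻⁹, restarted at every arc switch because the
  controls are discontinuous there; arcs are left-closed/right-open
  [T_{j−1}, T_j), with t = t_f assigned to the last arc. No smoothing of
  the control discontinuities.
* **Conditioning.** Cell densities (~10⁹) and concentrations (~10) differ
  by ten orders of magnitude, so biomass is integrated in units of
  10⁹ cells/L; user-facing units are always cells/L. Tolerances apply to
  the scaled state.
* **Clamping.** Monod/inhibition factors evaluate max(C, 0) so tiny
  negative integrator excursions cannot produce negative rates; the clamp
  threshold is exactly 0.
* **Dense output.** 400 samples per arc by default (configurable, min 2);
  the peak titer is the dense-grid maximum refined by a parabola through
  the three neighboring samples, exact for a locally quadratic titer curve.
* **Robustness.** Tightening rtol/atol tenfold moves the peak titer of
  every packaged scenario by <0.1% (tested).

## Raw-material accounting

Consumption is the closed-form arc sum Σ_j F_L,j·C_inlet,j·Δt_j (mmol for
substrates, cells for biomass), i.e. what was *fed*; the initial in-vessel
load is reported separately so both conventions are visible. Final volume
is V_L0 + Σ_j F_L,j·Δt_j and must agree with the integrated volume to
1 part in 10⁹ (tested on random policies). Specific productivity is
max mAb/(biomass basis × t_f) with the initial cell load as basis for batch
runs and the fed cells for fed-batch runs — the convention that reproduces
the batch reference figure (6.3×10⁻⁸ mg/(cell·h)).

Known inconsistency: the SP2 reference consumption row (44.46 mmol GLC,
8.00 mmol GLN, 1.7×10⁹ cells) is about 5× the closed-form sum over SP2's
quoted arcs; the per-arc policy is treated as ground truth, SP2 consumption
is excluded from the reference checks, and the discrepancy is carried in
the fixture metadata and surfaced by `fedbatch-mab compare`.

## Optimization

The decision vector stacks the four controls over N_div equal arcs
([F_L | GLC_in | GLN_in | X_v,in], 4·N_div reals) inside per-control boxes.
The objective Ω is the maximum titer of the simulated policy. The dilution
cap Σ_j F_L,j Δt_j ≤ f_max·V_L0 (default f_max = 0.25) couples all feed
rates jointly, so it is enforced as a hard penalty (−10⁶·(1+excess))
rather than a bound reparameterization; integrator failures return a still
lower penalty so the search loop never sees an exception.

The searcher is an in-package elitist differential evolution
(rand/1/bin, F = 0.7, CR = 0.9, population = min(10·dim, budget/2) with a
floor of 16) followed by a bounded derivative-free Powell polish of the
incumbent, accepted only on improvement. A single integer seed drives all
draws, so runs are bit-reproducible; the evaluation budget counts full
batch simulations. A warm-start policy is injected into the initial
population, which with elitism guarantees the result never falls below a
supplied reference policy. Ties in Ω break toward lower total substrate
consumption (a cost-motivated secondary key). The reference SP1–SP3
policies are treated as feasible reference points, not certified global
optima: the problem is non-convex and the solver that produced them is not
available.

The SP1 reference policy's dilution is 27.1%, above the nominal 10–25%
design cap; its packaged search space therefore carries
f_max = 0.30 so the reference policy itself is admissible (noted in the
fixture provenance). Unequal arcs, a free batch time and searched bounds
are representable in the types but not searched by default.

## Scope and limitations

The model is unstructured and assumes an ideal reactor: isothermal,
iso-pH, iso-DO, perfectly mixed, no outflow or evaporation, no transport
resistance into the alginate beads carrying the immobilized cells, and no
oxygen balance — none of these are parameters. Rate constants are treated
as exact; parameter estimation and robustness to parameter uncertainty are
out of scope, as are multi-reactor configurations and economic costing.
The packaged scenarios are model-reference points, not experimental data:
agreement with them validates the implementation of the model and
accounting conventions, not the biology of any particular cell line.
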