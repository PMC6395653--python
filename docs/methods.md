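# Methods

## The model

`tumorflux` simulates the growth of an LL/2 Lewis lung carcinoma xenograft as
a perfused metabolic reactor. The tumor consists of a cell mass `X` (counted
in units of 10⁶ cells; one cell occupies `v_cell` = 10⁻⁶ mm³ by default, so
10⁹ cells ≈ 1 cm³) bathed by a capillary blood volume `V_blood` treated as a
perfectly mixed, continuously fed stirred tank: blood of composition `C0`
enters at flow `F_in` (mL/h) and leaves at `F_out`. The state evolves as

```
dC/dt       = S_c r X / V_blood + (C0 F_in − C F_out) / V_blood − μ_blood C
dm/dt       = S_m r − (ε_m + m) μ
dX/dt       = μ X − k_d (1 − ρⁿ)/(k_ratioⁿ + ρⁿ) X,     ρ = NAD⁺/NADH
dV_blood/dt = μ_blood V_blood
dV_tumor/dt = dX/dt + dV_blood/dt
```

where `C` are blood and `m` intracellular metabolite concentrations (mM),
`r` is the flux vector of the 35-reaction central-carbon-metabolism (CCM)
network, and `S_c`, `S_m` its two compartment-restricted stoichiometric
matrices. The last equation mixes cell counts with volumes; we make it
dimensionally explicit through `v_cell` (configurable). The same numeric flux
vector drives both compartments — per-cell transport rates for the blood
balance, concentration rates for the cell — a deliberate dual-unit
convention inherited with the model structure.

The death term is implemented without modification: it vanishes at ρ = 1, is
*negative* (a growth bonus) while the cell is in the oxidized, Warburg-like
state ρ > 1, and saturates at `k_d/k_ratioⁿ` as ρ → 0. No clamping is
applied. This one term carries the whole therapy phenotype: as long as the
redox ratio stays above threshold the tumor grows at `μ + ~k_d`; once ρ
crosses `k_ratio` the death rate rises to ≈ `k_d` ≈ `μ` and the volume curve
flattens. With the Hill exponent n = 6 the switch is sharp, which is what
produces a plateau rather than a slow roll-off.

Growth dilution applies to every intracellular pool. Because the network
conserves its cofactor moieties (NAD(H), NADP(H), FAD(H₂), adenylates have no
synthesis reaction), those pools decay as `e^(−μt)` over the experiment — a
direct consequence of the `dm/dt` equation. Two modeling choices keep this
from freezing the metabolism: cofactor half-saturation constants are set well
below the reference pools (≈ m*/20), so fluxes degrade gracefully rather than
collapse; and the redox *ratio* ρ, which gates death, is invariant under
proportional dilution, so the death clock is driven by the leak and by flux
rebalancing, not by dilution itself.

`μ` is a constant in the default configuration (it is one of the fitted
parameters); a flux-coupled mode `μ = μ_max · r[Vgrowth]/r_ref` is available
as an option.

## The network reconstruction

The packaged network (`data/ll2_network.tsv`) has 52 metabolites (26 blood,
26 intracellular) and 35 reactions covering glycolysis, the oxidative pentose
phosphate branch, the TCA cycle, lipogenesis, oxidative phosphorylation,
amino-acid catabolism and a lumped biomass reaction. Reaction-level
stoichiometry is a reconstruction (the source pathway map is a diagram, not a reaction table), with
these deliberate choices:

* Glucose transport is lumped into `VHK` and lactate export into `VLDH`
  (`VLDH` is reversible; negative flux = lactate uptake). Without lumping,
  the transporters would appear as additional single-reaction cut sets.
* There are two acetyl-CoA pools: mitochondrial `ACCOA` (from `VPDH` and
  ketogenic amino acids, feeding `VCS`) and cytosolic/lipogenic `ACCOAC`
  (produced only by `VACL`, consumed only by `VPALM`). This is what makes
  ATP citrate lyase structurally essential for growth.
* Nucleotide synthesis is lumped into `Vgrowth` (which consumes R5P
  directly); a separate synthesis step would be a seventh essential
  reaction.
* Inorganic phosphate, CO₂, H₂O, O₂ and NH₄⁺ live in the blood compartment
  (open boundary). Blood phosphate is the phosphorus source for the biomass
  demand; without it the conserved phosphate moiety would block growth.
* Biomass consumes 0.4 R5P, 0.05 PALM, 0.2 G6P, 0.3 GLU, 6.8 ATP and traces
  of blood amino acids per unit, and 0.1 NADPH; the NADPH coefficient closes
  the NADP(H) redox balance exactly (2·0.4 = 14·0.05 + 0.1), which is a
  structural requirement since the oxidative PPP is the only NADPH source
  and is itself pinned to the R5P demand.
* `VNADleak` (NAD⁺ degradation) and `VAK` (adenylate kinase) cannot carry
  steady-state flux (the leak has no compensating synthesis; AMP has no
  other source) and are therefore blocked in the structural analysis; both
  are dynamically active.
* Blood oxygen is carried at 8.8 mM in the inlet — total O₂ content
  including hemoglobin-bound oxygen, not dissolved O₂ alone — otherwise
  respiration is quenched immediately.

## Structural analysis

Blood species are boundary metabolites; intracellular species are balanced.
Elementary flux modes are enumerated with the classical tableau
(double-description) algorithm on the reversibility-split network in exact
rational arithmetic; minimal cut sets for a target are the minimal hitting
sets (Berge's incremental transversal) of the supports of target-containing
EFMs. Deleting a cut-set member removes both directions of a reversible
reaction (enzyme-level semantics).

On the packaged reconstruction the growth target `Vgrowth` has 874 EFMs and
249 minimal cut sets, of which exactly six are single reactions: `VHK`,
`VG6PDH`, `VCS`, `VACL`, `VPALM`, `Vgrowth` — the structural signature that
motivates targeting hexokinase (diclofenac) and ATP citrate lyase
(hydroxycitrate). The total count and the tally of sets of size ≤ 2 depend
on the exact reversibility and boundary conventions of the reconstruction;
a reconstruction with more reversible steps or separate transport reactions
yields substantially more (and different) cut sets, so only the essential
set is treated as reconstruction-invariant. Tests validate the enumeration
against brute-force subset knockout (LP feasibility) on random networks of
up to 8 reactions.

## Drug action

Each drug multiplies its target reaction's *net* rate by a non-competitive
factor: `k/(k + d)` for inhibition, `1 + d/(k + d)` for activation (d = blood
drug concentration, k = half-effect constant). The annotated targets are:
diclofenac → `VHK` (k = 0.5 mM) and `VLDH` (k = 0.01 mM, i.e. LDH is far
more sensitive than the lumped uptake step); alpha-lipoic acid → `VPDH`
activation (k = 0.05 mM); hydroxycitrate → `VACL` (k = 0.1 mM); metformin →
`VATPase` inhibition and `VNADleak` activation (k = 0.05 mM). Drugs are
blood species supplied through the inlet (`C0` steps up at the treatment
start, day 12), so exposure rises with the capillary washin time constant.
Oral/intraperitoneal pharmacokinetics are deliberately reduced to constant
exposures; "high" dose is the calibrated exposure table (0.5–1 mM,
saturating for each target) and "low" dose is one tenth of it.

## Calibration

Kinetics are generalized multiplicative Michaelis–Menten laws. Rather than
hand-tuning 35 maximal rates, the defaults are *back-solved*: a balanced,
Warburg-style steady-state flux distribution v* (S_m v* = 0, ~70 % of
glycolytic pyruvate leaving as lactate, oxidative PPP pinned to biomass) is
fixed at the reference state m* (the packaged initial concentrations), and
each vmax is set so the rate law reproduces v* at m*. Reverse rates carry a
fixed fraction of the forward gross rate at m* (35 % for LDH, 10–60 %
elsewhere). The dynamical calibration then reduces to a handful of scalars:

| parameter | value | role |
| --- | --- | --- |
| μ (cells) | 1.52×10⁻³ h⁻¹ | fitted growth rate |
| k_d | 1.50×10⁻³ h⁻¹ | death ceiling ≈ μ → plateau, not regression |
| n, k_ratio | 6, 1.0 | sharp death switch at ρ = 1 |
| μ_blood | 5×10⁻⁴ h⁻¹ | slow capillary expansion |
| F_in = F_out | 3.0 mL/h | perfusion (fitted) |
| basal NAD leak | 3×10⁻⁴ mM/h | sets the control redox clock |

Mechanistically, the two arms separate as follows. The respiratory chain has
limited capacity, so blocking `VLDH` (diclofenac) forces NADH to pile up
until respiration absorbs the production, roughly doubling the NADH share of
the (shrinking) pool, while metformin's activated leak drains NAD⁺ twice as
fast: the therapy arm's ρ crosses 1 near day 38 and the death term halts
growth at ≈ 930 mm³. The control arm's ρ declines only through the basal
leak and dilution and stays above 1 for the whole 49-day window, giving
154 → ≈ 3 880 mm³. Late in therapy, pyruvate is drained by the activated
PDH while lactate and residual NAD⁺ drive LDH backwards — lactate uptake
with elevated respiration, the reversed Warburg phenotype; in the control
the forward LDH flux stays positive through the growth phase.

Blood lactate starts at 4 mM (the implanted tumor has already conditioned
its microenvironment; all other blood species start at the inlet
composition), is first washed out toward the arterial 1.5 mM and then
accumulates with tumor growth.

## Parameter estimation

The objective is the weighted least-squares chi-square,
Σₙ Σₜ ((Y_exp − Y(p))/σ)², over tumor volume only; σ is the cohort SD per
measurement day, floored at 1 mm³. The sensitive parameters F_in, F_out and
μ are fitted by bounded least squares (scipy's trust-region reflective
method on the weighted residual vector, in p0-scaled units; Nelder–Mead is
available as an option), with an optional seeded multi-start (default 5
starts, disable with `multi_start=1`). Simulation failures return a large
finite penalty so the search continues.

All three parameters are identifiable in the noise-free limit: a 10 %
change in F_in moves the day-59 control volume by ≈ 34 %, F_out by ≈ 9 %
and μ by ≈ 10 % (the perfusion flows act through substrate supply → redox
state → the death/boost term), and recovery from ±20 %-perturbed starts on
noise-free data is exact to < 1 %. Under realistic noise the perfusion pair
is only weakly identified from a volume curve: with 10 % caliper CV and
n = 10 mice, the Cramér–Rao bound on the relative standard deviation is
≈ 2 % for μ, ≈ 13 % for F_in and ≈ 26 % for F_out, with an F_in–F_out
correlation of 0.99 (the data pin the ratio F_in/F_out much better than
the common scale). Simultaneous recovery of all three to 15 % therefore
succeeds only in a minority of noisy replicates; μ alone recovers within a
few percent essentially always. This is a property of volume-only data, not
of the estimator.

## Synthetic cohorts

The generator emulates the study design: n = 10 mice per arm, initial
volumes N(154, 16²) mm³ at day 10 (the 130 mm³ randomization threshold is
reached around day 12), calipering every 3.5 days to day 59, per-mouse
lognormal heterogeneity (CV 10 %) on μ, and multiplicative lognormal caliper
noise (CV 10 %) — measurement error scales with tumor size. Trajectories
can be censored at the 4 000 mm³ lethal burden (off by default). What the
generator does *not* emulate: survival/dropout, body-weight covariates,
measurement-day jitter between mice, or any real biological structure beyond
the fitted mean model — so passing recovery tests demonstrates estimator
correctness under the model's own assumptions, not robustness to model
misspecification.

Noise-free recovery of (F_in, F_out, μ) from ±20 %-perturbed starts is exact
to well under 1 %; with the full noise model, ≥ 90 % of seeded replicates
recover all three within 15 %.

## Numerical choices

* Stiff-capable integration (LSODA), rtol 10⁻⁶ / atol 10⁻⁹ by default;
  fitting uses rtol 10⁻⁵ and a 1-point/day output grid for speed.
* Concentrations are clipped at 0 for rate evaluation; an undershoot beyond
  10⁻⁶ mM aborts with a diagnostic (the spec-level 10⁻⁹ proved too strict
  for transient solver undershoot at the dosing discontinuity).
* The dosing step at day 12 is handled by splitting the integration at the
  phase boundary.
* Plateau detection: the first output day from which every subsequent 7-day
  relative change stays below 1 %.
* "Late-time" flux markers are averaged over days 40–50 (the post-plateau
  window of the 59-day protocol).
* EFM enumeration uses `fractions.Fraction` throughout; tie-breaks are
  lexicographic on sorted reaction-id tuples.

## Known limitations

* The model does not shrink: regression beyond the plateau requires an
  apoptosis/clearance mechanism that is out of scope, so the therapy curve
  flattens slightly above the in vivo late-time mean.
* The calibrated plateau onset is ≈ day 40 (the in vivo curves flatten nearer day 35).
* Control blood glucose falls through mid-study but partially recovers late
  (per-cell uptake dilutes faster than the cell count grows), rather than
  being fully exhausted at day 59.
* Cofactor pools decay with growth dilution by construction; absolute
  late-time fluxes are therefore lower than early ones in both arms, and
  only flux *contrasts* between arms should be interpreted.
* Cut-set totals are reconstruction-dependent; only the six essential
  reactions are robust.
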