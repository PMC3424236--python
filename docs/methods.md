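# Methods

## Chemical model

A system is declared as *components* — free building blocks Fe³⁺ (metal),
ligand L (its fully deprotonated anion), H⁺ (proton) and optionally the
protein P — plus *species* M_pL_qH_r with cumulative formation constants

    beta_pqr = [M_p L_q H_r] / ([M]^p [L]^q [H]^r),   stored as log10.

Negative proton coefficients encode hydroxide/deprotonated water, with an
implicit OH⁻ pseudo-species at log Kw (default −13.997).  All constants are
*conditional*: valid at the ionic strength and temperature of their source,
used without Davies/Debye–Hückel activity corrections, matching how such
constants are used in practice for assay modelling at I ≈ 0.1 M.  All
concentrations are molar internally; configs may tag values with µM/nM units.

Protein adducts are added through stepwise association constants: the adduct's
cumulative log β is the core complex's log β plus log K_assoc (additivity of
cumulative constants), so a dissociation constant K_D maps to
log K_assoc = −log₁₀ K_D.  If the adduct core matches neither a declared
species nor a single free component (e.g. a speculative P + 2L candidate), the
supplied constant is interpreted as cumulative from free components, the
convention of equilibrium-refinement software.

### Packaged constants and their provenance

The packaged YAML files (ferric hydrolysis; catechol; 2,3-DHBA; gentisate;
salicylate; enterobactin) are **reconstructions from literature sources, not
asserted ground truth** — the study they support cites its constant sources
but prints no numbers.  Every constant carries a provenance string.  Two
policies applied at packaging time:

- The hydrolysis ladder is the mononuclear aqueous set FeOH (−2.19),
  Fe(OH)₂ (−5.67), Fe(OH)₄⁻ (−21.6).  Neutral Fe(OH)₃(aq) is omitted: it is
  poorly determined in the source and would act as a stand-in for the
  precipitate, which this package deliberately does not model.
- Where the literature spread exceeds ~0.5 log unit (the second-step Fe–SA
  and Fe–(GA)₂ constants), the packaged value was fixed once, inside the
  literature range, such that the models reproduce the qualitative speciation
  the original study published (GA/SA complex iron appreciably only at acidic
  pH; the 1:1 Fe:2,3-DHBA complex leads the ligand complexes at pH 7.2).
  These choices were frozen before any test was written and are inputs to the
  package, not findings of it.

A chemically important detail: desferri (iron-free) binding scenarios attach
the protein to the **protonated** catechol unit LH₂, the predominant free
ligand form at pH 7.2.  Binding the bare trianion L³⁻ would bury the
association under ~9 log units of protonation penalty and no titration at
µM ligand could ever show quench; with LH₂ as the core, the stepwise constant
is also the apparent sub-µM affinity the assay observes.

## Equilibrium solver

Mass balance for every non-clamped component j,

    free_j + sum_i nu_ij c_i(free) = T_j,

is solved by Newton iteration on ln(free) (positivity by construction) with
per-condition backtracking line search on the max-norm of the relative
residual, a step cap of 40 ln-units, at most 200 iterations, and a relative
convergence tolerance of 1e-9 on every component residual (a state is
"converged" only if all residuals pass).  Residuals are scaled by
max(T_j, 1e-30); absent components are floored at 1e-30 M so the log-space
solve stays finite, and reported back as exact zeros.  On stalling, the scalar
driver retries from spread cold starts and finally ramps the totals up
homotopy-style (10 geometric steps with warm starts).  Fixed-pH conditions
clamp [H⁺] = 10^−pH and drop the proton balance — titration against pH, which
is how pH speciation diagrams are defined.  The solver is vectorised over
conditions (batched Jacobian solves), which is what makes refinement
affordable: a 60-point titration costs one batched Newton run per residual
evaluation.

pH diagrams solve grid points sequentially with warm starts (verified
point-by-point identical to cold starts), flag non-converged points and
exclude them from the column-sum-to-one guarantee.  Fractions are referenced
to the metal by default (selectable), with the free component reported as its
own row.

## Quench model and refinement

Fluorescence is linear in protein-containing species: free protein at
coefficient 1, each bound species s at q_s ∈ [0, 1] (default 0 = fully
quenched), normalised against a zero-titrant anchor solve so f(0) ≡ 1.
Refinement holds all speciation constants fixed and adjusts only:

- log K_assoc per candidate bound species (log-parameterised),
- the candidate fluorescence coefficients q_s ∈ [0, 1],
- optional per-replicate normalisation scalars (bounded [0.5, 2]),

by bounded trust-region least squares on sigma-weighted residuals, jointly
across replicates.  A coarse 1-D scan over log K (0…16, unit steps) locates
the identifiable decade, then three local fits start from offsets
(−2, 0, +2); the lowest residual sum wins.  Standard errors come from the
Jacobian at the optimum (cov = s²(JᵀJ)⁻¹); AIC = n·ln(RSS/n) + 2p with p the
full parameter count, comparable across candidates fitted to the same data.
Model selection fits every candidate stoichiometry — restricted by default to
candidates whose metal-containing core is a predominant solution species at
the assay pH (metal-free cores are never dropped; the predominance threshold
is configurable because at µM totals the hydroxide ladder can hold most of
the iron even when one ligand complex clearly leads the others) — and returns
the AIC-best fit, breaking ties (ΔAIC < 2) toward fewer parameters, then
lower RSS.

**Identifiability rule.**  If the observed quench dynamic range is below
3× the estimated noise (stated sigmas, else replicate scatter at matched
ligand totals, else a MAD-based first-difference estimate), no point estimate
is reported.  Instead the result carries a K_D *lower bound*: the weakest 1:1,
fully-quenching association that would still have cleared the noise at the
largest ligand total, K_D^lb = (1−q)·L_max/q with q = 3×noise.  At the default
design (L_max = 20 µM, 1% noise) this is ≈ 0.65 mM — three orders of magnitude
above the fittable sub-µM scale, which is exactly the verdict flat titrations
deserve.

## Retention prediction

The ultrafiltration readout is idealised as a single equilibrium snapshot:
percent retained = 100 × (iron in protein-containing species)/(total iron) +
background.  Washing kinetics are not modelled; radiolabelled and cold iron
are treated as chemically identical.  The background defaults to 0 and is a
knob, never asserted, because the physical assay's nonspecific retention is
instrument-specific.  The prediction is monotone in the protein association
constant and saturates at 100% under protein excess with strong ternary
affinity (both property-tested).

## Synthetic data generator

`generate_titration` draws f = f_model·(1+ε), ε ~ N(0, noise_sd) i.i.d. per
point and replicate, clipping negative draws at zero (counted in metadata).
Noise is multiplicative because fluorescence error scales with signal; the
default 1% relative SD is a typical plate/cuvette fluorimeter precision —
the source study states no noise model, so this is a package default, exposed
in `GeneratorSpec`.  The default schedule is an exact-zero anchor plus 19
log-spaced ligand totals from 50 nM (half the protein concentration, so the
sub-µM region that pins sub-µM constants is sampled) to 20 µM, at 100 nM
protein and pH 7.2, three replicates.  Ferric scenarios co-titrate iron at
one third of the ligand total (the 0.33-equivalent premix protocol).

What a green test establishes: the estimator is calibrated *under its own
generating model* (coverage of ±3 SE intervals, AIC recovery of the
generating stoichiometry).  What it does not establish: robustness to
inner-filter effects, instrument drift, wavelength-resolved structure or
mis-specified speciation constants — none of which the generator emulates.

## Numerical and design choices

- Tolerances: solver 1e-9 relative (configurable); speciation column sums
  1e-6; optimizer at scipy defaults.
- Ties in predominance ranking break by table order; ties in AIC by parameter
  count then RSS.
- Degenerate inputs: zero totals are legal (absent components); negative
  totals raise; non-convergence is a flagged state for solves, an exception
  for retention (where a number from an unconverged state would mislead).
- The estimator-calibration suite runs on a minimal P/L/PL model at the assay
  design rather than the full ligand-speciation background, keeping the
  200-replication run inside a few minutes; the full chemistry is exercised
  by the scenario fixtures instead.

## Known limitations

- No activity corrections, no temperature extrapolation, no mixed-solvent
  (5% DMSO) effects; constants are conditional.
- No precipitation or redox chemistry; at neutral pH and tens of µM iron the
  real system can precipitate Fe(OH)₃, which appears here only as the soluble
  hydroxide ladder.
- Packaged constants are reconstructions; conclusions that depend on a
  specific constant to better than ~0.5 log unit should re-derive it from a
  primary source.
- The K_D lower bound for flat curves assumes a 1:1, fully-quenching limit;
  weaker partial-quench models would give even larger bounds.
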