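# Methods

## Observable and weighting

In fast exchange on the chemical-shift timescale, the observed amide peak is
the population-weighted average of the free and bound positions, so each
residue's peak migrates along the straight line from its free to its bound
coordinates as ligand is added. The per-residue readout is the combined
shift distance against the free (zero-ligand) reference spectrum,

    Δδ_w = sqrt(Δδ_H² + (α·Δδ_N)²),

with the ¹⁵N axis compressed by α so that nitrogen and proton perturbations
are compared on the frequency scale set by their gyromagnetic ratios. The
default α = |γ(¹⁵N)/γ(¹H)| = 0.1014 is the most literal gyromagnetic
weighting; the widespread empirical conventions (0.14, 0.154) are available
through the `alpha` argument everywhere it appears. Shift distances are
always measured per point against the free reference, not cumulatively
between consecutive points.

## Exchange-regime classification

A residue is called **intermediate** if its peak is absent at any
nonzero-ligand point, or — when peak heights are available — if a height
drops below θ (default 0.3) of the free-state height; **unperturbed** if
every observed Δδ_w is below a floor ε (default 0.005 ppm, the scale of HSQC
digital resolution); otherwise **fast**. Both θ and ε are configurable.
Intermediate-exchange residues never enter quantitative fits: their observed
positions sit between the free and bound frequencies in a way that depends on
kinetics, not just populations. They are reported as qualitative binders.

## Equilibrium models

Concentrations are mM throughout the API; reports render K_D in both µM and
mM.

**Single site.** For total protein *a*, total ligand *b* = x·*a* and
dissociation constant K_D, the complex concentration is the physical root of
[PL]² − (a+b+K_D)[PL] + ab = 0, giving the closed form
y = (Δδ∞/2)(B + x − sqrt((B+x)² − 4x)) with B = 1 + K_D/a. This ligand-
depletion ("quadratic") isotherm is mandatory here: the titrations run at
protein concentrations (0.08–0.78 mM) comparable to the constants being
estimated. The closed form is verified against an independent bracketed
root-finder on the mass balance (`single_site_oracle`) to < 1e-9 ppm over a
1000-point grid.

**Two independent sites.** A tandem construct is modelled as two
non-interacting sites on one protein (2:1 ligand:protein stoichiometry).
Free ligand L at total ligand L_tot solves

    L + p·L/(K₁+L) + p·L/(K₂+L) = L_tot,

a cubic in L with exactly one root in [0, L_tot]. It is solved by the
standard trigonometric closed form for three real roots, selecting the root
in the physical bracket. Numerical choices: the acos argument is clamped
when it exceeds [−1, 1] by ≤ 1e-12 (floating-point dust); anything worse
falls back to bisection with a warning; and the returned root is polished
with up to three Newton steps on the monotone mass-balance function, which
removes the cancellation error of the closed form near small roots and keeps
the mass-balance residual below 1e-9 mM across the tested parameter space
(verified against a bisection oracle on 1000 seeded random parameter
combinations). Avidity/cooperativity between sites is deliberately out of
scope: an affinity difference between a domain measured alone and in tandem
is an empirical output of the fits, not a model ingredient.

## Hotspot selection and site averaging

Binding-site residues are selected by the mean-plus-one-SD rule: over the
candidate residues (optionally restricted to one domain's residue range), a
residue is a hotspot if its Δδ_w at the chosen titration point is ≥ mean +
one sample SD (n−1 denominator). The final titration point is used by
default because it maximises dynamic range; the point is an argument.
Intermediate-exchange residues are excluded from the statistics and listed
separately. Selection tolerates rounding at the threshold (8·eps slack) so a
degenerate all-equal set selects every residue.

Site-level K_D estimation offers two averaging conventions, because
"averaging the selected residues" is genuinely ambiguous: **curve-average**
(default) fits the per-point mean of the hotspot curves once;
**kd-average** fits each hotspot separately and averages the constants,
reporting their SD. The two agree when hotspots share one true K_D and
diverge otherwise; both are exposed and neither is asserted as canonical.

## Two-site fitting: summed vs joint

The classical procedure sums the two site-mean curves and fits the two-site
model to the sum. The summed curve, however, carries no information about
which site produced which response: site labels can swap. The summed mode
therefore assigns δ₁ to the site whose mean saturates higher (a heuristic,
always accompanied by a warning). The **joint** mode fits both site means
simultaneously with a shared free-ligand concentration, preserving site
identity by construction; on seeded noisy replicates its median K error is
never worse than summed mode's (tested), and it is the default in the
pipeline. A site whose fitted amplitude is ~0 (< 1e-6 ppm) has its K
reported with infinite uncertainty: identifying a constant purely through
its ligand-depletion coupling to the other site is not defensible.

## Optimisation and uncertainty

Fits use bounded trust-region least squares (K ∈ [1e-6, 1e3] mM,
δ ∈ [0, 10] ppm; ftol = xtol = gtol = 1e-12). Starting values: Δδ∞₀ = 1.2 ×
max observed Δδ_w; K₀ = the ligand concentration at half-maximal shift by
linear interpolation; the two-site fit starts from single-site fits of the
separate site means. Missing points are dropped from the residuals, never
imputed; a per-residue fit requires ≥ 4 observed points including the free
reference, a two-site fit ≥ 6 points. Quoted uncertainties are asymptotic
standard errors (residual-variance-scaled inverse of JᵀJ; singular
directions report inf); a seeded residual bootstrap (`bootstrap_kd_sd`) is
available when the asymptotic approximation is doubtful at small n.

## Synthetic titration generator

`simulate_titration` emulates what an assigned peak list records, not the
spectrum: free positions uniform in δ_H ∈ [6.5, 10.5], δ_N ∈ [102, 132] ppm;
each binder gets a saturation amplitude drawn from `ddmax_range` (default
0.05–0.25 ppm, a typical amide CSP span) in a random direction in the
weighted shift plane; at each point the peak sits at free + (bound−free) ×
occupancy, with occupancy taken from the exact equilibrium oracle of the
chosen model. Gaussian position noise (default SD 0.003 ppm, a realistic
peak-picking precision at typical HSQC digital resolution) is applied to δ_H
and, divided by α, to δ_N, so the noise enters where experimental error
arises — peak positions — and the CSP computation itself is exercised.
Intermediate-exchange residues are deleted at points where their site
occupancy lies in (0.2, 0.8), the coalescence window where exchange
broadening is maximal and peaks vanish from real peak lists. One
`numpy` generator seeded from a single integer drives every draw.

The bundled fixtures (`reference_fixtures`) encode four reference titration scenarios:
two synthetic-peptide titrations into 0.78 mM protein over seven increments
(1:0 → 1:4; true K_D 1.19 mM and 0.5 mM), one recombinant-peptide
single-domain titration at 0.08 mM over ten increments (1:0 → 1:8.4; K_D
0.237 mM), and the tandem two-site titration at 0.08 mM (K₁ = 20.57 µM,
K₂ = 249.3 µM) with three site-1 residues in intermediate exchange. Domain
sizes are 26 residues (52 for the tandem), the span of a WW-domain
construct's observable amides, with a 0.4 binder fraction.

What the generator does **not** emulate: lineshapes and differential
relaxation, t₁ noise, peak overlap, assignment errors, slow exchange, or
inter-site cooperativity. Recovery results on it therefore validate the
analysis chain (CSP → selection → fitting), not the spectroscopy; on real
data, accuracy is additionally limited by saturation coverage, overlap and
exchange-regime misclassification.

## Problem sizes and determinism

Validation uses 1000-point oracle grids, noiseless end-to-end recovery on
all four fixtures (tolerances 1e-5 relative single-site, 1e-4 two-site
joint), and 200 seeded noisy replicates per stochastic check — sizes at
which the medians are stable to re-seeding. Identical seeds reproduce peak
lists byte-for-byte; all file formats round-trip losslessly (floats written
with shortest-roundtrip precision).

## Known limitations

- Fast-exchange positions only; no lineshape or k_ex estimation.
- The two-site model assumes independent sites; genuine cooperativity will
  surface as systematic misfit, not a cooperativity estimate.
- The mean+1SD hotspot rule is threshold-based and can admit a non-binder
  (or miss a weak binder) at high noise; the exchange classifier's height
  rule needs peak heights to detect broadening without peak loss.
- Asymptotic SEs understate uncertainty for strongly correlated (K, Δδ∞)
  pairs on non-saturating schedules; use the bootstrap there.
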