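# Methods

## Two-state stability-curve model

The thermodynamic core assumes two-state unfolding with a
temperature-independent heat-capacity change, giving the
constant-ΔCp Gibbs–Helmholtz form

ΔG(T) = ΔH·(1 − T/T_m) + ΔCp·[(T − T_m) − T·ln(T/T_m)],

with ΔG the free energy of unfolding (positive = folded favoured),
ΔH (kcal mol⁻¹) the unfolding enthalpy at the heat midpoint T_m (K),
and ΔCp (kcal K⁻¹ mol⁻¹) the curvature source. Derived quantities:

- T_s = T_m·exp(−ΔH/(ΔCp·T_m)) — temperature of maximal stability
  (closed form from dΔG/dT = 0; validated in tests against a dense
  grid argmax to 0.01 K).
- T_c — the low-temperature zero, found by Brent root-finding on
  [200 K, T_s] with 10⁻⁹ kcal mol⁻¹ function tolerance. The curve is
  monotone on that bracket so the root is unique when it exists. No
  unbracketed Newton step is ever taken: the curve is flat near T_s.
  Below 200 K the constant-ΔCp extrapolation is declared non-physical
  rather than solved; the report then carries a null T_c and a warning.
- ΔS = ΔH/T_m — the two-state midpoint relation.
- f(T) = K/(1+K), K = exp(ΔG/(R·T)), R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ —
  equilibrium folded fraction, exactly 0.5 at both zeros. Computed in
  logistic form so strongly stabilising ΔG saturates to 1.0 without
  overflow.

Temperatures are kelvin internally and °C at every user-facing surface
(conversion constant 273.15). The reported "folding %" is 100·f
evaluated at T_s, i.e. the best the protein ever does; this
interpretation reproduces the published column for all four constructs
(61/80/80/83 within rounding), whereas evaluation at a fixed working
temperature does not for the mutants.

Out of scope by design: temperature-dependent ΔCp, three-state or
oligomeric schemes, pressure effects.

## Thermogram fitting

The observable is far-UV CD ellipticity at 222 nm. The model is a
population-weighted mix of two linear baselines,
θ(T) = f·(a_F + b_F·T) + (1−f)·(a_U + b_U·T), seven free parameters
(ΔH, ΔCp, T_m, a_F, b_F, a_U, b_U). Cold- and heat-denatured states
share one unfolded baseline: nothing in a single-wavelength trace
distinguishes them, and sharing keeps the model identifiable with two
transitions. T_c is always re-derived from the fitted triple, never a
free parameter.

Initialisation uses variable projection: for each candidate triple on
a coarse grid (T_m every 1 °C across the data range, ΔH ∈ {10…60},
ΔCp ∈ {1.5, 2.5}), the four baseline coefficients are solved exactly
by linear least squares (the signal is linear in them at fixed f), and
the lowest-SSR candidate starts the fit. Simpler starts (steepest
gradient, half-amplitude crossing) are biased by several °C when the
folded plateau corresponds to only ~60 % occupancy, as it does for
wild-type Yfh1, because the folded baseline is never directly observed.
A near-constant trace short-circuits to fixed defaults flagged
`weak_signal`; an exactly constant trace raises an unidentifiability
error.

The solve is bounded trust-region least squares (scipy `least_squares`,
TRF, tolerances 10⁻¹²) with bounds ΔH ∈ (1, 200) kcal mol⁻¹,
ΔCp ∈ (0.1, 10) kcal K⁻¹ mol⁻¹, T_m ∈ (0, 110) °C, plus one restart
from +10 % on ΔH and ΔCp if the first attempt does not converge.
Weights are uniform unless the input file carries a per-point sigma
column. Standard errors come from the Gauss–Newton curvature at the
optimum (s²·(JᵀJ)⁻¹). Non-convergence is reported in the results
object, not raised.

Identifiability in practice: on noise-free synthetic data the fit
recovers the generating parameters to optimizer tolerance. At realistic
noise the Fisher information of a single-wavelength trace limits T_m
for marginally stable constructs: with the default synthetic conditions
(0–80 °C at 1 °C steps, noise 2 % of signal span) the Cramér–Rao sd of
T_m is ≈1.9 °C for a wild-type-like truth — the folded baseline is
unobserved and (ΔH, ΔCp, T_m) are strongly correlated — and ≈0.6 °C for
the better-folded mutant-like truth. The fitted estimator attains these
bounds (verified by comparing against fits started at the truth). The
derived T_c is much better determined (median absolute errors
≈0.8 °C / 0.25 °C) because the cold transition lies inside the data.

## Residue interaction networks

Node selection: positions of the reference protein whose alignment
column contains at least one D/E/K/R in any orthologue. Histidine is
not counted as charged (the experiments the analysis supports are at
pH 7.5). Columns where the reference is gapped are skipped; alignment
columns are mapped to 1-based reference numbering through the reference
row's non-gap positions. Charge class is taken from the reference
residue when it is itself charged, else from the orthologue that
contributed the charge.

Distances: per frame, the minimum over side-chain heavy atoms of the
two residues, in nm; glycine falls back to Cα. The convention reflects
what "side-chain approaches" measures; the backbone is excluded so
sequence-adjacent residues do not trivially register as contacts.
Trajectories are read as multi-model PDB through MDAnalysis (universal
and text-based; compressed MD formats are deliberately not a core
dependency), or precomputed per-frame distance tables can be supplied
as CSV.

Persistence and filter: p_ij = (#frames with d_ij < 0.6 nm)/n_frames,
an exact count ratio; the boundary d = threshold counts as *not* an
approach (strict `<`). An edge is retained iff the pair is farther than
the threshold in at most 99 % of frames, i.e. p_ij ≥ 0.01, so exactly
1 % persistence survives the filter. All selected residues remain as
nodes; edgeless ones are flagged isolated.

Cluster report: connected components of the acidic-node subgraph,
size-then-persistence ordered, singletons dropped (one residue is not a
cluster). With an optional per-residue secondary-structure annotation
each cluster also reports whether it spans more than one element — the
configuration expected to destabilise, since repulsion across elements
can pry them apart.

## Synthetic data

`generate_thermogram` evaluates the exact model signal on a temperature
grid (default 0–80 °C, 1 °C step — a standard CD melt) and adds
i.i.d. Gaussian noise to the ellipticity only; temperature is treated
as exact, which Peltier control justifies. Default truth baselines are
folded (−10 mdeg, +0.01 mdeg/°C) and unfolded (−3 mdeg, +0.02 mdeg/°C),
a plausible 222 nm helicity-loss contrast; they are fixtures, not
measurements. What the generator does not emulate: wavelength-dependent
CD spectra, aggregation or irreversibility at high temperature, and
instrument drift — so parameter-recovery results speak to estimator
behaviour under the stated noise model, not to instrument artefacts.

`generate_trajectory` plants contact patterns geometrically: each
planted edge (i, j, p) is placed at 0.55 nm in exactly
round(p·n_frames) frames and ≥0.8 nm otherwise, with all non-planted
pairs ≥0.8 nm always. Contact frames are prefix-scheduled (persistence
is permutation-invariant, so this loses no generality) and each
distinct active-edge configuration is embedded once by seeded stress
minimisation, then verified against the margins; an embedding that
cannot satisfy them (e.g. too many simultaneous contacts on one hub for
3-D geometry) raises an explicit infeasibility error. The margins sit
far from the 0.6 nm threshold so floating-point geometry cannot flip a
classification — network recovery tests are exact equality, not
statistical. Residues are written as three-atom poly-alanine (N, CA,
CB) so the side-chain minimum distance is the controlled CB–CB
distance. There is no force field and no dynamics: these are contact
patterns, not physics.

`generate_alignment` draws a neutral background (alphabet without
D/E/K/R/H) and plants exactly one charged residue per chosen column in
a randomly chosen sequence, mirroring the situation where a position is
charged in only one orthologue.

All generators are deterministic per seed, and every truth record
suffices to predict the pipeline output without running the pipeline.

## Problem sizes and numerical choices

Tests run synthetic recovery at 50 replicates per truth set and oracle
equivalence at 10 residues × 1000 frames, sizes at which the whole
suite completes in well under a minute while the Monte-Carlo standard
errors are small enough for the bias checks to be meaningful. Root
solving uses `brentq` with xtol 10⁻⁹; duplicate thermogram temperatures
are averaged at ingest; ties in cluster ordering break on member lists
for determinism.

## Known limitations

- The two-state assumption is load-bearing: intermediates or oligomer
  coupling would bias every derived quantity.
- ΔCp is constant; over the ~40 °C span between T_c and T_m of these
  constructs that is conventional, but it degrades for wider spans.
- Single-wavelength fits cannot resolve separate cold- and
  heat-denatured baselines; if the two unfolded states differ
  spectroscopically, the shared-baseline model absorbs the difference
  into the thermodynamic parameters.
- The RIN distance convention (side-chain heavy-atom minimum) is a
  declared choice; other atom sets would shift persistences near the
  threshold.
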