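# Methods

This note documents the models implemented in `porepass`, the defaults and
units of their parameters, the numerical choices behind them, and what the
synthetic fixtures do and do not establish.

## Scan reduction: from E(s) to ΔE_AA

An energy curve is an ordered set of (separation Å, total energy eV) points
for one amino acid against the pore wall, strictly increasing in s, with at
least six points and at least one sample beyond 10 Å so the asymptote is
constrained.

*Equilibrium energy.* A quadratic interpolating spline (B-spline of degree
2 through all points, the default knot placement at interval midpoints) is
searched for stationary minima by converting to piecewise-polynomial form
and taking derivative roots per piece, plus an endpoint check. The
stationary minimum is accepted only if it undercuts the lowest sampled
energy by more than 1e-10 of the curve's energy span; otherwise the lowest
computed value is returned and flagged (`method="lowest_point"`). The
tolerance is a tie-break: a machine-noise undercut (e.g. on data with a
symmetric kink) is not a genuine interpolated minimum. A sampled minimum on
the scan boundary also triggers the fallback, with a warning.

*Asymptotic energy.* V(s) = C + D(1 − e^(−a(s−s0)))² is fitted to all
points by bounded least squares (D > 0, a ∈ [1e-4, 50] 1/Å). Initial
guesses come from the data — s0 at the sampled minimum, C at the minimum
energy, D as plateau minus minimum, a = 1/Å — with up to 10 deterministic
jittered restarts (fixed internal seed) on failure. E_asymp = C + D, and
the fit's RMSE is reported.

*Interaction energy.* ΔE_AA = E_eq − E_asymp. Both terms shift equally
under a constant energy offset, so ΔE_AA is offset-invariant (tested to
1e-9 eV). Note that ΔE_AA ≤ 0 by construction whenever the fit is sane:
E_eq is the global lowest energy of the curve while the asymptote sits a
well depth above the fitted minimum level, so a "repulsive" scan (monotone
decay to its plateau) simply collapses to ΔE ≈ 0 — there is no bound state
to report. The repulsive warning branch is retained defensively.

*Discretisation accuracy.* At the scan spacing of 0.1 Å near the well, the
quadratic-spline minimum carries an O(h³) interpolation bias of order
3e-6 eV for a well of unit depth and inverse width 1.2/Å. This is far below
any physically meaningful scale here (table entries are ~1 eV), but it is
why the sub-1e-6 eV round-trip verification in the tests samples the well
at 0.02 Å: refining h isolates pipeline correctness from interpolation
error (the error falls as h³, reaching ~5e-9 eV).

*Packaged table.* The shipped 18-residue table stores printed magnitudes
(−ΔE_AA > 0) and negates them on load, because the kinetics needs signed
energies. MET and ILE have no entry; lookups fail loudly unless the caller
supplies an explicit substitute mapping. No energy is ever invented.

## Protein model

Each residue carries a representative coordinate — the alpha carbon, or the
heavy-atom centroid when no CA exists (configurable choice; residue-scale
geometry is what nearest-neighbour contact plausibly means). RSA values in
[0, 1] are the source of record when supplied as a table; the built-in
computation uses the Shrake–Rupley rolling-probe method (probe 1.4 Å, 960
deterministic sphere points per atom) normalised by the theoretical
per-residue maximum ASA of Tien et al. (2013), clipped at 1. Net charge
(e) and mass (kDa) must be given explicitly; nothing is inferred.

Neighbour lists are exact L-nearest under Euclidean distance on
representative coordinates, ties broken by ascending residue index, self
excluded. L defaults to 5.

## Contact-patch selection model

Defaults: patch size N = 4, neighbour pool L = 5, repetitions 500 000 —
the study conditions of the sampling scheme. The first patch residue is
drawn with probability RSA_i/ΣRSA (uniform with a warning if all RSA are
zero); the other N−1 are drawn uniformly *without replacement* from the
first residue's L-neighbour list — a physical contact patch cannot contain
a residue twice, and the seed residue is excluded from its own pool.
Energies add linearly over the patch.

The Monte-Carlo sampler is vectorised: first picks via a single weighted
draw, neighbour subsets via per-repetition argsort of iid uniforms (an
exact uniform-subset device), energies summed in fixed order, so a fixed
seed reproduces the sample vector bit for bit.

`enumerate_exact` computes the exact law — for each seed residue i (weight
RSA_i/ΣRSA) and each of the C(L, N−1) neighbour subsets (uniform) one
support point — and is the oracle for the sampler: at 500 000 repetitions
the Monte-Carlo mean sits within a few exact standard errors of the exact
mean on every test toy.

The gamma summary is a maximum-likelihood fit to sample magnitudes
|ΔE_protein| with location fixed at zero (fitting magnitudes is our
declared convention; the distribution family alone does not fix it), with
a method-of-moments fallback if the MLE fails and an explicit skip flag
for degenerate inputs (fewer than two samples, or relative spread below
1e-12 as in a homopolymer). Reported mean and std are moments of the
signed samples.

The sensitivity sweep scans N, L or the repetition count. For an
all-attractive table the exact mean is linear in N to R² > 0.99 (exactly
linear for a homopolymer), and the across-seed scatter of the Monte-Carlo
mean follows σ_exact/√reps within sampling error of the scatter estimate.

## Dwell-time kinetics

τ(ΔE) = τ0·e^(−ΔE/β⁻¹) with everything in eV. β⁻¹ = |q|·V_bias follows the
electrophoretic work scale (1 eV for +1e at 1 V, 2 eV for −2e); it
extrapolates linearly in voltage, and a zero net charge requires an
explicit β⁻¹ override since the electrophoretic picture breaks down.

τ0 solves m·dv/dt = F − γv, F = |q|·V/thickness, from rest at the pore
entrance to x = traversal length. Defaults: membrane thickness 38 Å,
traversal length equal to it (the pore-region length of 36 Å is an equally
defensible choice and is configurable), and γ = F/v∞ calibrated so the
terminal velocity is 0.1 m/s — the observed speed scale — rather than a
Stokes radius guess; a drag coefficient can be supplied instead
(mutually exclusive). The field is uniform inside the pore, the simplest
model consistent with a plate-like membrane.

The linear ODE has the closed form
x(t) = v∞t − (v∞ − v0)(m/γ)(1 − e^(−γt/m)); the solver integrates
numerically (implicit Radau with a crossing event; the relaxation time
m/γ ≈ 15 fs makes the problem stiff against the ~38 ns crossing) and
cross-validates against the closed-form root to 1e-8 relative, raising on
disagreement. Massless and drag-free limits are handled analytically
(L/v∞ and the ballistic √(2mL/F)). For a 3.9 kDa, +1e protein at 1 V the
noninteracting transit is 38 ns to within one part in 10⁶ of the
overdamped limit.

Dwell bounds evaluate τ at μ ± σ of the energy distribution (ordered so
tau_low ≤ tau_high); ±1σ is our declared convention for the dwell range.
Exponents beyond 700 in magnitude return infinity with an overflow flag.
Separability of two analytes means disjoint [tau_low, tau_high] intervals;
intervals touching at an endpoint are not separable.

## Occupied-pore current

I(t) = (δt·l_z)⁻¹ Σ q_i(z_i(t+δt) − z_i(t)) over ions inside the axial slab
|z − center| < l_z/2 at the earlier frame t (the slab is judged in z only;
l_z = 36 Å, δt from the frame spacing, no resampling). Both charge signs
drift with the field and add constructively. Units: 1 e/ps = 160.2177 nA,
fixed at 7 significant figures. Ions that disappear before the next frame
are skipped and counted in a warning. When the trajectory records a
periodic box height, per-step displacements are minimum-imaged, so wrapped
coordinates cannot corrupt the sum — the one subtle plumbing point of the
estimator, since the displacement in the sum must be physical.

The low-pass filter is a 4th-order Butterworth applied forward-backward
(zero phase). Only the cutoffs are physically prescribed (5 GHz for current
histograms, 1 GHz for smoothing COM/count traces); family and order are our
declared, configurable design. Two passes of a −3 dB-at-cutoff design give
gain 1/2 at the cutoff, DC is preserved, and the mean of a stationary
series survives to 0.1% on series long against the filter's response.

Histograms accept half-open [t0, t1) exclusion windows (e.g. unfolding
episodes); masking everything is an error. Dipole conditioning splits the
current histogram by the sign of the dipole projection on the field axis
(aligned iff angle < 90°, configurable threshold) on a shared binning.
COM tracking is a mass-weighted mean z per frame with optional 1 GHz
smoothing.

## Synthetic fixtures

The generators produce every input the pipeline needs, with ground truth
in metadata:

- *Energy curves*: Morse-shaped scans on a grid with 0.1 Å steps near the
  well, 0.2 Å beyond, 1.0 Å far out to 15 Å — the stated scan protocol —
  plus optional Gaussian noise.
- *Toy proteins*: line/ring (deterministic) or seeded Gaussian-cloud
  geometries with caller-supplied codes and RSA.
- *Ion trajectories*: drift–diffusion electrolytes, cations drifting +z and
  anions −z (field-driven), periodic wrap in a box taller than the pore
  slab, defaults (22 ions, 2 Å/ps drift, 0.5 Å²/ps diffusion, 80 Å box)
  chosen to give ~10 in-slab ions and currents of order 10² nA so fixtures
  resemble realistic occupied-pore magnitudes. The analytic mean current is
  n·(l_z/box_z)·v_d/l_z in e/ps.

What these fixtures do *not* establish: the fixtures contain no water, no
membrane atoms, no ion–ion forces, and no protein–current coupling, so
passing tests validate the estimators and the model algebra, not the
physical fidelity of any MD or electronic-structure input. Real scan
curves, structures, RSA tables and trajectories enter through the same
file interfaces. Thermal noise on the interaction energies and
conformation-dependent (time-evolving) RSA are out of scope by design.

## Problem sizes

Tests and the acceptance script use 6–18-residue toys (where exact
enumeration is cheap), 500 000-repetition samplers (vectorised, well under
a second), 600–2000-frame ion trajectories, and 2×10⁵-sample filter tones —
sizes at which every stochastic check is backed by an exact or closed-form
oracle.
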