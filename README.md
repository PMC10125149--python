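# porepass

Predicting whether two similar miniproteins can be told apart by a
solid-state nanopore.

Solid-state (silicon nitride) nanopores identify single molecules through
two observables: the ionic-current blockade while the analyte occupies the
pore, and the dwell time the analyte spends inside it. For small, roughly
isotropic miniproteins the current blockades can be nearly identical, so the
dwell time carries the discriminating signal. `porepass` implements a
dwell-time estimator that needs only per-amino-acid pore-wall interaction
energies and a structure with per-residue solvent accessibilities — no
translocation simulation — together with the occupied-pore current analysis
chain used to process ion trajectories from molecular dynamics.

## The model

**Per-residue interaction energies.** A total-energy scan E(s) of one amino
acid against the pore wall at separations s is reduced to

    ΔE_AA = E_eq − E_asymp

with E_eq from quadratic-spline interpolation of the scan minimum (falling
back to the lowest computed value when the spline vertex does not undercut
the data) and E_asymp = C + D from a least-squares Morse fit
V(s) = C + D(1 − e^(−a(s−s0)))². A packaged 18-residue table of ΔE_AA for
silicon nitride is included; all entries are attractive (ΔE_AA < 0).

**Protein-level energy.** The protein contacts the wall through a patch of
N = 4 residues. The first is drawn with probability proportional to its
relative surface accessibility (RSA); the remaining three are drawn
uniformly without replacement from its L = 5 nearest residues (alpha-carbon
distances). Patch energies add: ΔE_protein = Σ ΔE_AA. Repeating the draw
500 000 times yields a distribution summarised by a gamma fit with mean μ
and standard deviation σ. An exact enumeration of the same law serves as an
oracle on small systems.

**Dwell time.** Escape from the pore is a two-state Boltzmann transition:

    τ = τ0 · e^(−β ΔE_protein),      β⁻¹ = |q| · V_bias  (eV)

where q is the net charge and τ0 is the noninteracting transit time from
integrating m·dv/dt = |q|E − γv across the 38 Å membrane (E = V/thickness;
γ calibrated so the terminal velocity is 0.1 m/s). Attraction (ΔE < 0)
lengthens the dwell; two analytes are called separable when their
[τ(μ+σ), τ(μ−σ)] intervals are disjoint.

**Occupied-pore current.** From ion trajectories, the instantaneous current
over the 36 Å pore region is I(t) = (δt·l_z)⁻¹ Σ_i q_i Δz_i summed over
in-slab ions (1 e/ps = 160.2177 nA), optionally low-pass filtered
(zero-phase Butterworth, 5 GHz for histograms, 1 GHz for smoothing),
histogrammed with exclusion windows, and conditioned on the protein's
dipole alignment with the field.

## Worked example

```python
import numpy as np
from porepass import (AAEnergyTable, KineticsConfig, SelectionConfig,
                      dwell_time, neighbors, sample_energy_distribution)
from porepass.synthetic import gen_toy_protein

table = AAEnergyTable.default()
codes = ["CYS", "ARG", "GLY", "HIS", "LYS", "ASP", "SER", "TRP"]
protein, _ = gen_toy_protein(8, codes, list(np.linspace(0.2, 1.0, 8)),
                             geometry="random", seed=3)
dist = sample_energy_distribution(protein, neighbors(protein, 5), table,
                                  SelectionConfig(N=4, L=5, reps=500_000, seed=17))
print(f"dE_protein = {dist.mean:.3f} +/- {dist.std:.3f} eV")
est = dwell_time(dist, protein, KineticsConfig(bias_voltage=1.0))
print(f"tau0 = {est.tau0*1e9:.1f} ns, tau = {est.tau_mean:.3e} s")
```

prints

```
dE_protein = -7.778 +/- 1.122 eV
tau0 = 38.0 ns, tau = 9.076e-05 s
```

The toy protein's contact patches average −7.8 eV of attraction, so its
dwell stretches from the 38 ns noninteracting transit to ~0.1 ms — the
exponential amplification that makes dwell times discriminating even when
blockade currents are not.

The same pipeline is scriptable from the shell:

```
porepass synth ions --seed 3 --out ions.tsv
porepass current compute --traj ions.tsv --cutoff-ghz 5 --out trace.tsv
porepass select run --protein protein.json --reps 500000 --seed 7 --out dist.json
porepass dwell --dist dist.json --protein protein.json --voltage 1.0 --out dwell.json
```

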