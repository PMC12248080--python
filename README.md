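# taildyn

Analysis toolkit for the dynamics of intrinsically disordered histone tails
on the nucleosome.  Histone H3 tails associate with nucleosomal DNA as a
*fuzzy complex* — a bound state made of many rapidly interconverting,
non-specific configurations — and the quantities that report on it span NMR
spin relaxation, MD trajectory statistics and thermal-stability assays.
`taildyn` implements that whole analysis chain on a common set of containers,
together with synthetic-data generators whose ground truth is known
analytically, so every stage can be validated end-to-end without any
experimental download.

## What it computes

**MD → NMR relaxation** (`taildyn.md_to_nmr`).  From superposed trajectory
frames, the rank-2 orientational autocorrelation of each backbone NH bond
vector, C(t) = ⟨P₂(μ(s)·μ(s+t))⟩, is computed with chunk averaging (default
20 chunks), multiplied by exp(−t/τ_rot) to reintroduce the overall tumbling
of the nucleosome core particle (τ_rot = 163.4 ns by default), and fitted
with up to three exponentials.  The resulting spectral density

J(ω) = (2/5) Σᵢ aᵢ τᵢ / (1 + (ωτᵢ)²)

yields R₁, R₂ and the heteronuclear NOE through the standard dipolar + CSA
expressions (r_NH = 1.02 Å, Δσ = −170 ppm), and the per-residue effective
correlation time via

τ_c = 1/(4π ν_N) · √(6 R₂/R₁ − 7).

**Experimental NMR analysis** (`taildyn.nmr_relaxation`).  Chemical shift
perturbations Δδ = √(Δδ_H² + 0.154·Δδ_N²), single-exponential (no offset)
intensity-decay fits for R₁/R₂ with uncertainties from the fit covariance
and from repeated-delay scatter, and the same R₂/R₁ → τ_c estimator with
first-order error propagation.

**Contact kinetics** (`taildyn.contact_kinetics`).  Heavy-atom tail–DNA
contacts (strict d < 4 Å at 1 ns stride), per-residue/per-base-pair contact
statistics, full-tail bound/unbound state calling (unbound when ≤ 10% of
tail residues keep contacts), event segmentation with a 50 ns residence
filter, and ensemble thermodynamics K_d = N_unbound/N_bound,
ΔG⁰ = RT ln K_d at 310 K.

**Interaction networks** (`taildyn.interaction_network`).  A geometric
surrogate for ensemble residue–residue interaction analysis: conformations
extracted every 10 ns with tail copies pooled, hydrogen-bond and van der
Waals edges per conformation, edge probabilities as the fraction of states,
node degrees and adjacent-masked contact-probability maps.

**Thermal shift** (`taildyn.thermal_shift`).  Per-replicate min–max
normalization, forward-difference derivative assigned to the upper step
temperature, prominence-based melting-temperature detection and replicate
aggregation.

**Synthetic data** (`taildyn.synthetic_data`).  Rotational diffusion on the
unit sphere (exact exp(−t/τ) P₂ decay), diffusion-in-a-cone internal motion
matching a prescribed order parameter S², hidden two-state Markov contact
timelines, noisy exponential intensity decays on the experimental delay
schedules, logistic melt curves, and a scripted toy nucleosome for contact
and network fixtures.

## Worked example

```python
import numpy as np
from taildyn import *
from taildyn.md_to_nmr import (FieldParameters, SpectralDensityModel,
                               relaxation_from_J, chunk_average, fit_exponentials)

field = FieldParameters.at_field(600, nu_N_mhz=60.8)

# rigid rotor at the NCP tumbling time: forward rates, then the R2/R1 inversion
rec = relaxation_from_J(SpectralDensityModel([1.0], [163.4]), field)
print(f"R1 = {rec.R1_per_s:.4f} 1/s, R2 = {rec.R2_per_s:.1f} 1/s, tau_c = {rec.tau_c_ns:.1f} ns")

# recover a 5 ns tumbling time per residue from synthetic NH vectors
vt = gen_rotational_diffusion(tau_rot_ns=5.0, dt_ns=0.02, n_frames=100_000,
                              n_vectors=3, seed=1)
for res in vt.residues:
    model = fit_exponentials(chunk_average(vt, res, n_chunks=20))
    print(f"residue {res}: tau_c = {relaxation_from_J(model, field).tau_c_ns:.2f} ns")

# two-state binding kinetics -> ensemble Kd and binding free energy
tl = gen_two_state_timeline(k_bind_per_ns=0.02, k_unbind_per_ns=0.01,
                            n_residues=36, n_frames=1_000_000, seed=1)
stats = binding_stats(call_states(tl, unbound_threshold=0.10), temperature_K=310.0)
print(f"Kd = {stats.kd:.3f}, dG0 = {stats.dG0_kJ_per_mol:.2f} kJ/mol")

# biphasic melt-curve analysis
mc = gen_melt_curve([72.0, 81.0], noise_sd=0.02, n_replicates=3, seed=1)
print("Tm =", aggregate_replicates(mc).tm_C, "degC")
```

prints

```
R1 = 0.0904 1/s, R2 = 231.3 1/s, tau_c = 162.1 ns
residue 1: tau_c = 4.92 ns
residue 2: tau_c = 4.96 ns
residue 3: tau_c = 4.98 ns
Kd = 0.494, dG0 = -1.82 kJ/mol
Tm = [73. 81.] degC
```

The first line shows the τ_c estimator inverting the forward-computed rates
of a rigid, isotropically tumbling NH vector to within 1% of the 163.4 ns
input (the small deficit comes from the neglected high-frequency spectral
density terms).  The next lines recover a 5 ns tumbling time per residue
from raw synthetic bond vectors through the complete chunked-C(t) → fit →
J(ω) → rates pipeline.  The kinetics block recovers the stationary odds of
the generating Markov chain (truth: K_d = 0.5, ΔG⁰ = −1.79 kJ/mol at
310 K), and the melt analysis finds the two disassembly transitions within
one 1 °C grid step of the true 72/81 °C midpoints (the forward-difference
derivative is assigned to the upper step temperature, which can shift a
peak by one step).

A `taildyn` command-line interface wraps the same machinery
(`taildyn csp|relax|md2nmr|contacts|network|melt --help`).

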