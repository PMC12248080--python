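# Methods

This note records the models implemented in `taildyn`, the assumptions they
make, the defaults and why they were chosen, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## Spin relaxation from bond-vector trajectories

Backbone amide ¹⁵N relaxation in a disordered tail is driven by the ¹⁵N–¹H
dipolar interaction and the ¹⁵N chemical-shift anisotropy, both modulated by
reorientation of the NH bond vector.  The pipeline assumes:

* **Rank-2 autocorrelation.**  The relevant correlation function for
  dipolar/CSA relaxation is the second-Legendre one,
  C(t) = ⟨P₂(μ(s)·μ(s+t))⟩; the implementation evaluates it over all time
  origins via the outer-product/FFT identity and never uses the rank-1
  function.
* **Separable overall tumbling.**  Frames are first superposed on the rigid
  histone-core Cα atoms so the computed C(t) contains internal motion only;
  the overall rotation of the particle is then reintroduced as a
  multiplicative exp(−t/τ_rot) envelope.  This is exact when internal and
  overall motions are statistically independent — a good approximation for a
  tail on a particle tumbling two orders of magnitude more slowly.  The
  default τ_rot = 163.4 ns is the rotational correlation time of the intact
  nucleosome core particle.  The factorisation is verified directly against
  a co-simulated internal + overall process (`TestFactorization`).
* **Chunk averaging.**  C(t) is computed independently in 20 equal,
  contiguous trajectory chunks and averaged; any indivisible remainder (at
  most n_chunks − 1 trailing frames) is dropped.  The lag grid is truncated
  at half the chunk length, where the estimator variance starts to dominate.
  The chunk-to-chunk scatter provides a per-lag standard error that the
  fitting stage reuses (below).

### Tri-exponential spectral density

The (tumbled) correlation function is fitted with
C(t) ≈ Σᵢ aᵢ exp(−t/τᵢ), i ≤ 3, aᵢ ≥ 0, Σaᵢ ≤ 1, giving the analytic
spectral density J(ω) = (2/5) Σᵢ aᵢτᵢ/(1+(ωτᵢ)²).  Conventions and
numerical choices:

* The 2/5 rank-2 normalisation lives in J(ω), not in the dipolar constant;
  this single self-consistent convention is validated by the rigid-rotor
  inversion test (an inconsistent split would miss 163.4 ns by far more
  than the observed 0.8%).
* The amplitude sum is constrained to ≤ 1 rather than = 1 (a soft-barrier
  residual plus a final rescale); the convention is recorded on the model.
* **Variable projection with multistart.**  Candidate timescales come from a
  log-spaced grid on [0.01 ns, 2·τ_max] (τ_max = applied tumbling time,
  else the longest lag — timescales beyond twice the observation window are
  not identifiable); amplitudes are solved by NNLS per candidate tuple and
  the best starts are polished by bounded nonlinear least squares.
* **Lag weighting and subsampling.**  Lags are subsampled logarithmically
  (~64 points) because neighbouring lags of a sampled C(t) carry strongly
  correlated noise and a dense grid gives the long-lag tail spurious
  leverage.  When chunk-scatter SEMs are available, residuals are weighted
  by 1/SEM (floored at 10⁻⁴; the exact lag-0 point gets the largest finite
  weight): the very short lags of a well-sampled trajectory determine the
  decay rate to a fraction of a percent and should anchor the fit.
* **Parsimonious model order.**  The fit tries 1, 2, then 3 terms and
  accepts the smallest model whose weighted reduced χ² is ≤ 1, i.e. already
  consistent with the measured uncertainty; otherwise the lowest-χ² model
  wins, with ties broken toward fewer active terms.  The rationale: a slow
  exponential fitted to statistically insignificant long-lag structure
  contributes aᵢτᵢ to J(0) and can double the apparent R₂ even at
  aᵢ ≈ 0.01.  For correlation functions without uncertainty estimates
  (single-chunk or analytic input) the χ² threshold is meaningless and only
  the lowest-residual rule applies.  Near-duplicate timescales
  (ratio < 1.05) are merged; fits with RMS residual above 0.02 carry a
  poor-fit flag rather than raising.
* **Frequency-domain cross-check.**  J(ω) is also available as a numerical
  cosine transform of the reconstructed C(t) (trapezoidal quadrature with a
  step resolving both the fastest timescale and the highest frequency, and
  a 12·τ_max horizon); the analytic route is primary and the transform
  serves as an independent oracle, which agrees to < 1% out to twice the
  proton frequency.

Rates use the standard expressions with r_NH = 1.02 Å, Δσ(¹⁵N) = −170 ppm,
c = ω_N Δσ/√3 — field-standard values for backbone amides.  ν_N is a linear
frequency in Hz (60.8 MHz at a 600 MHz spectrometer); the 1/(4π ν_N)
prefactor of the τ_c estimator is dimensionally consistent only then.  The
NOE keeps the sign of γ_N.  τ_c is reported as NaN (fast-tumbling flag) when
6R₂/R₁ − 7 < 0.

## Experiment-side analysis

* CSPs combine shifts as √(Δδ_H² + 0.154·Δδ_N²); residues missing on either
  side of a comparison (prolines, exchange-broadened peaks) are explicit
  flagged gaps, never zeros.
* Decay fits use intensities (not log-intensities) against
  I(t) = I₀ exp(−Rt) with no offset.  Duplicate delays are kept as
  independent observations.  Two rate uncertainties are reported: the
  covariance-based one and, when repeated delays exist, one anchored to
  their pooled scatter — the data alone cannot say which the reader wants.
* τ_c uncertainties propagate first-order through R₂/R₁ and the square
  root (verified against finite differences).

## Contact kinetics

Contacts are strict d < 4.0 Å between heavy atoms, sampled every 1 ns;
KD-tree candidate search is confirmed by exact distances so results are
cell-identical to an all-pairs scan, and periodic images are ignored (the
solvated particle does not approach its images).  The full tail is unbound
in a frame when **no more than** 10% of its residues keep a contact — the
threshold comparison is inclusive, and all tail residues count in the
denominator (the residue range is configurable).  Events are maximal
constant-state runs tiling the timeline; the 50 ns minimum-residence filter
applies only to reported residence-time statistics, while transition counts
always use the unfiltered tiling (`n_transitions` counts all state changes,
with binding and unbinding also reported separately).  No duration filter is
applied to unbound segments when counting transitions.  K_d is the
unbound/bound frame ratio with ΔG⁰ = RT ln K_d at the 310 K simulation
temperature (R = 8.314 J mol⁻¹ K⁻¹, output in kJ/mol); if either frame
count is zero K_d and ΔG⁰ are NaN with the counts still reported.  The
radius of gyration is mass-weighted about the selection's centre of mass.

## Interaction networks

A deliberately simple geometric surrogate for ensemble interaction-network
analysis: only hydrogen-bond (donor–acceptor N/O within 3.5 Å, ≥ 120°
donor–H⋯acceptor angle when hydrogens exist, distance-only otherwise) and
van der Waals (heavy-atom pair within Bondi radii + 0.5 Å) classes are
implemented; ionic and π-system classes need charge-group and
aromatic-plane geometry outside this scope.  All cutoffs are configurable.
"Fraction of trajectories" is read as fraction of extracted frames (states
and frames coincide in the extraction protocol: every 10 ns, five runs, two
tail copies pooled → 2000 states).  Edges never observed are absent rather
than probability-0; adjacent-residue pairs stay in the graph but are masked
in contact-probability maps, where their trivially persistent contacts
would dominate.

## Thermal shift

Normalisation is per replicate over that replicate's full temperature range
(min → 0, max → 1); the derivative is a forward difference assigned to the
upper step temperature, which biases a detected peak by at most one grid
step upward — tests and documentation treat "within one grid step" as
agreement.  Peaks are local maxima of the derivative with prominence at
least max(10% of the global maximum, 5 robust noise SDs), the noise SD
being 1.4826·MAD of the derivative series.  The 10% floor reproduces the
by-eye identification of clear transitions and suppresses the attenuated
second step seen at elevated salt; the MAD term keeps replicate noise on a
fine grid from masquerading as a transition (with 2% noise and three
replicates on a 1 °C grid, the derivative noise floor exceeds a pure 10%
rule).  Buffer-only control subtraction is off by default.  Melting
temperatures are reported at grid resolution.

## Synthetic generators

The generators emulate the *statistical structure* of the real inputs — and
nothing else.  They are deterministic under a fixed seed, with independent
streams spawned from one seed hierarchy, and every artifact carries its
generating parameters.

* **Rotational diffusion**: Gaussian tangent-plane steps on the unit sphere
  with per-axis SD √(2D dt), D = 1/(6τ_rot) — the discretisation whose
  rank-l autocorrelation converges to exp(−l(l+1)Dt), so the P₂ law is
  exactly exp(−t/τ_rot).  The step must satisfy dt ≤ τ_rot/10.
* **Internal motion**: diffusion in a cone about z with reflecting
  boundary; the half-angle solves S = cos β(1+cos β)/2 (the β = π branch is
  taken at S² = 0), making the long-time plateau exactly S².  The wobble
  coefficient D = (1−S²)/(6τ_e) is exact in the free-diffusion limit and
  gives a measured effective internal decay of ~1.2–1.5·τ_e at S² = 0.5 —
  adequate for every consumer here, since J(0) depends on the internal time
  only through the small (1−S²)·τ_e τ_rot/(τ_e+τ_rot) term.
* **Two-state timelines**: alternating geometric dwells (the discretised
  exponential), contact emission with probability p (default 0.5) per
  residue per bound frame and a 2% · p unbound background so the 10%
  state-calling rule is exercised against a nonzero noise floor.  With 36
  residues and these defaults, state calling is essentially error-free
  (misclassification ≈ 4·10⁻⁴ per unbound frame), so recovered kinetics
  reflect the hidden chain.
* **Intensity decays / melt curves**: exact forward models plus Gaussian
  noise; the experimental relaxation delay schedules (including repeats)
  are shipped as defaults, as is the 25–95 °C, 1 °C instrument grid.  Melt
  amplitudes default to an equal split summing to 1, so `noise_sd` reads as
  a fraction of total amplitude; the default logistic steepness of 0.8 °C
  gives transitions ~4 °C wide, typical of dye-based nucleosome melts.
* **Toy nucleosome**: a static paired-bead DNA arc and scripted mobile tail
  chains (3 Å from assigned DNA beads when bound, ≥ 20 Å otherwise), plus
  four core beads for superposition.  The script *is* the oracle for every
  downstream contact/network statistic.

What passing these tests does **not** show: the generators contain no
force-field physics, no sequence specificity, no salt dependence, no real
spectral overlap or baseline artefacts.  Agreement on synthetic data
validates the estimators, not any biological claim about real nucleosomes.

## Problem sizes

The validation suite runs at desk scale by design: dynamics recovery uses
10 vectors × 10⁵ frames at 0.02 ns (2 μs equivalent), internal-motion
checks 3 vectors × 2·10⁵ frames, kinetics 10⁶ ns at 1 ns stride, melt
recovery 100 seeds of 3 replicates, and network bookkeeping five 2000 ns
toy runs.  These sizes put the estimators' sampling errors comfortably
inside the stated tolerances while keeping the whole suite under a minute
of compute per heavy module.

## Known limitations

* Absolute predicted R₂ values for real tails are expected to exceed
  measured ones when trajectories under-sample the conformational ensemble;
  the package targets trends and internal consistency, not absolute R₂.
* The τ_c estimator is undefined below R₂/R₁ = 7/6 and the pipeline reports
  such residues as fast-tumbling gaps.
* Superposition uses one joint fit over all supplied core atoms (reference
  frame = first stored frame unless overridden); per-copy alignment is not
  implemented.
* The interaction-network surrogate is not a drop-in replacement for
  residue-interaction webservers; its cutoffs are sensible defaults, not a
  reproduction of any specific tool's typing rules.
* Exponential-fit model selection assumes the chunk-scatter SEM is a
  usable (if imperfect) noise scale; pathological inputs with wildly
  miscalibrated SEMs could over- or under-select model order.
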