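# Methods

## Partition model

A DNA structure distributes between the dextran-rich droplets and the
PEG-rich continuous phase of a PEG/dextran aqueous two-phase system.
The mechanistic picture is that semiflexible double-stranded DNA can
penetrate the nanoscale cavities of the dextran-rich phase whereas the
PEG-rich phase is filled with flexible chains, so large DNA objects
accumulate in the droplets while short single strands have almost no
preference. We collapse this into a single-parameter surface-area law
(Brønsted/Albertsson form):

    K(A) = exp(min(λ_eff · A, ln K_cap)),   K ≥ 1,

with A the structure surface area in nm². λ_eff is an *effective*
interfacial free-energy per unit area (kT·nm⁻²) that lumps together
size, shape, flexibility and charge contributions; it is deliberately
kept as one fit-able constant (see *Calibration*) rather than being
decomposed, since the decomposition is not identifiable from yield data
alone. Defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| `lambda_eff` | 5·10⁻⁴ | nm⁻² (kT per nm²) | gives a 5 nm staple K ≈ 1.04 (a slight droplet preference) while flat origami (≥10⁴ nm²) partitions ≥97 % into the droplets |
| `K_cap` | 10⁶ | – | numerical clamp; beyond it retention is indistinguishable from 1 |
| `V_total_uL` | 40 | µL | dispersion volume after each replenishment |
| `V_droplet_uL` | 2 | µL | lever-rule estimate: ≈0.83 wt% total dextran in the dispersion at ~15 wt% dextran in the droplet phase |
| `retained_volumes_uL` | 15, 15, 5 | µL | the typical three-round bench protocol |

K is defined as droplet:continuous concentration ratio and constrained
to K ≥ 1: under these conditions DNA is never observed to prefer the
PEG phase.

## Fractionation recursion

Each round equilibrates completely (the dispersion is shaken and
centrifuged), then supernatant is removed down to f_n µL — which always
contains the entire droplet phase — and fresh PEG-rich phase restores
V_total. With V_c = V_total − V_d, the droplet share at equilibrium is
p = K·V_d/(K·V_d + V_c) and the per-round retention is

    r_n = p + (1 − p)·(f_n − V_d)/V_c.

Retained and discarded fractions sum to one exactly; r reduces to
f_n/V_total at K = 1 and tends to 1 as K → ∞. Cumulative yield is the
running product Yⁿ = Π r_i (Y⁰ = 1, non-increasing). Whether the kept
supernatant share should count as retained is genuinely open; both
conventions are supported (`keep_supernatant_share`), with the
supernatant-keeping form as the default because the protocol physically
retains that volume in the tube.

Protocols with more than three rounds repeat the 15 µL step and keep
the 5 µL step last; fewer rounds truncate the typical list. Under this
template the unbound-staple yield crosses 10 % exactly at three rounds
(37.6 % → 14.2 % → 1.8 %), which matches the bench observation that
three or more rounds are needed; ending every variant with the small
5 µL round instead would make two rounds suffice and contradict that
observation, so the truncation convention was chosen.

Dissociating assemblies are a known limitation: Y-motif hydrogels shed
monomers as free motifs are washed out, a coupled equilibrium the
fixed-size simulator does not represent. Droplet-interface accumulation
of origami is likewise not modelled.

## Efficiency statistic and landscape

For a target/contaminant pair, E = (Y_t − Y_c)/(Y_t + Y_c) ∈ [−1, 1]
(antisymmetric; 0/0 is an error). The landscape evaluates E on a
log-spaced grid of contaminant area A_c ∈ [10, 10⁹] nm² × area ratio
A_t/A_c ∈ [1, 10⁶] (200×200 by default, three rounds), vectorised over
the grid; cells agree with independent scalar simulation to machine
precision. Three regimes emerge: E → 1 for small contaminants with much
larger targets; E = 0 on the ratio-1 diagonal; E → 0 at large A_c where
both species saturate the droplets. Internally E is a fraction;
percentages appear only in reports. The absolute contour positions
depend on λ_eff, which is an effective reconstruction, so the landscape
*shape* — not exact contour placement — is the validated surface.

`min_rounds_to_purity` walks the protocol template up to a configurable
cap (default 20 rounds) and reports the smallest n with Yⁿ below the
threshold, or a sentinel (`n=None`) with the plateau yield and the
limiting per-round retention when the threshold is out of reach.

## Densitometry

Lane profiles are two-column (position, intensity) tables in either
orientation. The baseline is asymmetric least squares (ALS): minimise
Σ w_i (y_i − z_i)² + λ_s Σ (Δ²z_i)², w_i = p for y_i > z_i and 1 − p
otherwise, iterating weights to a fixed point (cap 10 iterations,
warning on non-convergence). Defaults λ_s = 10⁵, p = 0.01 are standard
ALS practice for smooth backgrounds under sharp peaks. The sparse
solver path is validated per-iteration against a dense solve of the
same normal equations on small profiles (10⁻⁸ relative).

Band area is the trapezoidal integral of max(y − z, 0) over a
user-selected region; negative residuals are clipped so noise cannot
produce negative areas (the clipping convention is a package decision).
Two numerical properties matter in practice: ALS is exact on affine
profiles (lines are in the curvature penalty's null space), and with
asymmetry p = 0.01 the converged baseline sits ≈1.7 noise-sd *below*
the true background under iid noise — a known property of asymmetric
weighting. Band regions should therefore be kept tight around the
visible band (≈±3 sd) so the accumulated offset stays small relative to
the band mass.

Relative band intensity = 100·(sample area)/(reference area), the yield
proxy; values above 100 % are allowed (polymer residues enhance SYBR
Gold fluorescence). Cleavage ratio = 100·F/(F + S) for a
fragment/substrate band pair. `measured_efficiency` feeds relative
intensities into E on the percent scale. Replicate ± values are
reported as mean ± sd over whatever replicate lanes the user provides;
no particular replicate convention is assumed. A local-maxima band
suggester exists but is explicitly a heuristic — regions are normally
chosen by the analyst.

## Synthetic data

Lane profiles: sum of Gaussian bands (each normalised to its requested
integral), a polynomial baseline of degree ≤ 3, and iid Gaussian noise
whose sd is a fraction of the tallest band peak. Truth records carry
band areas, ±5 sd band windows, the exact baseline, the absolute noise
sd and the seed. Fractionation observations: model yields at a known
λ_true plus clipped Gaussian noise, with the noiseless yields recorded.
One seeded `numpy.random.Generator` per spec; identical seeds give
bit-identical output. What the generators do *not* emulate: skewed or
saturated bands, lane-to-lane gel distortion, multiplicative
fluorescence effects, or structure dissociation during purification —
so passing recovery tests demonstrate correctness of the quantification
chain, not robustness to every real-gel artefact.

The recovery suites run at deliberately modest sizes — 512-point lanes,
100 seeds, five catalog structures per calibration — which keeps the
whole test battery in the low seconds while leaving the statistics
stable.

## Calibration

`calibrate_lambda` minimises squared (or absolute) yield residuals over
λ_eff ∈ [0, 10⁻²] nm⁻² by bounded scalar minimisation. Identifiability
comes from structures whose yields respond to λ in mid-range
(for the defaults, the ~7·10³ nm² triangular sheet dominates the
gradient); observations that are clamped or pinned for every candidate
λ trigger a degenerate-fit warning. Noiseless round-trips recover
λ_true to optimizer precision; at yield noise sd 0.02 the median
recovery error over 100 seeds is ≈2 %.

## Geometry conventions

Sphere πd²; discs and prisms count both faces plus the lateral rim
(hexagon face (3√3/2)s² with circumradius s; equilateral triangle side
a = R√3, face (√3/4)a²); cylinders are closed; tile tubes are
open-ended and count inner + outer lateral surface (2πdL), no caps.
Catalog dimensions not taken from measured sizes are package defaults
flagged in `assumed_dims`: 24HB diameter 13 nm (typical 24-helix
honeycomb bundle), Y-motif as a 5 nm sphere (staple-like), tube
diameters 8 nm (4-helix tile) and 14 nm (13-helix tile), and
hydrogel/microtube size ranges 200 nm–5 µm. All are overridable via a
user YAML catalog.
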