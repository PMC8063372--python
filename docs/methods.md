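# Methods

`channelscale` profiles the atomic environment around an ion-channel pore
with a family of cumulative, sphere-sampled functions, and uses them to
score missense variants by structural proximity to two landmarks: the
hydrophobic patch lining the pore and a scaling-critical point near the
selectivity filter.  This note records the model, the numerical choices,
what the synthetic generator emulates, and the known limitations.

## Frame and pore geometry

A protonated structure is read from PDB (hydrogens are kept: the hydropathy
moments weight every atom, including hydrogens).  The mass-weighted atomic
center is moved to the origin and the pore axis is mapped onto +z.  The
axis is the mass-weighted inertia eigenvector with the largest |dot|
against a user-supplied approximate pore direction (default: the input
file's +z); only the minimal (Rodrigues) rotation taking that eigenvector
onto +z is applied, so an already-aligned structure is left untouched and
there is no arbitrary in-plane re-orientation.  The annotation file states
which z end of the input frame is extracellular; the canonical frame keeps
the extracellular side at low z, so +z points extracellular → intracellular
and a positive axial moment ("in" orientation) points intracellularly.

Pore points are traced slice by slice (default spacing 1 Å) over the z
range covered by the pore-lining residues: at each z the in-plane position
maximises the clearance radius

    R(p) = min_i (‖c_i − p‖ − vdW_i)

by Nelder–Mead direct search (position tolerance 0.05 Å), warm-started at
the previous slice and softly confined to a 5 Å search disc around it.
Negative clearance (an occluded gate) is recorded, not clipped.  Each pore
point also carries the nearest-atom distance D(p) = min_i ‖c_i − p‖ and the
outer surface radius L(p) = max_i (‖c_i − p‖ + vdW_i).

## Atom packing and the sigmoid partition

The environment of p is sampled with K_α concentric spheres,
l_α = D(p) + α·(L(p) − D(p))/K_α (α = 1..K_α; default K_α = 800, the map
resolution used for the published-scale maps; the bundled toy analyses use
200).  The atomic CDF N(p, l) counts atoms with ‖c_i − p‖ ≤ l (an atom
exactly on the sphere counts, which makes N(p, L(p)) = N_c exact).

Four re-parametrised growth models are fitted to N(p, ·) by bounded
least squares (scipy `least_squares`, TRF): Logistic, Gompertz, modified
Gompertz (a Gompertz plus a second exponential increase with parameters w,
l_shift) and Richards with shape q̃.  Richards reduces exactly to the
Logistic at q̃ = 1 and to the Gompertz as q̃ → 0.  Initial guesses: A₀ =
max count, t₀ = max finite-difference slope, s₀ from the max-slope point,
q̃₀ = 1; A and t are bounded positive, q̃ ∈ [1e-4, 50].  The selected
family minimises AIC = n·ln(RSS/n) + 2k (no small-sample correction).
Fitting is on raw counts; normalisation by N_c is used for summaries only.

The selected model defines the packing partition: the lag domain ends at
s(p); the inflection scale ξ(p) is the root of the model's second
derivative (closed forms: s + A/2t for the Logistic, s + A/(e·t) for the
Gompertz, s + (1+q̃)/k for Richards; a numeric root for the modified
Gompertz), where the radial distribution function peaks at the maximum
packing rate t(p); and the asymptote domain starts at o(p) = s(p) + A/t
(from the identity t = A/(o − s)).  The pore-module→voltage-sensor
transition scale ν(p) is the smallest l_α at which the cumulative
voltage-sensor atom count overtakes the pore-module count (requiring at
least one pore-module atom inside, so the empty-sphere case does not
trigger vacuously).  Summary descriptors are medians over pore points with
converged fits, plus a per-α 2.5/97.5 percentile band of the normalised
CDF.

## Hydropathy moments and topology

Each atom carries a hydropathy index from a (residue, atom)-keyed table
plus a weak seeded Gaussian perturbation (σ = 0.001 kcal/mol), which keeps
the cumulative moments away from exact zeros without affecting their
scaling.  The shipped table (`data/hydropathy_synthetic.tsv`) is a
synthetic per-atom scale built from a polar/apolar chemical-group
classification — ±0.25 kcal/mol with hydrophobic positive; the sign
convention is declared in the file and switchable via `hydrophobic_sign`.

The zero-order moment h⁰(p, l) sums the perturbed indices inside the
sphere; the hydropathic density is m⁰ = h⁰/N.  The first-order moment
h¹(p, l) = Σ HIʷ_i (c_i − p) measures hydropathic imbalance; its axial
per-atom component m¹_z = h¹_z/N defines the "in"/"out" orientation states
by sign.  Cells with N = 0 are undefined (NaN), never 0/0.

Topology of a (p, α) field: zero crossings are sign changes between
adjacent α cells of one row, with the crossing radius l* linearly
interpolated; domains are 4-connected components of same-sign cells,
labelled T1, T2, ... by descending area (ties by first cell, so labels are
reproducible).  Exactly-zero cells side with the positive sign.  The
hydrophobic-patch boundary Ω⁰ keeps the crossings adjacent to hydrophobic
domains that touch the pore-lining low-α band (the first defined cell of a
row).

## Scaling criticality

On a scale-invariant stretch |m¹_z(p, l)| ~ l^γ(p); γ is estimated by
ordinary least squares on (ln l, ln |m¹_z|), with the mean absolute
relative fitting error (MARFE ± sd) reported in natural space.
Around the selectivity filter the piecewise pattern splits at ξ(p):
expansion (γ_I > 0) on (s, ξ] and contraction (γ_II < 0) on (ξ, o].  The
atom-packing energy proxy is U = |h¹_z|/l, modelled per phase as
n(p, l)·l^(γ−1) with the selected sigmoid n and a log-space multiplicative
constant per phase; extrapolations beyond (s, o] are reported separately
and never used for selection.

Critical-point selection: candidates are pore points within an axial
window (default ±6 Å) of the selectivity-filter residues' geometric
center whose piecewise exponents satisfy γ_I > 0 > γ_II.  Among them the
winner maximises the peak |m¹_z| over its (s, o] range — at the critical
point both the range and the intensity of the axial field maximize.  A
MARFE-minimising rule was tried first and rejected: axial offset smears
the break, and smeared (off-center) profiles are *better* fitted by
piecewise power laws than the sharp break at the true critical point, so
MARFE minimisation systematically drifts away from the filter.  MARFEs are
still computed and reported as fit-quality diagnostics.  If no candidate
satisfies the sign pattern an explicit no-critical-point result is
returned.

## Variant scores and classification

A mutation site is a distinct (residue, label) pair; multiple
substitutions at one residue collapse to one mapped site but remain listed.
Its structural location is the wild-type residue's heavy-atom centroid
(Cα and all-atom alternatives selectable).  Map projection: nearest pore
point p*, then the smallest α with l_α(p*) ≥ distance (inclusive boundary,
clamped to K_α with a warning); the 3-D site-to-p* distance is recorded
because map and 3-D distances genuinely differ on a skewed pore.

Distance scores: d_HP is the median over Ω⁰ elements of
| ‖site − p_j‖ − l*_j | (each boundary element treated as a spherical
locus), with a 2.5/97.5 percentile band; d_SF = | ‖site − p_crit‖ −
ξ(p_crit) |, the distance from the critical sphere; d_w = w·d_HP +
(1−w)·d_SF with w ∈ [0, 1] (default 0.5).

ROC analysis is oriented low-score-predicts-pain.  Thresholds sweep the
midpoints of sorted unique scores plus ±∞; the AUC is the trapezoid area,
which equals the pairwise-concordance (Mann–Whitney) statistic with ties
counted ½ — the implementation keeps both and the tests require exact
agreement.  The reported operating point maximises Youden's J with ties
broken toward higher specificity, then toward the smaller threshold.

## The synthetic toy channel

The generator (`channelscale.synthetic`) builds a fully specified channel
analogue (~2,900 atoms by default) whose every planted feature is emitted
as ground truth:

* a pore-lining cylinder (radius 9 Å, 16 atoms/slice, 31 slices over
  ±30 Å) around a sinusoidal axis phased to be flat at the filter, so the
  designed axis and the max-clearance path agree to within the jitter;
* a selectivity filter of two staggered 20-atom rings (radius 6 Å) at the
  pore midpoint — dense enough that the clearance optimiser cannot dodge
  sideways through angular gaps;
* a bulk of 1,200 two-atom clusters whose distances from the filter center
  are drawn from the *complement* of a truncated-logistic radial density
  (the target minus the deterministic lining contribution), so the total
  packing CDF around the filter is sigmoid by construction.  The planted
  break ρ* is the Richards inflection of the designed expected CDF,
  computed by a self-contained fit inside the generator (independent of
  the analysis code path).  Clusters nearer the axis than 18 Å count as
  pore-module material, the rest as voltage sensors, which places ν just
  above ξ — the ⟨ν⟩ ≈ ⟨ξ⟩ feature of the channels this emulates;
* planted hydropathy: a hydrophobic band on the lining (recoverable from
  the low-α sign of m⁰) and, on the bulk, an axially antisymmetric pattern
  whose sign reverses on the ρ* sphere — softened outside (factor 0.3) and
  blended over ±0.8 Å so the contraction does not swamp the expansion
  interval and the piecewise misfit grows smoothly with axial offset;
* planted variant sites: residues whose centroids lie on the ρ* shell
  (pain) or far off it (neutral), plus free-standing site generators for
  jitter/separation studies.

Planted indices are carried through the full I/O path: atom names encode
the hydropathy class and a companion lookup table reproduces them exactly,
so reading the PDB + table gives bit-identical indices.

What the toy channel does **not** emulate: real amino-acid chemistry and
packing correlations, side-chain geometry, the heterogeneity of real
hydropathy values, sequence-dependent variant effects, and a realistic
pore profile (its constriction is a thin ring, not a tapering vestibule).
Passing fixture tests therefore demonstrates correctness of the operators
and recoverability of planted structure, not biological performance on
real channels.

## Numerical choices and degenerate inputs

* Heaviside boundary: θ(0) = 1 everywhere (sphere counts are inclusive).
* Power-law fits need ≥ 5 positive in-interval points; nonpositive
  magnitudes are filtered with a warning, too few points flag failure
  rather than raise.
* Sigmoid fits need ≥ 10 grid points; integer counts must be
  nondecreasing, float series (noisy fixtures) are accepted as-is.  A
  non-converged fit is flagged and excluded from medians.
* Blocked pores (R ≤ 0) warn and record the negative clearance.
* Collinear structures have no defined pore frame and are rejected.
* Analysis problem sizes in the bundled tests and the acceptance script:
  toy channel ≈ 2,900 atoms, ≈ 60 pore points, K_α = 200 — chosen to keep
  the fixture studies quick while leaving every scale well resolved
  (grid step ≈ 0.15–0.25 Å).

## Limitations

* The published-scale results for NaV1.7 require the homology model, which
  is distributed only with permission; without it the pipeline runs on any
  protonated PDB plus a segment annotation, and the bundled variant table
  carries synthetic filler rows (only the variants named in the literature
  text are real).
* The shipped hydropathy table is a synthetic chemical-group
  approximation, not the published per-atom scale; swap in a measured
  table via `--hydropathy` for production use.
* ν(p) and the critical-point selection rule are reconstructions of
  procedures whose originals are only named in the source material; both
  are documented above and kept behind stable interfaces.
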