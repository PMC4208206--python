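# Methods

This note documents the models implemented in `watercolumn`, the
parameters that matter, what the synthetic data emulate (and what they do
not), and the numerical choices made where the design was open.

## Radiometric conventions

All spectra are wavelength-indexed vectors on [350, 1000] nm carrying an
explicit quantity kind and interface side. The working range for
correction is the visible, 400–700 nm at a 1-nm default step: beyond
700 nm pure-water absorption extinguishes the bottom signal within the
first metre, so nothing there constrains benthic retrievals.

Irradiance reflectance R = E_u/E_d is dimensionless; remote-sensing
reflectance ρ^RS = L_w/E_d carries sr⁻¹. Both the water body and the
bottom are treated as Lambertian reflectors, so R = π·ρ^RS and the bottom
radiance term enters the semi-analytical model as ρ_b/π. The air–water
interface conversion

    ρ^RS(0⁻) = ρ^RS(0⁺) / (0.5 + 1.5 ρ^RS(0⁺))

and its algebraic inverse form an exact round trip; operations validate
kind and side and refuse mismatched inputs rather than guessing.

## Bio-optical model

`build_iops` maps a constituent set to inherent optical properties on the
grid:

    a(λ)  = a_w(λ) + chl · a*_phy(440) · s_phy(λ)
          + a_CDOM(440) e^(−S_cdom (λ−440)) + a_d(440) e^(−S_d (λ−440))
    b_b(λ) = 0.00144 (λ/500)^−4.32             [pure water]
          + chl · 0.0006 (λ/500)^−0.37         [phytoplankton]
          + C_MieII · 0.0042 (λ/500)^n         [Type-II particles]

with defaults S_cdom = 0.014 nm⁻¹, S_d = 0.011 nm⁻¹,
a*_phy(440) = 0.03 m² mg⁻¹. All of these are keyword-configurable.

Choices made here, and why:

* **Pure-water absorption** ships as a packaged CSV of representative
  literature values on a 10-nm grid (Pope & Fry-style), interpolated
  linearly to the working grid. Only the 400–700 nm range is tabulated;
  requests outside raise.
* **Phytoplankton absorption shape** s_phy(λ) is a smooth two-Gaussian
  curve with maxima near 440 nm (Soret) and 675 nm (red), normalized to 1
  at 440 nm. No measured pigment basis is claimed; every downstream
  assertion uses only its relative behavior.
* **The phytoplankton backscattering term** is read as
  chl · 0.0006 · (λ/500)^−0.37 m⁻¹, the three-term structure the
  parameterization follows (water + phytoplankton + Mie particles); the
  coefficient and exponent are arguments so other readings can be swapped
  in.
* **Type-I particles** appear in the water-type definitions but have no
  separate scattering term; a configurable coefficient
  (`particles_i_coeff`, default 0) folds them into the Type-II term if a
  user wants them active. Their concentrations are retained so the
  canonical water types round-trip exactly.
* **K_d closure**: K_d = (a + b_b)/cos θ_s, the plane-parallel
  single-path closure. It is deliberately the simplest choice consistent
  with the two-flow model's use of one attenuation coefficient for both
  directions; `IOPSet` accepts any externally supplied K_d.

Four canonical water types (a–d) span chl 0.01–9 mg m⁻³,
a_CDOM(440) 0.0017–0.3 m⁻¹, Type-II particles 0–2.2 mg L⁻¹, detritus
a_d(440) 0–0.5 m⁻¹, with Mie exponent −1 for the clear pair and 0 for the
turbid pair.

## Forward models and the deep-water end member

The two-flow model and the semi-analytical model are implemented exactly
as stated in the README. The optically deep end member is closed with the
quasi-single-scattering polynomial ρ^RS_∞ = (0.084 + 0.17u)u, chosen for
internal consistency with the semi-analytical family; it is passed in as
an argument everywhere, so image-derived or radiative-transfer deep
spectra can replace it.

The three bottom spectra are parametric: coral sand rises linearly
0.25→0.5 across 400–700 nm; green algae has chlorophyll troughs at 435
and 675 nm, a green peak near 550 nm and peak albedo 0.15; brown algae
has a depressed blue, a shoulder near 575 nm, a 675-nm trough and peak
albedo 0.12. These are stand-ins for measured reef spectra: tests and the
benchmark only rely on their relative/shape properties (sand brighter
everywhere, algal red troughs, distinct shapes), not on absolute values.

## Inversions and validity

Each algebraic corrector is the exact algebraic inverse of its forward
model, so same-model round trips recover ρ_b to machine precision — until
the attenuation factor underflows. Retrievals therefore carry
per-wavelength flags governed by one shared configuration
(`ValidityConfig`):

* `out_of_range` — retrieved ρ_b outside the open interval (0, 1);
* `exponential_regime` — bottom-path attenuation factor below 0.0002
  (for the two-flow model the same numeric threshold is applied to
  e^(−2K_d z), adopted for symmetry since only the semi-analytical
  threshold is stated);
* `low_contribution` — bottom contribution below 0.5% of the surface
  signal;
* `deep_exceeds_signal` — undefined ratios (zero denominator / zero
  truth).

Bottom contribution is accounted as the bottom term of the respective
forward model over the total signal:
(ρ_b − R_∞)e^(−2K_d z)/R·100 for the two-flow model and
(ρ_b/π)e^(−(1/cosθ_s + D_uB/cosθ_v)k z)/ρ^RS·100 for the semi-analytical
one, which makes an exposed bottom exactly 100% in both accountings.
Because the two-flow numerator subtracts R_∞, a bottom darker than the
deep-water reflectance has negative contribution; in clear water the
λ^−4.32 pure-water backscatter makes the blue R_∞ bright enough that a
dark mixed bottom is undetectable below ≈435 nm even at zero depth. The
detectable-wavelength-range operation reports the longest contiguous
passing interval per depth; intervals are nested across depth.

One printed-formula ambiguity is resolved here deliberately: the
single-term exponential correction is exposed as ρ_b = R_w·e^(+g·K_d·z)
with g configurable (default 2, the two-way path; g = 1 gives the one-way
variant). A literal one-way *negative* exponent would attenuate rather
than correct and is not offered as a default. Similarly, the depth-free
pseudo-depth correction computes Z_α as the mean over bands of
ln ρ^RS_i/(−2K_d,i) — the per-band division is forced by requiring the
self-consistency case (ρ^RS_i = e^(−2K_d,i Z)) to return Z exactly when
K_d varies by band.

## Band-combination algorithms

All indices operate on deep-water-subtracted signals v_i − deep_i, whose
logarithm is linear in depth under single-exponential attenuation.
Non-positive differences are flagged (NaN in index outputs, explicit
pixel lists in errors), never clipped or dropped silently, so downstream
statistics can exclude them deliberately. The two-substrate sequential
partition thresholds each index at the midpoint of the training-class
means — the simplest reproducible rule for a procedure whose original
"statistical analysis" step is unspecified. The three fixed-coefficient
indices default their additive offsets h to 0. The known-depth index uses
geometric factor q = 2 at nadir (two-way vertical path) and can estimate
K_d·q by regression on depth when K_d is not supplied.

## Library matching and mixture inversion

The spectral library is the Cartesian product of constituent grids
(16 chl × 7 a_CDOM × 7 Type-II particle values), 16 depths (1–16 m) and
the three pure bottoms, rendered through the semi-analytical forward
model and converted above-surface — 37,632 entries — plus the 48
noiseless scenario spectra themselves, since the classification
experiment's queries are noisy versions of those spectra. Detritus and
the Mie exponent stay at clear-water values (0, −1) in the grid portion:
the turbid water types c and d are therefore *not* exactly representable
in the library, which is precisely where the residual confusion occurs.
Ordering is deterministic (water, depth, bottom) and hashable for
reproducibility. Classification is exhaustive minimum spectral angle
(scale-invariant by construction); ties break to the first entry.

Noise is multiplicative Gaussian per band, v·(1 + ε) with
ε ~ N(0, level), truncated so reflectance stays non-negative; the
canonical experiment uses level 0.05 with 25 independent seeded
realizations spawned from one master seed.

The mixture inversion fits seven bounded parameters — a_phy(440),
a_g(440), b_bp(440), three endmember scaling coefficients B_e and depth
z — by trust-region reflective least squares, restarting from the box
centre plus five Latin-hypercube points (the landscape is multimodal when
depth and brightness trade off). Inside the optimizer the bottom is
ρ_b = Σ B_e R_e; with two endmembers and weights (g, 1−g) this is the
standard two-substrate linear bottom model. b_bp(λ) follows a λ⁻¹ power
law anchored at 440 nm and a_g uses the CDOM slope 0.014 nm⁻¹.
Non-convergence is reported in the result object, never raised.

## The inter-comparison harness

`run_intercomparison` executes, on the canonical 48-scenario grid
(4 waters × 4 depths {3, 5, 10, 15} m × 3 bottoms, nadir geometry):

1. same-model round trips for both models (max relative error over valid
   wavelengths, expected ≈ 1e-13);
2. a cross-model table — truth generated with the semi-analytical model,
   inverted with the two-flow model — reporting valid fractions and mean
   |uncertainty| per scenario; uncertainty is the signed percentage
   (ρ_b,retrieved − ρ_b)/ρ_b·100 and grows with the optical path 2K_d z.
   This stands in for the original study's radiative-transfer-vs-model
   mismatch, which is not reproducible here;
3. the seeded SAM/LUT experiment with its 3×3 confusion matrix (row sums
   16 per seed), per-class accuracies averaged over seeds, a noiseless
   control (exactly diagonal, since the noiseless queries are library
   members) and an off-diagonal tally per water type.

The sensitivity analysis perturbs one input at a time by a factor
(1 + δ), δ ∈ [−0.95, +1.0], recomputes the inversion, and reports
100·|ρ_b1 − ρ_b2|/ρ_b1. The baseline ρ_b1 is the *retrieval* at δ = 0
(the same code path), so the zero perturbation is exactly zero. The
two-flow model accepts z, K_d, R_∞; the semi-analytical model z, a, b_b,
ρ_∞. In the most turbid water over sand at 10 m and 550 nm, a +50% K_d
overestimate moves the retrieval by ≈1700% — attenuation errors compound
exponentially with optical path, and anything beyond a few hundred
percent simply means the retrieval there is an artifact.

## What the synthetic data do and do not show

The generators emulate the *structure* of the problem: exponential
attenuation, additive water/bottom signal split, constituent-driven
spectral shape, sensor band integration and uncorrelated radiometric
noise. They do not emulate inelastic processes (Raman, fluorescence),
vertical stratification, surface-wave noise in E_d profiles, sensor
striping, or adjacency effects; and the bottom spectra are parametric
shapes rather than measured reef substrates. Passing tests therefore
demonstrate internal consistency and correct algebra of every method, and
realistic *relative* behavior (which waters/depths/wavelengths are
recoverable), but not field accuracy for any specific reef. In
particular, classification accuracies depend on the angular separability
of the bottom shapes: with these parametric spectra the brown-algae class
separates more cleanly than measured brown algae typically do.

## Numerical and I/O choices

* Wavelength grids must match exactly between interacting objects;
  mismatches raise instead of interpolating silently.
* Scene correction is fully vectorized; flag rasters use bit codes (one
  bit per validity rule, bit 7 = no data; no-data value −9999).
* All serialization is plain text with `%.17g` floats, so readers and
  writers round-trip float64 exactly: spectra as two-column tables with a
  kind/side header, scenes as JSON-headed whitespace grids, libraries as
  CSV through a DataFrame.
* WorldView-2 band edges are not published at boxcar precision; edges
  default to midpoints between adjacent centers, clipped to [400, 950],
  with correction work restricted to centers ≤ 700 nm (five bands).
* Every random process takes a seed or Generator; multi-stage experiments
  spawn child streams from one master `SeedSequence`.

## Known limitations

* The deep-water polynomial closure underpins both forward models and the
  detectable-range accounting; scenes whose deep reflectance departs from
  quasi-single-scattering behavior should supply measured deep spectra.
* The pseudo-depth (hue-preserving) correction preserves band ratios
  exactly only under band-uniform K_d; in general the preserved invariant
  is the (1/2K_d,i)-root spectrum shape.
* The mixture inversion's parameter bounds are a design input; recovery
  guarantees hold for self-generated data inside the bounds, and real
  spectra with model mismatch can land on bound edges.
* No atmospheric or sunglint correction is included; inputs are assumed
  surface-level reflectance or radiance with land/cloud masking done.
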