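# Methods

This note records the models, conventions and numerical choices behind
`peptoidbj`, and what the synthetic-data tests do and do not demonstrate
about real measurements.

## Trace model and measurement conventions

Conductance is expressed as log₁₀(G/G₀), G₀ = 2e²/h = 77.48 μS; currents
convert via G = I/V at the applied bias (default 250 mV). The synthetic
pulling trace has four regimes: a metallic-contact descent from a
configurable ceiling (default log G/G₀ = 0.48, i.e. ≈3 G₀) to 1 G₀; a
snap-back past 0.5 G₀ to a post-rupture level (default −0.8); either a bare
exponential tunneling decay (default 5 decades/nm) or, with per-trace
Bernoulli probability `p_molecule`, a fast drop (default 25 decades/nm)
onto a molecular plateau whose level is drawn from a Gaussian (or mixture
of Gaussians) in log-conductance; and a final decay clamped at the
detection floor (default −6.5). Multiplicative noise is Gaussian in log
space on the post-rupture segment. The Bernoulli junction-formation model
is the trace-level realization of Poisson statistics at low analyte
concentration; its rate, the plateau length (deterministic at its mean by
default, optionally Gaussian), the slopes and the noise scale are all
explicit configuration, because only the qualitative trace anatomy matters
for exercising the analysis stages. Ground-truth labels (molecule present,
population index, plateau level and length) ride along with every trace.

Randomness: one root seed; per-trace child streams derived by counter
(`SeedSequence(seed, spawn_key=(i,))`), so enlarging an ensemble never
reshuffles earlier traces.

What the generator does **not** emulate: current-amplifier saturation and
drift, within-trace conformational plateau wander, stochastic retraction
speed, and multi-molecule junctions. Tests that pass on this generator
demonstrate that the analysis chain recovers known inputs under realistic
noise and background; they do not certify instrument-specific artifacts.

## Alignment

Traces are aligned at 0.5 G₀: the displacement origin is placed at the
*final* downward crossing of the alignment level, found by linear
interpolation in (displacement, log G); ties break toward larger
displacement. "Junction breakage at 0 nm" and "aligned at 0.5 G₀" are
reconciled by defining breakage as that final crossing — traces that
re-cross the level through noise are anchored at the last rupture.
Alignment is a pure translation (pairwise displacement differences are
preserved exactly) and is idempotent. Traces that never reach the level
are excluded and reported, never silently dropped.

## Histograms and peak statistics

The 1D histogram compiles **all** samples of all traces (100 bins on
[−5.5, 0] by default); the 2D histogram is 30 × 30 over
displacement × log-conductance ([−0.1, 1] nm × [−5.5, 0]). Bins are
half-open, left-closed, last bin closed (NumPy convention); storage is
ascending in log G, with display orientation left to plotting tools.

The most probable conductance is the max-count bin refined by a
least-squares fit of a Gaussian over ±20 bins around the mode, on top of a
constant background plus a step that turns on below the peak
(`base + step·Φ((μ−x)/σ)`). The background model reflects the trace
anatomy: tunneling samples are roughly uniform in log G, while each
molecular trace's post-plateau decay adds counts only *below* its own
plateau, producing a population-CDF-shaped step. A plain-Gaussian fit
biases the mode low by a few hundredths of a decade and inflates the
width; the step model removes the bias (residual mode error ≲0.015 decades
at n = 5000 traces). FWHM is 2√(2 ln 2)·σ ≈ 2.3548 σ of the fit when it
converges (raw interpolated half-maximum crossings are always reported as a
cross-check; on ensembles with background the raw width is
background-inflated and the fit is the default). Peaks confined to one bin
are flagged unresolved.

## Featurization and population detection

Each aligned trace is summarized by its own 30 × 30 2D histogram
(flattened row-major, displacement-major) concatenated with its own
100-bin 1D histogram — 1000 dimensions at the default binning.

Two feature-space choices are ours and documented here. First,
standardization: features are Z-scored per dimension, zero-variance
dimensions dropped. Second, kernel smoothing (enabled through
`cluster_feature_spec()` for population detection, off for plain
featurization): the raw count histogram of a single sparse trace is
near-orthogonal to that of any trace whose plateau sits in different bins,
so Euclidean distances *saturate* — a 0.5-decade and a 1.5-decade level
separation produce the same distance, and the silhouette of even perfectly
separated populations plateaus near 0.36. Convolving the per-trace
histograms with a Gaussian kernel of the order of the between-population
separations of interest (σ = 25 of 100 bins ≈ 1.4 decades in 1D; (2, 8)
bins in 2D) restores a metric that grows with level separation out to a
few decades. With it, well-separated bimodal ensembles reach silhouettes
≈0.6 while a continuum split of a unimodal ensemble stays ≈0.35–0.44 —
exactly the regime in which a fixed threshold can arbitrate.

Model selection fits a full-covariance Gaussian mixture (ridge 1e-6 on the
diagonal, 10 seeded restarts, best likelihood kept) for each candidate k
and computes the silhouette of the hard labels with Euclidean distance in
the standardized space; the selected k maximizes the silhouette, demoted
to "single population" when the best k ≥ 2 silhouette falls below a
threshold (default 0.5, always reported, never hidden — k = 1 has no
silhouette of its own). As a numerical device the standardized features
are rotated onto their principal axes and trailing components beyond
99.9 % of the variance are discarded before the EM fit: a rigid rotation
leaves distances and silhouettes essentially unchanged while conditioning
the covariance estimates (at ~10³ samples in 10³ dimensions the raw
covariances are singular) and reducing the EM cost by orders of magnitude.
The pipeline is deterministic given features and seed.

Problem sizes: the packaged tests and the acceptance script use ensembles
of 1200–5000 traces for histogram statistics and 1200 traces for
clustering, with candidate k ∈ {2, 3} — sizes at which every recovery
statistic is already stable across seeds.

## Tunneling-pathway bond counting

Electron-transfer coupling is modeled as a product of per-step decay
factors along a path through the bonded network between the two anchor
sulfurs. A covalent step costs 1, a hydrogen-bond step costs exactly 2
(decay through an H-bond twice that through a covalent bond); through-space
jumps exist as an optional third edge kind (default cost 3) but are
excluded from default builds. The best pathway minimizes the effective
bond count (Dijkstra on the weighted graph); ties resolve to the
lexicographically smallest atom-id sequence. Conductance scales as
ε_C^(effective count); ε_C is not fixed by theory here — the package
default is 0.6 (a Δ of 3 bonds at ε_C = 0.46 is one order of magnitude),
and it is always echoed in output. The backbone builder's bond-counting
convention (anchors bonded to the first N and last C; carbonyl O as a
spur; peptide N–H present, peptoid N-substituted) is explicit and
configurable; absolute bond counts depend on it, while the sign of any
with/without-H-bond comparison does not. An exhaustive simple-path
enumerator serves as the independent oracle on small graphs.

## Junction-preparation computations

Backbone randomization sets each φ/ψ to an independent uniform draw on
[−180, 180) and each ω to 0 (cis) or 180 (trans) with probability ½, by
rigid rotation of the C-terminal-side fragment about the bond — bond
lengths and angles are preserved exactly.

Ring piercing: a bond pierces a ring iff its segment intersects the ring
surface, triangulated as a fan about the centroid (so puckered rings are
handled); Möller–Trumbore segment/triangle intersection with inclusive
tolerances; bonds sharing an atom with the ring are skipped; zero-area
rings are flagged and skipped. Mitigation pairs the two bond atoms with the
three ring atoms nearest the intersection point (which three is not
dictated by the physics; nearest-to-intersection is the package's choice,
swappable), six exclusion pairs per piercing, de-duplicated.

The three restraint potentials use the minimal functional forms satisfying
their contracts, with all constants configurable and logged:

* anchor restraint U = ½ k (s − d)², s the *signed* projection of the
  anchor-anchor vector on the pulling axis (projection, not full distance,
  so lateral wobble is unpenalized — the electrodes constrain the axial
  gap); stage targets 6/9/12 Å by convention, any positive value accepted;
* field term U = −Σ qᵢ E zᵢ — a uniform field of magnitude E along the
  axis acting on partial charges (250 mV across a 1 nm gap gives
  E = 2.5 × 10⁸ V/m); energies in kcal/mol with charges in e;
* orientation term U = k(1 − cos θ) per anchoring sulfur, θ between the
  mean lone-pair direction (opposite the bisector of the two S-substituent
  bonds, so a thioether sulfur is required) and the outward electrode
  direction (±axis by the sulfur's axial position).

Forces are analytic throughout and verified against central finite
differences (h = 10⁻⁵ Å) to relative error < 10⁻⁵; the orientation
gradient chains through the normalized bisector with the standard
(I − ûûᵀ)/|u| Jacobian.

## Trajectory analyses

H-bond candidates are all donor-heavy-atom × acceptor combinations
(backbone/cap nitrogens with ≥1 bonded H; carbonyl oxygens), with the
per-frame H···O distance taken over the closest attached hydrogen.
Occupancy uses both thresholds — N···O ≤ 3.5 Å and H···O ≤ 2.5 Å by
default (no universal printed standard exists; both are configurable and
echoed). Dihedrals follow the IUPAC sign convention on (−180, 180];
ω = 0 is cis, 180 trans; summaries are circular (mean, circular sd).

Distance-matrix PCA: per-frame upper-triangle pairwise distances of a
backbone-atom selection (n(n−1)/2 features), Z-scored per dimension
(zero-variance dimensions — e.g. distances within rigid units of an
idealized geometry — dropped with a warning), then whitened PCA; the first
two components are returned with explained-variance fractions, and the
whitened projections have unit variance by construction. The default
selection is backbone N/Cα/C′/O plus the C-terminal cap nitrogen, which
gives 17 atoms (136 distances) for a 4-residue oligomer and 21 (210) for
5 residues; the selection is explicit user input whenever the default does
not apply.

Free-energy surfaces: F(x, y) = −k_B T ln p̂ with p̂ the normalized 2D
histogram, minimum shifted to 0, empty bins NaN (never an infinite
sentinel); energies in kcal/mol (k_B = 0.0019872 kcal/mol/K). S–S "z" is
the axial component of the inter-sulfur vector, "xy" the norm of the
perpendicular components; the axis defaults to +z and matches the
trajectory generator, which orients the anchor axis along z and applies an
optional random rigid tilt to emulate junction wobble.

The trajectory generator builds coordinates by sequential
internal-coordinate (NeRF) placement with generic amide bond lengths and
angles; `anchor_separation_A` is recorded as the holding-stage label in the
frame metadata, while the realized S–S distance follows from the backbone
conformation — a rigid internal-coordinate chain cannot hit an arbitrary
anchor separation exactly, and nothing downstream requires that it does.
Idealized geometry means some interatomic distances are exactly constant
across frames (hence the PCA zero-variance drop path is exercised by
design) and no bond-stretch vibrations are present.

## Known limitations

* The silhouette demotion threshold (0.5) arbitrates between "split of a
  continuum" and "two populations" only when the feature metric is graded;
  with smoothing disabled the threshold is not meaningful.
* The background-step peak model assumes a single dominant peak inside the
  fit window; overlapping populations closer than ~2 bins are reported as
  one peak.
* The pathway model is topological: no geometry-dependent decay, no
  Green's-function transmission.
* The restraint forms encode the stated intent of the junction potentials,
  not any specific published parameterization; constants are user inputs.
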