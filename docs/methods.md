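# Methods

This note documents the models behind `inhaledose`, the defaults and the
reasoning where a design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Emission library

Each nuclide entry carries discrete gamma/x-ray lines (energy in keV,
yield in emissions per decay), beta branches (endpoint energy, branch
probability, daughter proton number) and, for the plutonium pair, a
single intensity-weighted 5.15 MeV alpha line at yield 1. Line data are
transcribed from evaluated nuclear data compilations into
`src/inhaledose/data/nuclide_library.json`; beta branch constants are
ENSDF-derived fixture values shipped in the same file (no runtime
download). Auger electrons are excluded: they are mostly below the
10 keV transport cutoff and occur in a small fraction of decays. The
⁹⁰Sr–⁹⁰Y entry treats the pair in secular equilibrium — two betas per
pair decay (stored as two branches at probability 0.5 with
`betas_per_decay = 2`), no photon lines (the daughter's 2.186 MeV gamma
at 1.4×10⁻⁶ per decay is negligible next to a beta every decay).

Beta spectra use allowed-shape Fermi theory,
`N(E) ∝ p·E_tot·(Q−E)²·F(Z,E)`, with the nonrelativistic Coulomb
correction `F = 2πη/(1−e^(−2πη))`, `η = +Zα/β`. This closed form is
adequate for spectral shape; it is not an evaluated-spectrum database.
Consequence worth knowing: the library's photon-to-beta energy ratios
per decay (e.g. ≈3.2 for ¹³⁷Cs, ≈9.7 for ¹³⁴Cs, computed by
`photon_energy_per_decay / mean_beta_energy_per_decay`) differ by tens
of percent from ratios quoted from evaluated beta-spectrum tables;
reports carry the computed values and do not force agreement.

One emission is transported per history; tallies are converted to per
decay by multiplying with the total yield of that radiation kind at
report time.

## Aerosol model

Diameters are i.i.d. lognormal with median = AMAD and ln-SD = ln GSD,
stored as aerodynamic diameters. Activity is taken proportional to
particle mass (uniform specific activity), so AMAD doubles as the
mass-median treatment and deposition fractions are reported on mass or
count basis. The aerodynamic→geometric conversion
`d_g = d_ae·√(χ/ρ)` is applied only where physical carrier geometry
matters (alpha self-shielding), and is off by default there — see below.
Default ensemble size is 10⁵ particles (2×10⁴ in the CLI default for
speed). For GSD ≥ 3 the mass-weighted statistics are dominated by the
sparse large-particle tail: a single 4.2 µm particle outweighs a
0.42 µm particle 1000-fold, so mass-based deposition fractions at these
sample sizes carry substantial outlier variance. This truncation bias
is inherent; `n` is exposed in every sampling call.

## Airway deposition surrogate

The airway is a deterministic procedural tree: a mouth-throat conduit, a
trachea (G0), and up to nine bifurcating generations with constant
length/radius ratios (0.76/0.79) and 35° branching in alternating
planes. The outlet target (default 115 terminal bronchioles) is split
recursively and near-evenly over subtrees, producing leaves at mixed
depths when the target is not a power of two. Flow split per
bifurcation defaults to 50/50 (no measured asymmetry is built in).

Regional deposition probabilities are an explicit tabulated input
p(region; d, Q) on a log-diameter × log-flow grid. The shipped defaults
combine a logistic impaction term in ln(d²Q) — half-capture in the
mouth-throat near 11 µm at 15 L/min, progressively weaker per-pass
capture downstream — with a diffusion term rising at small sizes, and a
double-lognormal alveolar deposition-fraction curve (ultrafine diffusive
mode near 0.02 µm, micron sedimentation/impaction mode near 2.5 µm,
minimum near 0.4 µm, referenced to the aerosol entering the mouth).
These shapes qualitatively reproduce resolved-flow behaviour (head
deposition rising steeply with size; a modal tracheobronchial profile
emerging from serial filtration) but are a surrogate, not a CFPD claim:
passing tests show correct bookkeeping, conservation and limiting
behaviour, not fidelity of absolute regional deposition fractions to
any airway geometry. Genuine CFPD output can be substituted through the
shared particle CSV schema.

The breath cycle is three steps: serial filtration in anatomical order
on inhalation; biased-coin alveolar removal at the outlets with
probability `clip(DF_alv(d)·N_inj(bin)/N_exit(bin), 0, 1)` over 30
logarithmic diameter bins spanning the ensemble range (the ratio
corrects the curve's mouth-inlet reference to the population actually
reaching the acinus; it can exceed 1 after strong upstream filtration,
hence the clip); reverse traversal on exhalation. Retained particles
stay at their own exit outlet — how alveolar particles distribute among
outlets sharing a size bin is not observable in our data, and
per-own-outlet retention is the simplest consistent choice. Particle
count is conserved exactly at every stage. Deposited particles get
surface positions with a configurable carina "hotspot" weight
(default 0.3) concentrating axial positions near the distal bifurcation
ridge.

## Voxel phantom

The reference phantom is constructive geometry (ellipsoids/cylinders)
on a regular grid, default 1 cm voxels: 186 cm tall, ≈98 kg, supine,
z = head-to-toe. It contains lungs (ρ = 0.26 g/cc), trachea
("respiratory" organ, with an interior-air lumen), heart wall, liver,
thyroid, esophagus, spinal bone, skull, limb bones, muscle filler,
subcutaneous fat, a skin shell and brain. Tissue compositions follow
the segmented-phantom values for organs near the source (mass fractions
sum to 1±0.001); fat, skin and air use standard reference compositions.
Organ volumes were tuned once so that discretized masses land within
±10% of the reference values for lung (910.3 g), heart wall (401.8 g),
liver (1935.5 g) and thyroid (27.5 g), and total body mass within ±10%
of 103 kg, stable to <5% for the major organs between 0.5 and 1 cm
voxels (the 27 cc thyroid is not resolvable at 2 cm). The "respiratory"
organ is modelled as the trachea tube; the reference tables list
"respiratory" (15.5 g) separately from lung parenchyma and the exact
split is ambiguous — our trachea organ weighs ~20–30 g depending on
voxel size. I/O is MetaImage (.mhd/.raw) plus a JSON sidecar
(conventions, organ → material map); any compatible phantom, including
a converted segmented-human one, is accepted by the reader.

## Registration

The deposited cloud is mapped by a uniform-scale rigid transform:
scale = max axis ratio of the respiratory-mask bounding box to the
cloud bounding box, rotation from the configured axis convention
(identity by default — the tree is built in the body frame), centroid
translation. Transformed points are voxelized and snapped to the
nearest respiratory voxel within 8 voxels (Euclidean distance
transform; ties resolved by scan order to the lowest linear index);
the run fails if more than 5% of positions stay unplaced. Source
weights are volume-proportional via 64 linear volume bins (each source
takes its bin's midpoint volume), implemented as importance weights;
`literal_duplication=True` reproduces explicit copy-multiplication for
cross-checks. Alveolar-retained particles at the outlets snap to the
nearest lung voxel like any other position.

## Photon transport

Woodcock delta tracking against a per-energy majorant (per-energy max
of the linear attenuation over the phantom's materials, ×1.01
headroom). Cross sections: total Klein–Nishina per electron times
electrons per gram for Compton; parametric photoelectric
`τ/ρ = c·Σ wᵢZᵢ^4.5/Aᵢ·E⁻³` with c anchored so the model total for
water at 30 keV equals 0.3756 cm²/g — the anchor folds the omitted
coherent term in where it matters most. Coherent scattering,
fluorescence and pair production are omitted (sub-percent for ≤1.4 MeV
lines in tissue); photoelectric deposits locally; Compton deposits the
transfer E−E′ at the collision voxel with Kahn-sampled energy–angle;
photons below the 10 keV cutoff (chosen to match the Auger-neglect
threshold) deposit locally. Fluence uses the delta-collision estimator
(each tentative collision scores 1/(Σ_maj·V)). Per batch,
emitted = deposited + escaped holds to accumulator precision, and the
mesh energy tally equals the organ tally total by construction.

## Electron transport

Condensed history: Berger–Seltzer collision stopping power (density
effect omitted; bremsstrahlung neglected, <~2% below 2.3 MeV in
tissue), fractional-energy steps (5% of E, capped at half a voxel),
energy deposited in the voxel where the step starts, Highland multiple
scattering with a Rayleigh-sampled polar deflection per step, 10 keV
cutoff with local deposit. Mean excitation energies combine by Bragg
additivity. The module reports energy deposition and organ dose;
electron fluence is not tallied.

## Alpha self-shielding and deposition

Range–energy: `R(E) = k·Eᵖ` fitted to water anchors
R(4 MeV) = 25.8 µm, R(6 MeV) = 48.5 µm (standard stopping tables),
giving p ≈ 1.557 and R(5.15 MeV) ≈ 38 µm in water; Bragg–Kleeman
scaling `(ρ_w/ρ_m)·(√A_m/√A_w)` with compound √A = (Σ wᵢ/√Aᵢ)⁻¹ gives
R(5.15 MeV) ≈ 13.4 µm in UO₂. Decay points are uniform in the carrier
sphere with isotropic directions; the chord to the surface is
`s = −rμ + √(R²−r²(1−μ²))` and the exit energy follows from the inverse
range relation. The sampled ensemble diameter is treated directly as
the physical UO₂ sphere diameter by default; the aerodynamic→geometric
conversion (factor 1/√10.97 ≈ 0.30 for UO₂) is available and raises
exit energies substantially — this convention choice changes the
self-shielding result and is therefore exposed as an explicit flag.
The ensemble average weights exit energies by sphere volume
(activity ∝ carrier mass). Note that this average is computed over the
*sampled* (inhaled) ensemble; a deposition-weighted ensemble is
enriched in large particles by impaction and yields a lower mean exit
energy. Surviving energy deposits in the voxel of the deposition site
(range ≪ voxel); both the direct per-decay sphere simulation and the
point-source mode with per-diameter mean exit energies are available.

## Statistics and reproducibility

Tallies carry per-batch first and second moments; the relative error of
a bin is the standard deviation of the batch mean divided by the mean
(flagged ∞ at zero mean), and scales as 1/√N with histories. The
kernels draw from counter-based splitmix64 streams keyed on
(seed, batch, history), so results are bit-reproducible for a given
seed and independent of execution order. Default desk-scale sizes —
10⁶ photon histories, 2×10⁵ electron histories, 10⁵ alpha spheres,
2×10⁴ aerosol particles, 1 cm voxels — are 1% of production-scale runs;
statistical errors on organ doses near the source are then ≲1%, distal
organs correspondingly worse.

## Known limitations

- Deposition curves are qualitative surrogates; absolute regional
  deposition fractions should come from resolved-flow data when fidelity
  matters.
- The constructive phantom preserves organ masses and gross topology,
  not organ shape; per-organ doses and inter-organ ratios are
  anatomy-specific and not comparable organ-by-organ with segmented
  phantoms (whole-body absorbed fractions transfer much better).
- No biokinetics: doses are per decay with particles fixed on airway
  surfaces — the freshly-inhaled configuration, not a cumulative dose.
- Photon physics omits coherent scattering and fluorescence transport;
  electron physics omits the density effect and bremsstrahlung; both
  are documented few-percent effects in this energy range.
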