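# Methods

## Scope and grain

The toolkit models the λ recombination intasomes at *domain* granularity: each
protein domain is a small cloud of pseudo-atoms (10–40 per domain), and DNA is
a chain of base-pair frames (origin + orthonormal triad per bp). This matches
what an ~11 Å map constrains — domain placement, arm trajectories, bridge
connectivity — and deliberately excludes all-atom geometry, sequence-dependent
elasticity, and energy minimization. Stereochemical regularity is obtained by
construction (exact helical steps) rather than by restrained refinement.

## DNA geometry

Base-pair steps use a symmetric mid-step convention: the step rotation is
`Rz(twist/2)·Ry(roll)·Rz(twist/2)` and the origin advances `rise` along the
mid-step axis `Rz(twist/2)·Ry(roll/2)·ẑ`. Only twist/roll/rise are modeled
(tilt/slide/shift are zero). Consequences used throughout the tests: a
zero-roll path has an exactly straight axis regardless of twist; N equal
rolls at zero twist trace a planar arc of exactly N·roll; end-to-end length
of a straight N-mer is exactly (N−1)·rise. Defaults are the canonical B-DNA
values, twist 36.0°/step and rise 3.38 Å/step, both overridable.

Helical-parameter *extraction* from arbitrary frames is ambiguous (the
(twist, roll) pair has a (twist+180°, −roll) twin); the accessor returns the
branch with twist nearest +36°, which is unique for |roll| < 90°.

Splicing superposes an ideal splint (2×`splint_len` bp) onto the upstream
tail by least squares over frame markers (origin + x/y axis tips), then
places the downstream path on the splint's second half. The upstream path
never moves; twist continuity at the junction is exact for ideal flanks.
Superposition itself is the Kabsch proper-rotation fit
(`scipy.spatial.transform.Rotation.align_vectors`); collinear point sets are
rejected as degenerate rather than silently fit.

Kink adjustments mirror how protein-bent DNA is varied during fitting:
*in-plane* rotation about the existing bend axis of the distal kink (both
kink origins fixed, bend deepened/shallowed), and *torsion* about the axis
connecting the two kink origins (per-frame axis distances preserved).
Adjustments of ≥10° emit a warning, since protein-bound DNA deformations
beyond that are not credible.

## The junction core and isomerization

The four-way junction is near-planar and pseudo-fourfold: arm exits at
azimuths 0°/90°/180°/270° with slightly unequal radii (12 Å for C/C′, 13 Å
for B/B′) so a 90° rotation maps exits onto each other within ~1.4 Å — close
to, but detectably off, exact symmetry. The four scissile phosphates form a
parallelogram; the activated diagonal pair sits at 8 Å radius and the
inactive pair at 12 Å, so the active diagonal is always the shorter.
Isomerization is implemented as a deterministic rebuild with the other
isomer flag: the branch point shifts by exactly 1 bp, the active/inactive
pairs exchange, arm exits twist by 1.5° (≈0.6 Å displacement, under the 2 Å
"nearly isosteric" bound), and applying it twice restores the core exactly.
Proteins are untouched — isomerization is core-internal at this grain.
Whether real particles are one isomer or a mixture is unresolved; the
builder constructs either on request.

## att coordinates and DNA accounting

No numeric bp coordinates for the binding sites are published; the packaged
TSV is an implementer default satisfying every stated constraint: 240 bp
total, 7-bp overlap at the origin, the core-proximal→distal orders
(P arm: H2, Xis/Fis cluster, P2, H1, P1; P′ arm: H′, P′1, P′2, P′3), the
X2/F shared interval, and plausible site widths. DNA is accounted as
P arm 127 bp + overlap 7 bp + P′ arm 76 bp + two 15-bp attB-side flanks
= 240 bp. The registry file is user-replaceable; all invariants are
re-validated on load.

## Arm trajectories (the open design)

The published account gives qualitative architecture, not trajectory
parameters. Arms are therefore built from full-length ideal B-DNA plus a
frozen per-pathway *bend program*: discrete kinks at the IHF/Xis/A-tract
positions plus small distributed rolls in protein-free regions. Two modeling
choices matter:

1. **Kinks are coplanar ("phased") rather than helically phased.** With
   36°/step twist, two kinks 9 bp apart are 324° out of phase and would not
   sum coplanarly; the coarse model treats bend-plane azimuths as free
   parameters so that, e.g., a 160° IHF bend is exactly 160°. This is a
   known simplification: in real DNA, bend phase is slaved to helical
   position.
2. **The bend-program constants are design values**, chosen once so the
   models satisfy the architecture's qualitative constraints and then
   frozen: excisive P/P′ arms parallel with zero projected crossings; the
   integrative P arm passing *over* the unchanged P′ arm with exactly one
   negative node; every bridge within the extended-linker reach; the P′ arm
   bit-identical between pathways. They are not fits to any map or
   deposited coordinates, and the models do not aim to reproduce deposited
   structures.

IHF components default to two kinks 9 bp apart totalling 160°; Xis to three
tandem 30° bends (≈90° cumulative redirection); both are config-exposed
defaults. The excisive Int-C NTD is omitted (no arm site binds it in
excision); the integrative model places NTDs at P′1/P′2/P′3/P1.

Bridge feasibility uses the NTD–CB linker, residues 56–74 (19 residues), at
an extended-chain contour of 3.8 Å/residue: maximum anchor separation
72.2 Å. Anchors are the CTD linker-attachment point (top inner corner of
each CTD cloud) and the arm-site NTD position.

## Crossing nodes and writhe

Crossing signs follow the supercoiling node convention with both duplexes
oriented along increasing att coordinate (the stored P-arm path runs
core→distal and is reversed by `AssemblyModel.arm_crossing`). The sign is
the knot-theoretic crossing sign of the projected, oriented tangents —
right-handed (plectonemic) crossings score −1 — so summed signs over random
projections converge to the Gauss double-integral writhe, which is computed
per segment pair by the exact solid-angle (Klenin–Langowski) formula.
Near-tangent crossings (height difference < 0.5 Å) are perturbed by 10⁻³ Å
along the view axis before evaluation, making degenerate cases
deterministic.

## Density and FSC stack

Maps are cubic-voxel float grids (default 2.8 Å voxel). The forward model
sums isotropic Gaussians, σ = resolution/(π√2), weighted by radius³ (mass ∝
volume); the σ choice makes the kernel's Fourier transform fall to ~1/e at
the nominal resolution. Sharpening multiplies amplitudes by exp(−B·s²/4)
and leaves phases untouched. Masks are thresholded supports dilated by a
Euclidean-distance margin (default 15 Å) with a raised-cosine edge (default
5 voxels). Phase randomization beyond a limit takes replacement phases from
the transform of a real random field, so Hermitian symmetry — and hence map
realness — is preserved exactly while per-voxel amplitudes are kept.

FSC uses one-Fourier-voxel shells; shells with <10 voxels merge inward; the
DC shell is dropped. The mask correction
FSC_true = (FSC_t − FSC_n)/(1 − FSC_n) is applied one shell *above* the
randomization limit (the boundary shell mixes randomized and untouched
voxels and would produce a spurious discontinuity); FSC_n = 1 makes the
correction undefined and is reported as missing (NaN), never clamped.
Threshold resolutions interpolate linearly between shell centers; a curve
that never crosses reports the Nyquist shell with an explicit flag. The
model-to-map agreement score is the normalized Fourier-coefficient
correlation up to a resolution limit between the map simulated from the
model and the target map — the scoring form of the density-agreement term
used to keep flexible regions inside an envelope (a score here, not a
refiner).

## FRET comparison and dye accessibility

The packaged table carries the published FRET distances, FRET-model
distances and EM-model distances verbatim, grouped `free` /
`conflict_site3` / `conflict_site8` by predicted dye steric environment.
`fret_compare` is pure arithmetic (per-pair |Δ|, RMS per group) against
either a distance map or a model. Label sites (`P+50T`, `B-15T`, …) parse to
(coordinate line, signed offset, strand); positions on arm extensions beyond
the modeled construct raise an explicit out-of-model error. The dye proxy is
the labeled bp origin displaced 10 Å along the strand's major-groove
direction (frame x for top, rotated 144° for bottom) — a stand-in for the
tether midpoint, since no dye geometry is published. Accessibility is the
fraction of Fibonacci-sphere directions in which a probe sphere (default
5 Å) placed one probe radius out clears every pseudo-atom; the labeled bp ±3
neighbors are not occluders (the tether spans them by construction). The
fraction is monotone non-increasing in probe radius.

## Synthetic data

`make_components` emulates the crystallographic/NMR inputs as labelled
pseudo-atom clouds with exact bend geometry; `make_half_maps` adds
independent white Gaussian voxel noise (seeded per half) to the simulated
map. Real reconstruction noise is colored and signal-dependent; white noise
suffices to exercise FSC mechanics, which is all the fixtures claim. All
randomness flows from one integer seed (two derived streams for the two
halves); identical configs give bit-identical fixtures. What passing tests
show is therefore that the *computations* are correct on known-answer
inputs, not that the synthetic components resemble experimental structures.

## Numerical choices and limitations

- Frame orthonormality is enforced to 1e-8; splice/bend identities hold to
  1e-6–1e-8 in tests.
- Map data are float64 in memory; CCP4/MRC files are written mode-2 float32
  (values must fit single precision — relevant when sharpening white noise
  with large |B|, where corner-frequency gains of e⁵⁹ overflow; band-limited
  maps are safe).
- Problem sizes are deliberately small: 24³–40³ grids for Fourier tests,
  ~140 protein pseudo-atoms and 480 DNA pseudo-atoms per model; the full
  pipeline runs in seconds on one core.
- The pipeline's FSC resolution on synthetic half-maps reflects the chosen
  noise level, not any experimental resolution claim.
- The coarse models satisfy the architecture's countable and topological
  claims; they are not, and cannot be, substitutes for the deposited
  experimental coordinates (distances to which are not modeled targets).
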