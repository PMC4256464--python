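# Methods

## The measurement problem

On-section immunogold labelling yields micrographs in which gold particles
scatter around traced membrane profiles. Two estimation problems stand
between those annotations and a statement like "this transporter sits in
the plasma membrane": (i) the amount of membrane of each compartment in
the sampled sections must be estimated without bias, and (ii) the observed
label must be corrected for the nonspecific binding every antiserum shows.
`goldstereo` implements both, plus a simulator that generates annotations
with known ground truth so the estimators can be checked by recovery.

## Stereological length estimation

The lattice estimator is `L̂ = (π/4)·d·I` for a square lattice with
spacing `d` and crossing count `I`. It follows from the standard
test-line relations: a square lattice carries test-line length `2/d` per
unit area, and for isotropic uniform random test lines the boundary
length per area is `B_A = (π/2)·I_L`. Randomising only the lattice
translation would leave the estimator biased for anisotropic curves (a
straight membrane parallel to a lattice family is never crossed by it),
so the placement randomises rotation on `[0, π/2)` as well — the quarter
turn is the lattice's full symmetry group. Unbiasedness is verified by
Monte Carlo on a circle and on a straight segment.

Degenerate configurations get a fixed, testable convention: a segment
endpoint exactly on a lattice line counts as one crossing for that
segment (crossings are counted per segment-line pair, so a shared vertex
on a line counts for both adjacent segments); a segment collinear with a
lattice line contributes zero. These are measure-zero events under the
random placement, so any fixed convention leaves the estimator unbiased;
this one is deterministic and cheap to test.

Spacings follow the protocol defaults: 262 nm for plasma membrane and
nuclear envelope (618 and 914 nm are the other stated alternatives),
914 nm for endo-membranes (1.54 µm the coarse alternative). The mapping
is configurable per compartment.

**Mitosome lengths.** Grid spacings are stated only for plasma membrane,
nuclear envelope and endo-membranes; mitosomes are tiny (50–300 nm across)
and are scanned comprehensively, so lattice counting would be hopelessly
noisy for them (a 300 nm profile meets a 262 nm lattice about once). The
package therefore measures mitosome membrane length directly as the
analytic length of the traced polyline (`spacing_map` value `"trace"`).
This gives mitosomes a defined density so they participate in the
specificity statistics, at the cost of assuming their profiles are traced
completely — which comprehensive scanning provides.

## Particle assignment

"Less than one particle width away from a membrane profile" is read as an
edge-to-membrane gap smaller than one particle diameter; for 10 nm gold
that puts the particle centre within radius + diameter = 15 nm of the
traced line. Whether the original rule measured from the particle edge or
centre is ambiguous, so `assoc_dist_nm` is configurable (10 nm reproduces
the centre reading). The inequality is strict at the boundary. A particle
within threshold of several profiles goes to the nearest; exact ties
break by lexicographic compartment name — deterministic, and exercised
only on measure-zero configurations. Assignment conserves particles:
assigned plus unassigned always equals the input count.

## Densities and pooling

Densities are `D = N / L̂` in gold/µm. Within one experiment, micrographs
are pooled as a ratio of sums (`ΣN / ΣL̂`), the standard choice for
stereological ratio quantities: it weights micrographs by the membrane
they actually contain and tolerates micrographs with `L̂ = 0`. A
compartment with no measured membrane has an *undefined* density (`None`),
never zero, and undefined densities propagate through the specificity
formulas rather than silently vanishing.

Sampling streams (systematic-uniform-random fields vs comprehensive
mitosome scans) are quantified separately and never pooled; when both are
present, mitosome statistics come from the comprehensive stream and every
other compartment from the SUR stream.

## Specificity statistics

Per experiment: `D(sp) = D(0) − D(−)` exactly, with negative values
retained in the density tables (they indicate signal induced by the
inhibited antiserum and are diagnostically meaningful); `F(sp) =
D(sp)/D(0)`, reported raw and clamped to [0, 1]; and the specific
distribution `Ng(sp) = F(sp)·N(0)` using the clamped fraction, since a
frequency distribution of gold counts cannot be negative. `D(0) = 0` is
defined to give `F(sp) = 0`: no label, no specific label. Compute order
is fixed: pool within experiment → specificity per experiment → mean ±
SEM (sample SD, n−1, over √n) across experiments. SEM requires at least
two replicates and is flagged unavailable otherwise.

Whether the specific fraction should be computed per compartment or once
per section is genuinely open; the default is per-compartment (densities
are compared per compartment), and a section-wide mode
(`section_wide_fsp`) computes one pooled fraction and applies it to every
compartment's counts, without asserting which variant any particular
study used.

## The synthetic generator

Scenes are vector annotations, not images: the real measurements are made
on annotated micrographs, so pixel-level simulation would add nothing the
pipeline consumes. Each field (3 µm square by default) holds one
star-convex smoothed closed plasma-membrane profile (radius 1 µm with
low-order harmonic perturbations), a nuclear envelope (0.45× the cell
radius), four open random-walk endo-membrane tubules (200–800 nm), and
four closed elliptical mitosomes with axes uniform in 50–300 nm. Shapes
are described only qualitatively in the source material
("tubulovesicular and cisternal profiles"), so these are the package's
own choices; the ground truth is whatever polyline was generated, with
its exact analytic length.

Labelling: specific gold is a Poisson process along each membrane at
λ_c gold/µm, displaced perpendicular to the membrane by Normal(0, 8 nm) —
below the 15 nm association threshold, so most specific gold is
recoverable, but wide enough that some is lost, as in real sections.
Background is a uniform spatial Poisson process at β gold/µm². The
defaults encode the study conditions the pipeline is validated against:
λ = 5 gold/µm on the plasma membrane, 0.5 on the nuclear envelope, 1.0 on
endo-membranes, 0 on the mitosome, and β = 33.3 gold/µm², which makes
background alone register ≈ 1 gold/µm on any membrane through the 30 nm
association band. Complete inhibition (ρ = 1) removes the specific
component in the control condition.

A study is 3 experiments × 18 micrographs per condition (the protocol
states 16–20 per sample; 18 is a midpoint choice, not a reported value).
Every micrograph is an independent section with its own geometry and its
own gold realisation; native and inhibited fields are different sections,
as on a real grid. All randomness flows from one `SeedSequence`, so a
seed reproduces a study bit for bit. Ground truth (true lengths, rates,
particle origins) lives in a sidecar the pipeline never reads.

**What the generator does not emulate:** section thickness and projection
effects, membrane-proximity correlations in the background, antibody
penetration gradients, clustered (non-Poisson) labelling, segmentation
error in the traced polylines, and the separate comprehensive-scan
micrograph stream (simulated studies emit a single SUR stream; the
pipeline still handles both). Passing recovery tests therefore show the
estimators are correct for annotations of this kind, not that any real
antibody behaves this way.

## Numerical and scale choices

Profiles are discretised at 96 (plasma membrane), 64 (nuclear envelope)
and 48 (mitosome) vertices; the inscribed-polygon length of a smooth
closed curve is then short by < 0.3%, far below the sampling noise at
study scale. Validation sizes are chosen to estimate each quantity well
while keeping runs quick: 10,000 lattice placements bound the estimator
bias check at ~1% Monte-Carlo error; recovery uses 20 full studies of
3 × 18 × 2 micrographs; the null-specificity control uses 50. The
acceptance script uses 10, 20 and 5,000 respectively and finishes in well
under a minute.

## Known limitations

- 2-D only: membrane profile length per section, no 3-D surface density.
- No hypothesis testing between compartments; reports are descriptive
  mean ± SEM, matching the study design the pipeline mirrors.
- The clamped `F(sp)` biases `Ng(sp)` slightly upward in compartments
  whose true specific density is zero (negative fluctuations clamp to 0,
  positive ones survive); the raw values are always reported alongside
  for diagnostics.
- Particle detection is out of scope: particles arrive as coordinates.
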