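# goldstereo

Quantitative analysis of immunogold electron-microscopy labelling, built
around the workflow used to localise membrane transporters in
microsporidian parasites (*Trachipleistophora hominis* meronts): unbiased
membrane-length estimation by stereological intersection counting,
distance-rule assignment of gold particles to subcellular compartments,
peptide-inhibition specificity correction, and replicate aggregation —
plus a synthetic micrograph-annotation generator so the whole pipeline can
be validated by parameter recovery without any real EM data.

## Who this is for

Microscopists quantifying on-section immunogold label over membrane
compartments (plasma membrane, nuclear envelope, endo-membranes,
mitosomes) from annotated micrographs: traced membrane polylines plus gold
particle coordinates, in physical units (nm).

## The method

**Membrane length.** A square lattice of test lines with spacing *d* is
placed on each micrograph with uniformly random offset and rotation, and
the crossings *I* between the lattice and each compartment's membrane
profiles are counted. The classical stereological estimator for a square
lattice gives the membrane profile length

&nbsp;&nbsp;&nbsp;&nbsp;*L̂* = (π/4) · *d* · *I*,

which is design-unbiased for any rectifiable curve because both offset and
rotation are randomised. Fine spacings (262/618/914 nm) are used for the
plasma membrane and nuclear envelope, coarse ones (914 nm / 1.54 µm) for
endo-membranes; the small mitosome profiles are measured by direct
tracing.

**Gold assignment.** A particle is membrane-associated when it lies less
than one particle width from a membrane profile (with 10 nm protein-A gold
and the edge-to-membrane reading: centre-to-line distance < 15 nm,
configurable). It goes to the nearest qualifying compartment; exact ties
break lexicographically. Densities *D* = *N*/*L̂* (gold/µm) are pooled
across the micrographs of an experiment as a ratio of sums.

**Specificity.** Each native labelling density *D*(0) is compared with the
density *D*(−) from the paired peptide-inhibited control:

&nbsp;&nbsp;&nbsp;&nbsp;*D*(sp) = *D*(0) − *D*(−),&nbsp;&nbsp;
*F*(sp) = *D*(sp)/*D*(0),&nbsp;&nbsp;
*Ng*(sp) = *F*(sp) · *N*(0).

Negative *D*(sp) (signal induced by the inhibited antiserum) is retained in
the density tables; *F*(sp) is clamped to [0, 1] when distributing counts.
Replicate experiments are summarised as mean ± SEM.

## Worked example

```sh
python analysis/01_simulate_study.py        # 3 experiments x 18 micrographs x 2 conditions
python analysis/02_quantify_labelling.py
python analysis/03_specificity_report.py
```

The simulated study places 5 gold/µm of specific label on the plasma
membrane, a little on internal membranes, none on the mitosome, and a
uniform nonspecific background; the inhibited condition removes the
specific component. The pipeline, which sees only the annotations, prints:

```
plasma-membrane density, native: 5.76 gold/um (range 5.73-5.82)
plasma-membrane density, inhibited: 0.99 gold/um (range 0.93-1.04)

specific gold distribution Ng(sp), mean +/- SEM:
  endo_membrane          29.4 +/- 6.8
  mitosome                0.0 +/- 0.0
  nuclear_envelope       25.7 +/- 6.0
  plasma_membrane       545.5 +/- 6.7

modal compartment: plasma_membrane (91% of specific gold)
```

Background inflates the raw native density to ~5.8 gold/µm; subtracting
the control (~1 gold/µm) recovers the specific density, and the specific
distribution concentrates on the plasma membrane with essentially nothing
over the mitosome — exactly the truth the generator encoded. Tables land
in `results/`, including the per-experiment *D*(0)/*D*(−)/*D*(sp) density
table and the aggregated distribution.

The same pipeline runs on real annotation directories through the CLI:

```sh
goldstereo simulate --seed 1 --out scratch/annotations
goldstereo report --annotations scratch/annotations --out results/
```

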