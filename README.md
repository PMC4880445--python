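# intasome

Coarse-grained construction and validation toolkit for the higher-order
protein–DNA complexes of bacteriophage λ site-specific recombination.

## The problem

λ integrase (Int) inserts the phage chromosome into, and excises it from, the
*E. coli* genome through two opposing, tightly regulated reactions. Each
reaction assembles a ~400 kDa machine on the 240-bp *att* region: a Holliday
junction (HJ) intermediate bound by an Int tetramer plus accessory DNA-bending
proteins (IHF, and Xis for excision), with Int's two DNA-binding domains
forming *bridges* between core cleavage half-sites (B, B′, C, C′) and distant
arm sites (P1, P2, P′1–P′3). The excisive HJ complex comprises 11 protein
subunits on the 240-bp junction; excision uses three Int bridges
(C′–P′1, B–P′2, B′–P2), integration four (C′–P′1, C–P′2, B′–P′3, B–P1).
Architecturally, the excisive P and P′ arms run nearly parallel without
crossing, whereas in the integrative complex the P arm must pass over the P′
arm, creating a single **negative DNA-crossing node** — a structural
explanation for why integration requires negative supercoiling.

This package is for structural/computational biologists who want these
published architectural and map-validation computations as reusable,
testable code operating on synthetic (or user-supplied) coarse components —
no downloads, no all-atom modeling.

## What it implements

- **`intasome.registry`** — the *att*-site coordinate system: 16 protein
  binding sites around a 7-bp overlap, pathway occupancy ensembles, Int
  bridge patterns.
- **`intasome.geometry`** — base-pair-frame DNA: ideal B-DNA (36°/step,
  3.38 Å rise), Kabsch superposition, splint splicing with twist continuity,
  ±1° roll bending, in-plane/torsional kink adjustments.
- **`intasome.assembly`** — junction core with scissile-phosphate
  parallelogram and one-bp branch-migration isomerization; full excisive and
  integrative models; bridge feasibility from the 19-residue NTD–CB linker
  (19 × 3.8 Å = 72.2 Å reach); crossing-node sign and Gauss-integral writhe.
- **`intasome.density`** — map simulation, B-factor sharpening
  (amplitudes × exp(−B·s²/4)), tight soft-edged masks, FSC, phase
  randomization, mask-effect correction
  FSC_true = (FSC_t − FSC_n)/(1 − FSC_n), and 0.143/0.5 threshold
  resolutions.
- **`intasome.validation`** — site-to-site distances, the packaged FRET
  distance table with per-group RMS comparison, dye steric accessibility,
  and exact model censuses.
- **`intasome.synth`** — deterministic synthetic components (Int CTD
  tetramer core, NTD blobs, IHF- and Xis-bent duplexes) and noisy half-maps.
- **`intasome.io` / `intasome.cli`** — coarse PDB and CCP4/MRC I/O, CSV FSC
  curves, a JSON-manifest pipeline, and an `intasome` console command
  (`synth`, `assemble`, `simulate-map`, `sharpen`, `fsc`, `validate-fret`,
  `census`, `crossing`, `pipeline`).

## Worked example

```python
from intasome import FixtureConfig, assemble, load_registry, make_components
from intasome.validation import census

reg = load_registry()                      # packaged 240-bp att registry
lib = make_components(FixtureConfig(seed=0))
model = assemble("excisive", reg, lib)
print(census(model))
print(model.arm_crossing())
```

prints

```
{'protein_subunits': 11, 'int': 4, 'ihf_heterodimers': 2, 'xis': 3,
 'dna_bp': 240, 'bridges': 3, 'arm_sites_occupied': 3,
 'crossings': 0, 'crossing_sign': 0}
(0, 0)
```

— the excisive complex: 240 bp of junction DNA bound by 11 subunits, three
feasible Int bridges, and parallel (non-crossing) P/P′ arms. Swapping in
`"integrative"` gives 4 bridges, a third IHF heterodimer, no Xis, and
`arm_crossing() == (-1, 1)`: one negative node. The `examples/` directory
has one short narrative script per capability (DNA building, ensembles,
assembly, FSC validation, crossing topology, FRET comparison); each prints
the numbers it computes with a line on what they mean.

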