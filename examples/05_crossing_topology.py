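"""DNA crossing-node topology of the two pathways.

The excisive complex's P and P' arms run nearly parallel (no node); in the
integrative model the P arm passes over the P' arm, creating one negative
crossing node — the topological signature that links integration to negative
supercoiling.  The writhe of the combined arm path quantifies the same
chirality.
"""

import numpy as np

from intasome import FixtureConfig, assemble, load_registry, make_components
from intasome.assembly import writhe

reg = load_registry()
lib = make_components(FixtureConfig(seed=0))

for pathway in ("excisive", "integrative"):
    model = assemble(pathway, reg, lib)
    sign, count = model.arm_crossing()
    print(f"{pathway:>11}: {count} P x P' crossing(s), node sign {sign:+d}"
          if count else f"{pathway:>11}: arms run parallel, no crossing node")
    # writhe of the continuous P -> P' walk (P arm reversed to att order)
    walk = np.vstack([model.dna["P"].origins[::-1], model.dna["P'"].origins])
    print(f"{'':>13}writhe of the P->P' arm path: {writhe(walk):+.3f}")

print("\nA mirror image of the integrative model flips the node to +1,")
print("so the sign is a genuine chirality, not a viewing artifact.")
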