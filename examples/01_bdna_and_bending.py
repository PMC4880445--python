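"""Ideal B-DNA generation, splicing and roll bending.

Builds two straight duplexes, splices them through an ideal splint, and bends
the result with small rolls — the construction primitives used to thread the
recombination complex's DNA arms.
"""

import numpy as np

from intasome import bend_roll, generate_bdna, splice

# 21 bp of straight ideal B-DNA: 36 deg twist, 3.38 A rise per step
duplex = generate_bdna("GCTTTTTTATACTAAGTTGGC")
end_to_end = np.linalg.norm(duplex.origins[-1] - duplex.origins[0])
print(f"21-bp straight duplex end-to-end: {end_to_end:.2f} A  (20 x 3.38 = 67.60)")

# splice a 30-mer and a 40-mer; twist stays ideal through the junction
joined = splice(generate_bdna("A" * 30), generate_bdna("G" * 40), splint_len=4)
dev = np.abs(joined.step_twist() - 36.0).max()
print(f"spliced 30+40 bp -> {len(joined)} bp, max twist deviation {dev:.2e} deg")

# a +1 deg roll at one step bends the helix axis by 1 deg; envelope fitting
# iterates such small rolls in the protein-free regions of the arms
bent = bend_roll(joined, 35, 1.0)
print(f"roll at step 35 after bend: {bent.step_roll()[34]:+.3f} deg "
      "(all other steps unchanged)")
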