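"""The att-site registry and the two pathway occupancy ensembles.

The 240-bp att region carries 16 protein-binding sites; excisive and
integrative recombination use different overlapping subsets with different
Int bridge patterns (3 vs 4 bridges).
"""

from intasome import ensemble, load_registry

reg = load_registry()
print(f"att registry: {len(reg.protein_sites)} protein-binding sites, "
      f"{reg.overlap.width}-bp overlap, {reg.span_bp()} bp total")

for pathway in ("excisive", "integrative"):
    ens = ensemble(reg, pathway)
    bridges = ", ".join(f"{c}-{a}" for c, a in ens.bridges)
    print(f"{pathway:>11}: {ens.n_bridges} Int bridges ({bridges})")
    xis = sorted(s for s in ens.occupied_sites if s.startswith("X"))
    print(f"{'':>13}Xis sites occupied: {xis or 'none'}")
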