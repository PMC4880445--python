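"""File I/O and the end-to-end pipeline.

Coarse PDB output: one chain per protein subunit with CA-named pseudo-atoms
(radius stored in the B-factor column), DNA as two P-named pseudo-atoms per
bp (the two strands offset 8.9 A from the helix axis along the bp frame at
azimuths 0 and 144 deg).  Maps go through CCP4/MRC mode-2 float via gemmi.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

from .assembly import AssemblyModel, Component
from .density import DensityMap, fsc, fsc_true, phase_randomize, resolution_at_threshold, sharpen, simulate_map, tight_mask
from .geometry import DuplexPath
from .registry import load_registry
from .synth import FixtureConfig, make_components, make_half_maps
from .validation import census, fret_compare, load_fret_table

__all__ = [
    "RunConfig",
    "read_structure",
    "write_structure",
    "read_map",
    "write_map",
    "write_fsc_csv",
    "load_em_stats",
    "retained_particle_percent",
    "run_pipeline",
]

log = logging.getLogger("intasome")

_STRAND_OFFSETS = [(8.9, 0.0), (8.9, 144.0)]  # (radius A, azimuth deg) per strand


# --------------------------------------------------------------------------
# configuration

_RUNCONFIG_KEYS = {
    "registry_path", "pathway", "component_source", "voxel", "resolution",
    "noise_sigma", "mask_margin", "bfactor", "randomization_limit",
    "output_dir", "seed", "log_level",
}


@dataclass
class RunConfig:
    pathway: str = "excisive"
    registry_path: str | None = None
    component_source: str = "synthetic"
    voxel: float = 2.8
    resolution: float = 11.0
    noise_sigma: float = 0.1
    mask_margin: float = 15.0
    bfactor: float = -2500.0
    randomization_limit: float = 18.0
    output_dir: str = "intasome_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.pathway not in ("excisive", "integrative"):
            raise ValueError(f"unknown pathway {cfg.pathway!r}")
        if cfg.component_source != "synthetic":
            raise ValueError("only the synthetic component source is built in")
        return cfg


# --------------------------------------------------------------------------
# structures (coarse PDB)

def write_structure(model: AssemblyModel, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = f"intasome_{model.pathway}"
    mdl = gemmi.Model("1")
    for sub in model.subunits:
        chain = gemmi.Chain(sub.chain_id)
        for k, (pos, rad, resi) in enumerate(
            zip(sub.positions, sub.radii, sub.residue_indices)
        ):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(resi), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*[float(x) for x in pos])
            atom.b_iso = float(rad)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        mdl.add_chain(chain)
    dna_chains = {"P": "1", "P'": "2", "B": "3", "B'": "4"}
    for arm, cid in dna_chains.items():
        chain = gemmi.Chain(cid)
        duplex = model.dna[arm]
        serial = 1
        for i in range(len(duplex)):
            origin, triad = duplex.origins[i], duplex.triads[i]
            for r, az in _STRAND_OFFSETS:
                a = np.deg2rad(az)
                p = origin + r * (np.cos(a) * triad[:, 0] + np.sin(a) * triad[:, 1])
                res = gemmi.Residue()
                res.name = "DA"
                res.seqid = gemmi.SeqId(serial, " ")
                atom = gemmi.Atom()
                atom.name = "P"
                atom.element = gemmi.Element("P")
                atom.pos = gemmi.Position(*[float(x) for x in p])
                atom.b_iso = 4.0
                atom.occ = 1.0
                res.add_atom(atom)
                chain.add_residue(res)
                serial += 1
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    st.write_pdb(str(path))


def read_structure(path: str | Path) -> Component:
    """Read a coarse PDB back as a single pseudo-atom Component (chain ids
    and residue indices preserved; radii from the B-factor column)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in structure file")
    positions, radii, chains, resids = [], [], [], []
    for chain in st[0]:
        for res in chain:
            for atom in res:
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                radii.append(atom.b_iso)
                chains.append(chain.name)
                resids.append(res.seqid.num)
    if not positions:
        raise ValueError(f"{path}: structure contains no atoms")
    return Component(
        Path(path).stem,
        np.asarray(positions), np.asarray(radii), chains, np.asarray(resids),
    )


# --------------------------------------------------------------------------
# maps (CCP4/MRC via gemmi)

def write_map(density: DensityMap, path: str | Path) -> None:
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(density.data, dtype=np.float32))
    n = density.shape
    ccp4.grid.unit_cell = gemmi.UnitCell(
        n[0] * density.voxel, n[1] * density.voxel, n[2] * density.voxel,
        90.0, 90.0, 90.0,
    )
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header(2, True)  # mode 2 float
    for i, word in enumerate((50, 51, 52)):  # ORIGIN records (A)
        ccp4.set_header_float(word, float(density.origin[i]))
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path) -> DensityMap:
    ccp4 = gemmi.read_ccp4_map(str(path))
    data = np.array(ccp4.grid, copy=True)
    voxel = ccp4.grid.unit_cell.a / ccp4.grid.nu
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    return DensityMap(data, float(voxel), origin)


def write_fsc_csv(path: str | Path, curves: dict[str, "object"]) -> None:
    """Write FSC curves as CSV: shell_freq plus one column per curve."""
    import pandas as pd

    names = list(curves)
    base = curves[names[0]]
    df = pd.DataFrame({"shell_freq": base.freqs})
    for name in names:
        df[name] = curves[name].values
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# packaged single-particle bookkeeping

def load_em_stats() -> dict:
    with resources.files("intasome").joinpath("data/em_stats.json").open() as fh:
        return json.load(fh)


def retained_particle_percent(picked: int | None = None, final: int | None = None) -> float:
    """Percentage of picked particles retained in the final reconstruction."""
    stats = load_em_stats()
    picked = stats["particles_picked"] if picked is None else picked
    final = stats["particles_final_reconstruction"] if final is None else final
    if picked <= 0:
        raise ValueError("picked particle count must be positive")
    return 100.0 * final / picked


# --------------------------------------------------------------------------
# pipeline

def run_pipeline(config: RunConfig | dict, output_dir: str | Path | None = None) -> dict:
    """assemble -> simulate/half-maps -> FSC validation -> census/FRET report.

    Returns (and writes, as JSON) a manifest with the resolved config, the
    model census, bridge report, crossing topology, FSC resolutions and the
    FRET comparison summary."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    logging.basicConfig(level=config.log_level)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1/5: registry + synthetic components (seed=%d)", config.seed)
    registry = load_registry(config.registry_path)
    fix = FixtureConfig(
        seed=config.seed, noise_sigma=config.noise_sigma,
        voxel=config.voxel, resolution=config.resolution,
    )
    components = make_components(fix)

    log.info("stage 2/5: assemble %s complex", config.pathway)
    from .assembly import assemble, bridge_reachability

    model = assemble(config.pathway, registry, components)
    write_structure(model, out / f"{config.pathway}_model.pdb")

    log.info("stage 3/5: simulate map, sharpen, half-map FSC")
    full = simulate_map(model, voxel=config.voxel, resolution=config.resolution)
    sharpened = sharpen(full, config.bfactor)
    write_map(sharpened, out / "simulated_sharpened.mrc")
    h1, h2 = make_half_maps(model, fix)
    mask = tight_mask(full, 0.1 * float(full.data.max()), config.mask_margin)
    m1 = h1.like(h1.data * mask.data)
    m2 = h2.like(h2.data * mask.data)
    curve_t = fsc(m1, m2)
    r1 = phase_randomize(h1, config.randomization_limit, seed=config.seed * 2 + 1)
    r2 = phase_randomize(h2, config.randomization_limit, seed=config.seed * 2 + 2)
    curve_n = fsc(r1.like(r1.data * mask.data), r2.like(r2.data * mask.data))
    curve_true = fsc_true(curve_t, curve_n, config.randomization_limit)
    write_fsc_csv(
        out / "fsc.csv",
        {"fsc": curve_t, "fsc_randomized": curve_n, "fsc_true": curve_true},
    )
    res_143, crossed = resolution_at_threshold(curve_true, 0.143)

    log.info("stage 4/5: census + bridge + crossing validation")
    counts = census(model)
    bridges = [
        {
            "core_subunit": b.core_subunit, "arm_site": b.arm_site,
            "span_A": round(b.span, 2), "max_span_A": b.max_span,
            "feasible": bool(b.feasible),
        }
        for b in model.bridges
    ]

    log.info("stage 5/5: FRET distance comparison")
    fret = None
    if config.pathway == "excisive":
        records = load_fret_table()
        modeled = [
            r for r in records
            if _in_model(model, r.site_i) and _in_model(model, r.site_j)
        ]
        df = fret_compare(model, modeled)
        df.to_csv(out / "fret_comparison.csv", index=False)
        fret = {
            "n_pairs": int(len(df)),
            "rms_by_group": {
                g: round(float(v), 2)
                for g, v in df.groupby("group")["group_rms"].first().items()
            },
        }

    validations = {
        "bridges_feasible": all(b["feasible"] for b in bridges),
        "expected_crossings": counts["crossings"]
        == (0 if config.pathway == "excisive" else 1),
    }
    manifest = {
        "config": asdict(config),
        "census": counts,
        "bridges": bridges,
        "crossing": {"sign": counts["crossing_sign"], "count": counts["crossings"]},
        "fsc_resolution_A_at_0.143": round(res_143, 2),
        "fsc_threshold_crossed": bool(crossed),
        "fret": fret,
        "validations": validations,
        "all_validations_pass": all(validations.values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _in_model(model: AssemblyModel, site) -> bool:
    try:
        model.bp_origin(site.line, site.offset)
        return True
    except KeyError:
        return False
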