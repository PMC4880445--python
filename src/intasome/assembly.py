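"""Coarse 3D assembly of lambda excisive / integrative recombination complexes.

The model frame convention: the Holliday-junction center sits at the origin,
the junction pseudo-twofold along z ("top" = +z, where the bent arms run over
the Int tetramer; the catalytic CTD domains sit below the junction plane).
Arm-exit azimuths: C' +x, C -x, B +y, B' -y.

Arm trajectories are built from ideal B-DNA by a per-pathway "bend program"
(kinks at the IHF / Xis / A-tract positions plus small distributed rolls in
protein-free regions).  The bend-plane azimuths and small corrective rolls are
frozen design constants of this coarse model, chosen to satisfy the
architecture's qualitative constraints: the excisive P and P' arms run nearly
parallel without crossing, the integrative P arm passes over the P' arm with a
single negative crossing node, the P' arm is identical in both pathways, and
every Int bridge stays within reach of the 19-residue NTD-CB linker.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    IDEAL_RISE,
    IDEAL_TWIST_DEG,
    DuplexPath,
    RigidTransform,
    _axis_angle_matrix,
    _rotate_downstream,
    generate_bdna,
)
from .registry import (
    AttRegistry,
    OccupancyEnsemble,
    ensemble as registry_ensemble,
)

__all__ = [
    "Component",
    "JunctionCore",
    "Subunit",
    "Bridge",
    "AssemblyModel",
    "build_core",
    "isomerize",
    "assemble",
    "bridge_reachability",
    "crossing_sign",
    "signed_crossing_number",
    "writhe",
    "LINKER_RESIDUES",
    "CONTOUR_PER_RESIDUE",
]

# Int domain boundaries used in linker-reachability arithmetic:
# NTD 1-55, NTD-CB linker 56-74, catalytic+CB core 75-356.
NTD_RESIDUE_RANGE = (1, 55)
LINKER_RESIDUE_RANGE = (56, 74)
CTD_RESIDUE_RANGE = (75, 356)
LINKER_RESIDUES = LINKER_RESIDUE_RANGE[1] - LINKER_RESIDUE_RANGE[0] + 1  # 19
CONTOUR_PER_RESIDUE = 3.8  # A per residue, fully extended chain

CORE_SUBUNITS = ("B", "C'", "C", "B'")  # order around the junction (azimuth)
_EXIT_AZIMUTH = {"C'": 0.0, "B": 90.0, "C": 180.0, "B'": 270.0}


# --------------------------------------------------------------------------
# components

@dataclass
class Component:
    """A rigid pseudo-atom component (protein domain or protein-bent duplex)."""

    name: str
    positions: np.ndarray          # (n, 3) A
    radii: np.ndarray              # (n,) A
    chain_ids: list[str]
    residue_indices: np.ndarray    # (n,)
    anchors: dict[str, np.ndarray] = field(default_factory=dict)
    duplex: DuplexPath | None = None
    kink_steps: tuple[int, ...] = ()
    meta: dict = field(default_factory=dict)

    def transformed(self, t: RigidTransform) -> "Component":
        out = copy.deepcopy(self)
        out.positions = t.apply(self.positions)
        out.anchors = {k: t.apply(v) for k, v in self.anchors.items()}
        if out.duplex is not None:
            out.duplex = out.duplex.transformed(t)
        return out


# --------------------------------------------------------------------------
# junction core

_DEFAULT_CORE_GEOMETRY = {
    "exit_radius_cc": 12.0,      # C/C' arm-exit radius (A)
    "exit_radius_bb": 13.0,      # B/B' radius; slight inequality = pseudo-fourfold
    "scissile_radius_active": 8.0,
    "scissile_radius_inactive": 12.0,
    "scissile_z": -2.0,
    "overlap_bp_spacing": 1.6,   # coarse in-junction bp spacing along the C-C' axis
    "isomer_exit_twist_deg": 1.5,  # small torsional change of arm ends on isomerization
}

_ISOMERS = ("top_strand", "bottom_strand")
#: which diagonal pair of Ints is activated for cleavage in each isomer
ACTIVE_PAIRS = {"top_strand": ("B", "C"), "bottom_strand": ("B'", "C'")}


def _exit_triad(azimuth_deg: float) -> np.ndarray:
    """Right-handed triad with z = outward tangent in the junction plane."""
    a = np.deg2rad(azimuth_deg)
    z = np.array([np.cos(a), np.sin(a), 0.0])
    x = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


@dataclass
class JunctionCore:
    """The four-way junction: 7-bp overlap, arm exits, scissile phosphates."""

    overlap_seq: str
    isomer: str
    geometry: dict
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self):
        if len(self.overlap_seq) != 7:
            raise ValueError(
                "overlap region must span 7 bp (the strand exchanges are "
                "staggered by seven base pairs); override geometry explicitly "
                "to model a different spacer"
            )
        if self.isomer not in _ISOMERS:
            raise ValueError(f"isomer must be one of {_ISOMERS}")

    @property
    def branch_point(self) -> int:
        """Branch-point offset (bp) from the overlap center; the two isomers
        differ by exactly one bp of branch migration."""
        return 0 if self.isomer == "top_strand" else 1

    def _local_exits(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        g = self.geometry
        sign = +1.0 if self.isomer == "top_strand" else -1.0
        dphi = sign * g["isomer_exit_twist_deg"] / 2.0
        out = {}
        for name, az in _EXIT_AZIMUTH.items():
            r = g["exit_radius_cc"] if name in ("C", "C'") else g["exit_radius_bb"]
            a = az + dphi
            tri = _exit_triad(a)
            origin = r * np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a)), 0.0])
            out[name] = (origin, tri)
        return out

    def arm_exits(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """World-frame (origin, triad) of the four arm exits, keyed B/B'/C/C'."""
        t = self.transform
        return {
            k: (t.apply(o), t.rotation @ tri)
            for k, (o, tri) in self._local_exits().items()
        }

    def scissile_phosphates(self) -> dict[str, np.ndarray]:
        g = self.geometry
        active = ACTIVE_PAIRS[self.isomer]
        out = {}
        for name, az in _EXIT_AZIMUTH.items():
            r = (
                g["scissile_radius_active"]
                if name in active
                else g["scissile_radius_inactive"]
            )
            a = np.deg2rad(az)
            p = np.array([r * np.cos(a), r * np.sin(a), g["scissile_z"]])
            out[name] = self.transform.apply(p)
        return out

    def diagonals(self) -> tuple[float, float]:
        """(active, inactive) scissile-phosphate diagonal lengths (A)."""
        sp = self.scissile_phosphates()
        active = ACTIVE_PAIRS[self.isomer]
        inactive = tuple(s for s in CORE_SUBUNITS if s not in active)
        d_act = float(np.linalg.norm(sp[active[0]] - sp[active[1]]))
        d_in = float(np.linalg.norm(sp[inactive[0]] - sp[inactive[1]]))
        return d_act, d_in

    def overlap_bp_origins(self) -> np.ndarray:
        """Coarse origins of the 7 overlap bp (att -3..+3) along the C-C' axis,
        shifted by the branch-point offset."""
        g = self.geometry
        att = np.arange(-3, 4, dtype=float)
        x = (att + 0.5 * self.branch_point) * g["overlap_bp_spacing"]
        pts = np.column_stack([x, np.zeros(7), np.full(7, -1.0)])
        return self.transform.apply(pts)

    def ctd_attachment(self) -> dict[str, np.ndarray]:
        """Linker attachment point (residue ~74) per CTD, top inner corner."""
        out = {}
        for name, az in _EXIT_AZIMUTH.items():
            a = np.deg2rad(az)
            p = np.array([14.0 * np.cos(a), 14.0 * np.sin(a), 4.0])
            out[name] = self.transform.apply(p)
        return out


def build_core(
    overlap_seq: str = "TTTATAC",
    isomer: str = "bottom_strand",
    geometry: dict | None = None,
) -> JunctionCore:
    """Build the coarse four-way junction core.

    The default isomer is the bottom-strand cleavage configuration (B' and C'
    activated), the one poised to resolve toward attP + attB products.  Coarse
    geometry is sequence-independent; the sequence is carried for bookkeeping.
    """
    geo = dict(_DEFAULT_CORE_GEOMETRY)
    if geometry:
        geo.update(geometry)
    return JunctionCore(str(overlap_seq).upper(), isomer, geo)


def isomerize(core: JunctionCore) -> JunctionCore:
    """Branch-migrate by one bp: toggle the isomer, exchanging the active and
    inactive scissile diagonals, with only small arm-end displacements.
    Applying it twice restores the original core exactly."""
    other = "bottom_strand" if core.isomer == "top_strand" else "top_strand"
    out = JunctionCore(core.overlap_seq, other, dict(core.geometry))
    out.transform = RigidTransform(
        core.transform.rotation.copy(), core.transform.translation.copy()
    )
    return out


# --------------------------------------------------------------------------
# bend programs (frozen design constants)

def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# Each op: ("kink", step, axis, angle_deg) — a discrete protein kink;
#          ("rolls", step0, step1, axis, total_deg) — distributed small rolls,
#          one per step in [step0, step1], all about the same world axis.
# Axes are world-frame; angles follow the right-hand rule.
#
# P' arm (identical for both pathways): exits C' along +x, the IHF kinks at H'
# (steps 15 and 24, 9 bp apart) U-turn it up and back over the Int tetramer;
# protein-free rolls complete the turnaround and give the return leg a small
# lateral drift so it clears the outbound leg.
PPRIME_BEND_PROGRAM = [
    ("kink", 15, (0.0, 1.0, 0.0), -85.0),
    ("kink", 24, (0.0, 1.0, 0.0), -85.0),
    ("rolls", 25, 42, (0.0, 1.0, 0.0), -10.0),
    ("rolls", 25, 42, (0.0, 0.0, 1.0), 8.0),
]

# Excisive P arm: exits C along -x; the IHF kinks at H2 (steps 27 / 36) are
# phased laterally so the arm runs back alongside the tetramer at low z; the
# three Xis bends (at the X1/X1.5/X2 centers) pitch it up and swing it east
# over the top, positioning P2 within reach of the B' NTD while the distal
# (H1/P1) tail exits parallel to the P' arm without crossing it.
P_EXCISIVE_BEND_PROGRAM = [
    ("kink", 27, (0.0, 0.0, 1.0), 85.0),
    ("kink", 36, (0.0, 0.0, 1.0), 85.0),
    ("kink", 50, (0.174, 0.985, 0.0), -20.0),
    ("kink", 60, (0.0, 0.0, 1.0), 16.0),
    ("kink", 71, (0.0, 0.0, 1.0), 16.0),
    ("rolls", 72, 84, (-0.353, 0.871, 0.0), 14.0),
]

# Integrative P arm: no Xis; after the same lateral H2 U-turn the arm climbs
# (protein-free pitch at step 45), then the A-tract bend at the Fis site plus
# supercoiling-like bending swings it north across and above the P' return
# leg (the single negative node), and the H1 kinks (steps 99 / 108) U-turn it
# back down, delivering P1 to the Int-B NTD on the opposite face.
P_INTEGRATIVE_BEND_PROGRAM = [
    ("kink", 27, (0.0, 0.0, 1.0), 85.0),
    ("kink", 36, (0.0, 0.0, 1.0), 85.0),
    ("kink", 45, (0.174, 0.985, 0.0), -35.0),
    ("kink", 71, (-0.565, 0.005, 0.796), 87.6),
    ("kink", 99, (-0.985, 0.162, -0.075), 60.0),
    ("kink", 108, (-0.985, 0.162, -0.075), 60.0),
]

#: IHF kink steps per site (arm path index); 9-bp separation.
IHF_KINK_STEPS = {"H2": (27, 36), "H'": (15, 24), "H1": (99, 108)}
#: Xis bend steps (X1, X1.5, X2 centers on the P-arm path).
XIS_BEND_STEPS = (50, 60, 71)


def _apply_bend_program(path: DuplexPath, program) -> DuplexPath:
    for op in program:
        if op[0] == "kink":
            _, step, axis, angle = op
            g = _axis_angle_matrix(_unit(axis), angle)
            path = _rotate_downstream(path, step, g, path.origins[step])
        elif op[0] == "rolls":
            _, s0, s1, axis, total = op
            per = total / (s1 - s0 + 1)
            g = _axis_angle_matrix(_unit(axis), per)
            for s in range(s0, s1 + 1):
                path = _rotate_downstream(path, s, g, path.origins[s])
        else:
            raise ValueError(f"unknown bend op {op[0]!r}")
    return path


# --------------------------------------------------------------------------
# assembly model

@dataclass
class Subunit:
    """One placed protein subunit (pseudo-atom cloud)."""

    name: str
    kind: str  # Int | IHF | Xis
    chain_id: str
    positions: np.ndarray
    radii: np.ndarray
    residue_indices: np.ndarray


@dataclass
class Bridge:
    core_subunit: str
    arm_site: str
    span: float = float("nan")
    max_span: float = LINKER_RESIDUES * CONTOUR_PER_RESIDUE
    feasible: bool = False


class AssemblyError(RuntimeError):
    pass


@dataclass
class AssemblyModel:
    pathway: str
    registry: AttRegistry
    ensemble: OccupancyEnsemble
    junction: JunctionCore
    dna: dict[str, DuplexPath]               # arms keyed P, P', B, B'
    dna_att: dict[str, np.ndarray]           # att coordinate per bp of each arm
    subunits: list[Subunit]
    bridges: list[Bridge]
    ntd_anchor: dict[str, np.ndarray]        # occupied arm site -> NTD anchor
    ctd_anchor: dict[str, np.ndarray]        # core subunit -> linker attachment

    def all_pseudo_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """(positions, radii) over all protein subunits."""
        if not self.subunits:
            return np.zeros((0, 3)), np.zeros(0)
        pos = np.concatenate([s.positions for s in self.subunits])
        rad = np.concatenate([s.radii for s in self.subunits])
        return pos, rad

    def dna_bp_count(self) -> int:
        return sum(len(p) for p in self.dna.values()) + len(self.junction.overlap_seq)

    def bp_origin(self, line: str, att: int) -> np.ndarray:
        """Origin of the bp at att coordinate `att` on line 'attP' or 'attB'."""
        if line == "attP" and -3 <= att <= 3:
            return self.junction.overlap_bp_origins()[att + 3]
        arms = ("P", "P'") if line == "attP" else ("B", "B'")
        for arm in arms:
            coords = self.dna_att[arm]
            hit = np.nonzero(coords == att)[0]
            if hit.size:
                return self.dna[arm].origins[hit[0]]
        raise KeyError(
            f"position {att:+d} on {line} is outside the modeled DNA "
            "(extended arms are not part of this construct)"
        )

    def arm_crossing(self, view_axis=(0.0, 0.0, 1.0)) -> tuple[int, int]:
        """(node sign, crossing count) of the P x P' arm crossing, with both
        arms oriented along increasing att coordinate (the P path is stored
        core-to-distal, i.e. att-decreasing, so it is reversed here)."""
        return crossing_sign(
            self.dna["P"].origins[::-1], self.dna["P'"], view_axis
        )

    def bp_frame(self, line: str, att: int):
        if line == "attP" and -3 <= att <= 3:
            origin = self.junction.overlap_bp_origins()[att + 3]
            return origin, self.junction.transform.rotation @ np.eye(3)
        arms = ("P", "P'") if line == "attP" else ("B", "B'")
        for arm in arms:
            coords = self.dna_att[arm]
            hit = np.nonzero(coords == att)[0]
            if hit.size:
                i = hit[0]
                return self.dna[arm].origins[i], self.dna[arm].triads[i]
        raise KeyError(f"position {att:+d} on {line} is outside the modeled DNA")


def _place_subunit(comp: Component, name: str, kind: str, chain_id: str,
                   t: RigidTransform) -> Subunit:
    placed = comp.transformed(t)
    return Subunit(
        name, kind, chain_id, placed.positions, placed.radii.copy(),
        placed.residue_indices.copy(),
    )


def _frame_transform(origin: np.ndarray, triad: np.ndarray) -> RigidTransform:
    return RigidTransform(np.asarray(triad, dtype=float), np.asarray(origin, float))


_CHAIN_IDS = list("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


def assemble(
    pathway: str,
    registry: AttRegistry,
    components: dict[str, Component],
    config: dict | None = None,
) -> AssemblyModel:
    """Build the coarse excisive or integrative complex model.

    Excisive: 11 protein subunits (Int x4, two IHF heterodimers at H2/H',
    Xis x3), three Int bridges, P and P' arms parallel without crossing, the
    Int-C NTD left unplaced (no density accounts for it).  Integrative: ten
    subunits (Int x4, three IHF heterodimers), four bridges, the P arm passing
    over the unchanged P' arm with one negative crossing node.
    """
    cfg = dict(config or {})
    ens = registry_ensemble(registry, pathway)
    need = {"IntCTD_tetramer_core", "IntNTD", "IHF_duplex", "Xis_segment"}
    if pathway == "integrative":
        need.discard("Xis_segment")
    missing = need - set(components)
    if missing:
        raise AssemblyError(f"missing component(s): {sorted(missing)}")

    core_comp = components["IntCTD_tetramer_core"]
    junction = build_core(
        overlap_seq=cfg.get("overlap_seq", "TTTATAC"),
        isomer=cfg.get("isomer", "bottom_strand"),
        geometry=cfg.get("core_geometry"),
    )
    exits = junction.arm_exits()

    # ---- DNA arms -----------------------------------------------------
    def arm_path(exit_name: str, n_bp: int, program) -> DuplexPath:
        path = generate_bdna("A" * n_bp)
        origin, triad = exits[exit_name]
        path = path.transformed(_frame_transform(origin, triad))
        return _apply_bend_program(path, program)

    p_lo, p_hi = registry.p_arm
    pp_lo, pp_hi = registry.pprime_arm
    b_lo, b_hi = registry.b_flank
    bp_lo, bp_hi = registry.bprime_flank
    n_p = p_hi - p_lo + 1
    n_pp = pp_hi - pp_lo + 1

    p_program = (
        P_EXCISIVE_BEND_PROGRAM if pathway == "excisive" else P_INTEGRATIVE_BEND_PROGRAM
    )
    dna = {
        "P": arm_path("C", n_p, p_program),
        "P'": arm_path("C'", n_pp, PPRIME_BEND_PROGRAM),
        "B": arm_path("B", b_hi - b_lo + 1, []),
        "B'": arm_path("B'", bp_hi - bp_lo + 1, []),
    }
    dna_att = {
        "P": -4 - np.arange(n_p),            # i=0 at att -4, distal negative
        "P'": 4 + np.arange(n_pp),
        "B": -4 - np.arange(b_hi - b_lo + 1),
        "B'": 4 + np.arange(bp_hi - bp_lo + 1),
    }

    def arm_index(arm: str, att: float) -> int:
        coords = dna_att[arm]
        return int(np.argmin(np.abs(coords - att)))

    # ---- protein placement -------------------------------------------
    subunits: list[Subunit] = []
    chains = iter(_CHAIN_IDS)
    ctd_anchor = junction.ctd_attachment()

    # Int subunits: the CTD tetramer component carries one cloud per core
    # half-site in the junction local frame.
    placed_core = core_comp.transformed(junction.transform)
    for s in CORE_SUBUNITS:
        sel = [i for i, c in enumerate(placed_core.chain_ids) if c == s]
        subunits.append(
            Subunit(
                f"Int_{s}", "Int", next(chains),
                placed_core.positions[sel],
                placed_core.radii[sel],
                placed_core.residue_indices[sel],
            )
        )

    # IHF heterodimers at the occupied IHF sites: the component cloud is built
    # around its own kink vertex anchor; place it at the arm's kink midpoint.
    ihf_sites = sorted(
        s for s in ens.occupied_sites if registry[s].category == "ihf"
    )
    ihf = components["IHF_duplex"]
    for site in ihf_sites:
        arm = "P'" if site == "H'" else "P"
        k1, k2 = IHF_KINK_STEPS[site]
        path = dna[arm]
        mid = 0.5 * (path.origins[k1] + path.origins[k2])
        # concave-side offset: toward the average of the surrounding tangents
        t_in = _unit(path.origins[k1] - path.origins[k1 - 4])
        t_out = _unit(path.origins[min(k2 + 4, len(path) - 1)] - path.origins[k2])
        inward = t_out - t_in
        inward = _unit(inward) if np.linalg.norm(inward) > 1e-6 else np.array([0, 0, 1.0])
        t = RigidTransform(np.eye(3), mid + 6.0 * inward)
        placed = ihf.transformed(t)
        for half, cid in (("alpha", next(chains)), ("beta", next(chains))):
            sel = [i for i, c in enumerate(placed.chain_ids) if c == half]
            subunits.append(
                Subunit(
                    f"IHF_{site}_{half}", "IHF", cid,
                    placed.positions[sel], placed.radii[sel],
                    placed.residue_indices[sel],
                )
            )

    # Xis subunits (excisive only) at the three X sites on the P arm.
    if pathway == "excisive":
        xis = components["Xis_segment"]
        x_sites = ["X1", "X1.5", "X2"]
        for site, step in zip(x_sites, XIS_BEND_STEPS):
            path = dna["P"]
            pos = path.origins[step] + 5.0 * path.triads[step][:, 0]
            sel = [i for i, c in enumerate(xis.chain_ids) if c == "subunit"]
            t = RigidTransform(np.eye(3), pos - xis.positions[sel].mean(axis=0))
            placed = xis.transformed(t)
            subunits.append(
                Subunit(
                    f"Xis_{site}", "Xis", next(chains),
                    placed.positions[sel], placed.radii[sel],
                    placed.residue_indices[sel],
                )
            )

    # Int NTDs at the occupied arm-type sites (the Int-C NTD has no arm site
    # in the excisive complex and is omitted from the model).
    ntd = components["IntNTD"]
    ntd_anchor: dict[str, np.ndarray] = {}
    arm_sites = sorted(
        s for s in ens.occupied_sites if registry[s].category == "arm"
    )
    bridge_by_site = {site: sub for sub, site in ens.bridges}
    ntd_extra: dict[str, np.ndarray] = {}
    for site in arm_sites:
        arm = "P" if registry[site].arm == "P" else "P'"
        i = arm_index(arm, registry[site].center)
        path = dna[arm]
        anchor = path.origins[i] + 6.0 * path.triads[i][:, 0]
        ntd_anchor[site] = anchor
        t = RigidTransform(np.eye(3), anchor - ntd.positions.mean(axis=0))
        placed = ntd.transformed(t)
        # NTDs belong to the bridging Int subunit; merge their cloud into it
        sub_name = f"Int_{bridge_by_site[site]}"
        for s in subunits:
            if s.name == sub_name:
                s.positions = np.concatenate([s.positions, placed.positions])
                s.radii = np.concatenate([s.radii, placed.radii])
                s.residue_indices = np.concatenate(
                    [s.residue_indices, placed.residue_indices]
                )
                break

    # ---- bridges ------------------------------------------------------
    bridges = [Bridge(sub, site) for sub, site in ens.bridges]
    model = AssemblyModel(
        pathway, registry, ens, junction, dna, dna_att, subunits, bridges,
        ntd_anchor, ctd_anchor,
    )
    report = bridge_reachability(model)
    for b in report:
        if not b.feasible:
            raise AssemblyError(
                f"bridge {b.core_subunit}-{b.arm_site} infeasible: span "
                f"{b.span:.1f} A exceeds the {b.max_span:.1f} A linker reach"
            )
    model.bridges = report
    return model


def bridge_reachability(
    model: AssemblyModel,
    residues_per_linker: int = LINKER_RESIDUES,
    contour_per_residue: float = CONTOUR_PER_RESIDUE,
) -> list[Bridge]:
    """Per-bridge linker-span report.

    A bridge is feasible iff the CTD-to-NTD anchor separation does not exceed
    the fully extended NTD-CB linker contour length (19 residues x 3.8 A/res
    = 72.2 A by default)."""
    max_span = residues_per_linker * contour_per_residue
    out = []
    for b in model.bridges:
        if b.arm_site not in model.ntd_anchor:
            raise AssemblyError(
                f"bridge {b.core_subunit}-{b.arm_site} references an "
                "unoccupied arm site"
            )
        span = float(
            np.linalg.norm(
                model.ctd_anchor[b.core_subunit] - model.ntd_anchor[b.arm_site]
            )
        )
        out.append(Bridge(b.core_subunit, b.arm_site, span, max_span, span <= max_span))
    return out


# --------------------------------------------------------------------------
# crossing topology

def _projection_basis(view_axis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    v = _unit(view_axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(v, ref))
    e2 = np.cross(v, e1)
    return e1, e2, v


def _segment_crossings(pa, pb, va, vb, v_hat, e1, e2, tangency_tol=0.5,
                       perturb=1e-3):
    """Signed crossings between two polylines projected along v_hat.

    Returns a list of crossing signs: +1 for a crossing where (t_over,
    t_under, viewer) is right-handed, -1 otherwise; viewer looks along
    -v_hat (v_hat points toward the viewer).  Near-tangent crossings are
    perturbed infinitesimally along the view axis before evaluation.
    """
    def proj(p):
        return np.column_stack([p @ e1, p @ e2])

    a2, b2 = proj(pa), proj(pb)
    ha, hb = pa @ v_hat, pb @ v_hat
    signs = []
    for i in range(len(a2) - 1):
        p, r = a2[i], a2[i + 1] - a2[i]
        for j in range(len(b2) - 1):
            q, s = b2[j], b2[j + 1] - b2[j]
            denom = r[0] * s[1] - r[1] * s[0]
            if abs(denom) < 1e-12:
                continue
            dq = q - p
            t = (dq[0] * s[1] - dq[1] * s[0]) / denom
            u = (dq[0] * r[1] - dq[1] * r[0]) / denom
            if not (0.0 <= t < 1.0 and 0.0 <= u < 1.0):
                continue
            za = ha[i] + t * (ha[i + 1] - ha[i])
            zb = hb[j] + u * (hb[j + 1] - hb[j])
            if abs(za - zb) < tangency_tol:
                za += perturb  # resolve near-tangency deterministically
            ta = va[i] if va.ndim > 1 else va
            tb = vb[j] if vb.ndim > 1 else vb
            t_over, t_under = (ta, tb) if za > zb else (tb, ta)
            cross = np.cross(
                np.append(t_over @ np.column_stack([e1, e2]), 0.0),
                np.append(t_under @ np.column_stack([e1, e2]), 0.0),
            )
            signs.append(1 if cross[2] > 0 else -1)
    return signs


def _polyline_tangents(p: np.ndarray) -> np.ndarray:
    return np.diff(p, axis=0)


def crossing_sign(
    arm_a: DuplexPath | np.ndarray,
    arm_b: DuplexPath | np.ndarray,
    view_axis=(0.0, 0.0, 1.0),
) -> tuple[int, int]:
    """Net sign and count of projected crossings between two DNA arms.

    Uses the standard supercoiling node convention: with both duplexes
    oriented consistently (along increasing att coordinate) the node sign is
    the knot-theoretic crossing sign, so a right-handed (negatively
    supercoiled plectoneme-like) crossing scores -1::

          under   over            under    over
             \    /                  \     /
              \  v                    \   ^
               \/          vs          \ /
               /\                       x
              /  \                     / \\
             v    \                   v   \
            node -1                  node +1

    Callers are responsible for orienting both curves consistently
    (AssemblyModel.arm_crossing does this for the P/P' arms).  Returns
    (net_sign in {-1, 0, +1}, crossing count).
    """
    pa = arm_a.origins if isinstance(arm_a, DuplexPath) else np.asarray(arm_a, float)
    pb = arm_b.origins if isinstance(arm_b, DuplexPath) else np.asarray(arm_b, float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("arms must be non-empty")
    e1, e2, v = _projection_basis(view_axis)
    signs = _segment_crossings(
        pa, pb, _polyline_tangents(pa), _polyline_tangents(pb), v, e1, e2
    )
    total = sum(signs)
    net = 0 if total == 0 else (1 if total > 0 else -1)
    return net, len(signs)


def signed_crossing_number(points: np.ndarray, view_axis) -> int:
    """Sum of knot-theoretic crossing signs of one polyline with itself in the
    projection along view_axis (adjacent segments excluded)."""
    p = np.asarray(points, float)
    e1, e2, v = _projection_basis(view_axis)
    tang = _polyline_tangents(p)
    total = 0
    n = len(p) - 1
    for i in range(n):
        for j in range(i + 2, n):
            signs = _segment_crossings(
                p[i : i + 2], p[j : j + 2], tang[i : i + 1], tang[j : j + 1],
                v, e1, e2,
            )
            total += sum(signs)
    return total


def writhe(points: np.ndarray) -> float:
    """Gauss double-integral writhe of a polygonal curve.

    Exact per-segment-pair solid-angle evaluation (Klenin & Langowski method
    1a).  Equals the average, over all projection directions, of the signed
    self-crossing number."""
    p = np.asarray(points, dtype=float)
    if len(p) < 4:
        raise ValueError("writhe needs at least 4 points")
    n = len(p) - 1
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            total += _segment_pair_writhe(p[i], p[i + 1], p[j], p[j + 1])
    return 2.0 * total


def _segment_pair_writhe(p1, p2, p3, p4) -> float:
    r12 = p2 - p1
    r34 = p4 - p3
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2

    def unit_or_zero(v):
        nv = np.linalg.norm(v)
        return v / nv if nv > 1e-12 else None

    n1 = unit_or_zero(np.cross(r13, r14))
    n2 = unit_or_zero(np.cross(r14, r24))
    n3 = unit_or_zero(np.cross(r24, r23))
    n4 = unit_or_zero(np.cross(r23, r13))
    if n1 is None or n2 is None or n3 is None or n4 is None:
        return 0.0  # coplanar/degenerate pair contributes nothing

    def asin_clip(x):
        return float(np.arcsin(np.clip(x, -1.0, 1.0)))

    omega = (
        asin_clip(np.dot(n1, n2))
        + asin_clip(np.dot(n2, n3))
        + asin_clip(np.dot(n3, n4))
        + asin_clip(np.dot(n4, n1))
    )
    sign = np.sign(np.dot(np.cross(r34, r12), r13))
    return omega * sign / (4.0 * np.pi)
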