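"""The att-site coordinate system: binding sites, occupancy ensembles, bridges.

The 240-bp att region carries 16 protein-binding sites (5 arm-type Int sites,
3 IHF sites, 3 Xis sites, 1 Fis site, 4 core half-sites) plus the 7-bp overlap
region O.  Positions are integers on the top strand, origin at the center bp
of the overlap, P arm negative, P' arm positive; intervals closed/inclusive.
B and B' live on the attB-side coordinate line.  Excisive and integrative
recombination use two distinct but overlapping ensembles of these sites, with
different Int bridge patterns (3 bridges for excision, 4 for integration).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "BindingSite",
    "AttRegistry",
    "OccupancyEnsemble",
    "RegistryError",
    "load_registry",
    "ensemble",
    "EXCISIVE_BRIDGES",
    "INTEGRATIVE_BRIDGES",
]

SITE_NAMES = [
    "P1", "H1", "P2", "X1", "X1.5", "X2", "F", "H2",
    "C", "O", "C'", "H'", "P'1", "P'2", "P'3", "B", "B'",
]
CATEGORIES = {"arm", "ihf", "xis", "fis", "core", "overlap"}
ARMS = {"P", "P'", "core"}

#: (core half-site subunit, arm site) Int bridges per pathway.
EXCISIVE_BRIDGES = [("C'", "P'1"), ("B", "P'2"), ("B'", "P2")]
INTEGRATIVE_BRIDGES = [("C'", "P'1"), ("C", "P'2"), ("B'", "P'3"), ("B", "P1")]

#: core-proximal -> distal site order along each arm (Xis/Fis cluster order is
#: a schematic-derived default and configurable via the registry TSV).
_P_ARM_ORDER = ["H2", "X1", "X1.5", "X2", "P2", "H1", "P1"]
_PPRIME_ARM_ORDER = ["H'", "P'1", "P'2", "P'3"]

# attB-line records (kept on their own coordinate line for overlap checks)
_ATTB_SITES = {"B", "B'"}


class RegistryError(ValueError):
    """Raised when a registry file violates the att-site invariants."""


@dataclass(frozen=True)
class BindingSite:
    name: str
    category: str
    arm: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise RegistryError(f"site {self.name}: unknown category {self.category!r}")
        if self.arm not in ARMS:
            raise RegistryError(f"site {self.name}: unknown arm {self.arm!r}")
        if self.end < self.start:
            raise RegistryError(f"site {self.name}: end < start")


@dataclass
class AttRegistry:
    """All named sites plus the arm extents of the modeled att DNA."""

    sites: dict[str, BindingSite]
    att_length: int = 240
    p_arm: tuple[int, int] = (-130, -4)
    pprime_arm: tuple[int, int] = (4, 79)
    b_flank: tuple[int, int] = (-18, -4)
    bprime_flank: tuple[int, int] = (4, 18)

    def __getitem__(self, name: str) -> BindingSite:
        return self.sites[name]

    @property
    def protein_sites(self) -> list[BindingSite]:
        return [s for s in self.sites.values() if s.category != "overlap"]

    @property
    def overlap(self) -> BindingSite:
        return self.sites["O"]

    def span_bp(self) -> int:
        """Total modeled DNA: P arm + overlap + P' arm + attB flanks."""
        spans = [self.p_arm, self.pprime_arm, self.b_flank, self.bprime_flank]
        total = sum(b - a + 1 for a, b in spans)
        return total + self.overlap.width

    def validate(self) -> None:
        missing = set(SITE_NAMES) - set(self.sites)
        if missing:
            raise RegistryError(f"missing site(s): {sorted(missing)}")
        n_protein = len(self.protein_sites)
        if n_protein != 16:
            raise RegistryError(f"expected 16 protein-binding sites, found {n_protein}")
        counts = {}
        for s in self.protein_sites:
            counts[s.category] = counts.get(s.category, 0) + 1
        expected = {"arm": 5, "ihf": 3, "xis": 3, "fis": 1, "core": 4}
        if counts != expected:
            raise RegistryError(f"site category census {counts} != {expected}")
        if self.overlap.width != 7:
            raise RegistryError(
                f"overlap O spans {self.overlap.width} bp; the strand exchanges "
                "are staggered by 7 bp (override explicitly to change)"
            )
        if self.span_bp() != self.att_length:
            raise RegistryError(
                f"modeled DNA spans {self.span_bp()} bp != configured "
                f"att_length {self.att_length}"
            )
        self._check_order("P", _P_ARM_ORDER)
        self._check_order("P'", _PPRIME_ARM_ORDER)
        self._check_overlaps()

    def _check_order(self, arm: str, order: list[str]) -> None:
        dists = []
        for name in order:
            s = self.sites[name]
            if s.arm != arm:
                raise RegistryError(f"site {name} expected on arm {arm}, got {s.arm}")
            dists.append((name, abs(s.center)))
        for (na, da), (nb, db) in zip(dists, dists[1:]):
            if db <= da:
                raise RegistryError(
                    f"ordering violation on arm {arm}: {nb} must lie core-distal "
                    f"to {na}"
                )

    def _check_overlaps(self) -> None:
        def clash(a: BindingSite, b: BindingSite) -> bool:
            return a.start <= b.end and b.start <= a.end

        lines: dict[str, list[BindingSite]] = {"attP": [], "attB": []}
        for s in self.sites.values():
            lines["attB" if s.name in _ATTB_SITES else "attP"].append(s)
        allowed = {frozenset({"X2", "F"})}
        for group in lines.values():
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    if clash(a, b) and frozenset({a.name, b.name}) not in allowed:
                        raise RegistryError(
                            f"sites {a.name} and {b.name} overlap "
                            f"([{a.start},{a.end}] vs [{b.start},{b.end}])"
                        )


@dataclass(frozen=True)
class OccupancyEnsemble:
    pathway: str
    occupied_sites: frozenset[str]
    bridges: tuple[tuple[str, str], ...]
    fis_present: bool = False

    @property
    def n_bridges(self) -> int:
        return len(self.bridges)


_EXCISIVE_OCCUPIED = frozenset(
    {"C", "C'", "B", "B'", "H2", "H'", "X1", "X1.5", "X2", "P2", "P'1", "P'2"}
)
_INTEGRATIVE_OCCUPIED = frozenset(
    {"C", "C'", "B", "B'", "H1", "H2", "H'", "P1", "P'1", "P'2", "P'3"}
)


def default_registry_path() -> Path:
    return Path(importlib.resources.files("intasome") / "data" / "att_sites.tsv")


def load_registry(config_path: str | Path | None = None) -> AttRegistry:
    """Load and validate a registry TSV (packaged default when path is None).

    Columns: name, category, arm, start, end.  Lines beginning ``#key\\tval``
    set registry-level extents (att_length, p_arm, pprime_arm, b_flank,
    bprime_flank).
    """
    path = Path(config_path) if config_path is not None else default_registry_path()
    sites: dict[str, BindingSite] = {}
    meta: dict[str, tuple[int, ...]] = {}
    header: list[str] | None = None
    for raw in path.read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if len(parts) >= 2 and parts[0].strip() in {
                "att_length", "p_arm", "pprime_arm", "b_flank", "bprime_flank"
            }:
                meta[parts[0].strip()] = tuple(int(p) for p in parts[1:] if p.strip())
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            if header[:5] != ["name", "category", "arm", "start", "end"]:
                raise RegistryError(f"unexpected registry columns {header}")
            continue
        name, category, arm, start, end = (p.strip() for p in parts[:5])
        if name in sites:
            raise RegistryError(f"duplicate site record {name}")
        sites[name] = BindingSite(name, category, arm, int(start), int(end))
    extra = set(sites) - set(SITE_NAMES)
    if extra:
        raise RegistryError(f"unknown site record(s): {sorted(extra)}")
    kwargs = {}
    if "att_length" in meta:
        kwargs["att_length"] = meta["att_length"][0]
    for key in ("p_arm", "pprime_arm", "b_flank", "bprime_flank"):
        if key in meta:
            kwargs[key] = (meta[key][0], meta[key][1])
    reg = AttRegistry(sites, **kwargs)
    reg.validate()
    return reg


def ensemble(registry: AttRegistry, pathway: str) -> OccupancyEnsemble:
    """The fixed site-occupancy ensemble and Int bridge pattern of a pathway.

    Excisive complexes (as purified, without Fis) occupy H2, H' and all three
    Xis sites and use three Int bridges; integrative complexes occupy all
    three IHF sites and four arm sites with four bridges and no Xis.
    """
    if pathway == "excisive":
        occ, bridges = _EXCISIVE_OCCUPIED, EXCISIVE_BRIDGES
    elif pathway == "integrative":
        occ, bridges = _INTEGRATIVE_OCCUPIED, INTEGRATIVE_BRIDGES
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    unknown = occ - set(registry.sites)
    if unknown:
        raise RegistryError(f"ensemble references unknown sites {sorted(unknown)}")
    return OccupancyEnsemble(pathway, occ, tuple(bridges), fis_present=False)
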