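"""Distance, accessibility and census validation of assembled models.

Includes the comparison of model inter-dye distances against the published
in-gel FRET distance estimates for the excisive complex (packaged as a CSV
table).  Label sites follow the attP/attB nomenclature: an arm letter (P for
the attP line, B for attB), a signed bp offset from the overlap center, and
the labeled strand (T top / B bottom), e.g. ``P+50T`` or ``B-15T``.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import AssemblyModel

__all__ = [
    "LabelSite",
    "FretRecord",
    "load_fret_table",
    "site_distance",
    "fret_compare",
    "dye_accessibility",
    "census",
]

_LABEL_RE = re.compile(r"^([PB])([+-]\d+)([TB])$")


@dataclass(frozen=True)
class LabelSite:
    """A dye-labeled position, e.g. P+50T (attP, bp +50, top strand)."""

    label: str

    @classmethod
    def parse(cls, label: str) -> "LabelSite":
        if not _LABEL_RE.match(label):
            raise ValueError(
                f"cannot parse label site {label!r}; expected e.g. 'P+50T' "
                "(arm letter P/B, signed offset, strand T/B)"
            )
        return cls(label)

    @property
    def line(self) -> str:
        return "attP" if self.label[0] == "P" else "attB"

    @property
    def offset(self) -> int:
        return int(_LABEL_RE.match(self.label).group(2))

    @property
    def strand(self) -> str:
        return _LABEL_RE.match(self.label).group(3)


@dataclass(frozen=True)
class FretRecord:
    site_i: LabelSite
    site_j: LabelSite
    r_fret: float
    r_fret_model: float
    r_em_model: float
    group: str

    def __post_init__(self):
        for r in (self.r_fret, self.r_fret_model, self.r_em_model):
            if r <= 0:
                raise ValueError("FRET distances must be positive")


def _fret_table_path() -> Path:
    return Path(importlib.resources.files("intasome") / "data" / "fret_table1.csv")


def load_fret_table(path: str | Path | None = None) -> list[FretRecord]:
    """The packaged FRET-vs-model distance table for the excisive complex.

    Groups: ``free`` (dye sites clear of steric interference), and
    ``conflict_site3`` / ``conflict_site8`` (dyes at attP -118 and +79, which
    clash with the P' arm and the P2-bound NTD respectively, so poorer
    agreement is expected)."""
    df = pd.read_csv(path or _fret_table_path())
    return [
        FretRecord(
            LabelSite.parse(r.position_i),
            LabelSite.parse(r.position_j),
            float(r.r_fret),
            float(r.r_fret_model),
            float(r.r_em_model),
            str(r.group),
        )
        for r in df.itertuples()
    ]


def site_distance(model: AssemblyModel, a: LabelSite | str, b: LabelSite | str) -> float:
    """Euclidean distance (A) between the bp-frame origins at two label sites.

    Raises KeyError for positions on arm extensions outside the modeled
    construct."""
    if isinstance(a, str):
        a = LabelSite.parse(a)
    if isinstance(b, str):
        b = LabelSite.parse(b)
    pa = model.bp_origin(a.line, a.offset)
    pb = model.bp_origin(b.line, b.offset)
    return float(np.linalg.norm(pa - pb))


def fret_compare(
    model_or_distances: AssemblyModel | dict[tuple[str, str], float],
    records: list[FretRecord],
) -> pd.DataFrame:
    """Per-pair |R(FRET) - R(model)| and group-wise RMS.

    `model_or_distances` is either an assembled model (distances measured via
    site_distance) or a precomputed {(label_i, label_j): distance} mapping.
    Returns a DataFrame with one row per record plus the columns
    ``delta`` = |r_fret - r_model| and ``group_rms``.
    """
    if not records:
        raise ValueError("no FRET records to compare")
    rows = []
    for rec in records:
        key = (rec.site_i.label, rec.site_j.label)
        if isinstance(model_or_distances, dict):
            r_model = model_or_distances[key]
        else:
            r_model = site_distance(model_or_distances, rec.site_i, rec.site_j)
        rows.append(
            {
                "position_i": key[0],
                "position_j": key[1],
                "r_fret": rec.r_fret,
                "r_model": r_model,
                "delta": abs(rec.r_fret - r_model),
                "group": rec.group,
            }
        )
    df = pd.DataFrame(rows)
    rms = df.groupby("group")["delta"].apply(lambda d: float(np.sqrt(np.mean(d**2))))
    df["group_rms"] = df["group"].map(rms)
    return df


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _attachment_point(model: AssemblyModel, site: LabelSite) -> np.ndarray:
    """Dye proxy position: the labeled bp origin displaced 10 A along the
    major-groove direction of the labeled strand (frame x-axis for the top
    strand, rotated 144 deg about the helix axis for the bottom strand)."""
    origin, triad = model.bp_frame(site.line, site.offset)
    if site.strand == "T":
        direction = triad[:, 0]
    else:
        a = np.deg2rad(144.0)
        direction = np.cos(a) * triad[:, 0] + np.sin(a) * triad[:, 1]
    return origin + 10.0 * direction


def dye_accessibility(
    model: AssemblyModel,
    site: LabelSite | str,
    probe_radius: float = 5.0,
    n_directions: int = 512,
    seed: int | None = None,
) -> float:
    """Fraction of directions along which a probe sphere of `probe_radius`,
    centered `probe_radius` out from the dye attachment point, clears every
    pseudo-atom and every DNA bp (4 A effective radius).  The labeled bp and
    its +-3 neighbors on the host duplex are not counted as occluders (the
    dye tether spans them by construction).  Directions come from a
    deterministic Fibonacci sphere; `seed` adds random jitter."""
    if isinstance(site, str):
        site = LabelSite.parse(site)
    attach = _attachment_point(model, site)
    dirs = _fibonacci_sphere(n_directions)
    if seed is not None:
        rng = np.random.default_rng(seed)
        dirs = dirs + 0.05 * rng.standard_normal(dirs.shape)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos, rad = model.all_pseudo_atoms()
    host_arms = ("P", "P'") if site.line == "attP" else ("B", "B'")
    dna_parts = []
    for arm, duplex in model.dna.items():
        keep = np.ones(len(duplex), dtype=bool)
        if arm in host_arms:
            keep = np.abs(model.dna_att[arm] - site.offset) > 3
        dna_parts.append(duplex.origins[keep])
    dna_parts.append(model.junction.overlap_bp_origins())
    dna = np.concatenate(dna_parts)
    pos = np.concatenate([pos, dna]) if len(pos) else dna
    rad = np.concatenate([rad, np.full(len(dna), 4.0)])
    centers = attach[None, :] + probe_radius * dirs
    d = np.linalg.norm(centers[:, None, :] - pos[None, :, :], axis=2)
    clear = np.all(d >= (rad[None, :] + probe_radius), axis=1)
    return float(np.mean(clear))


def census(model: AssemblyModel | None) -> dict[str, int]:
    """Exact integer counts of the model's composition and topology."""
    if model is None or not getattr(model, "subunits", None):
        keys = (
            "protein_subunits", "int", "ihf_heterodimers", "xis", "dna_bp",
            "bridges", "arm_sites_occupied", "crossings",
        )
        return {k: 0 for k in keys}
    kinds = [s.kind for s in model.subunits]
    sign, count = model.arm_crossing()
    return {
        "protein_subunits": len(model.subunits),
        "int": kinds.count("Int"),
        "ihf_heterodimers": kinds.count("IHF") // 2,
        "xis": kinds.count("Xis"),
        "dna_bp": model.dna_bp_count(),
        "bridges": len(model.bridges),
        "arm_sites_occupied": len(model.ntd_anchor),
        "crossings": count,
        "crossing_sign": sign,
    }
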