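"""Synthetic pseudo-atom components and noisy half-volumes.

These fixtures stand in for the experimental component structures (an Int
tetramer core on a four-way junction, IHF-bent and Xis-bent duplexes, small
NTD domains) at domain-level granularity, plus Gaussian-noise half-maps for
exercising the FSC validation stack.  Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .assembly import CORE_SUBUNITS, Component, _EXIT_AZIMUTH
from .density import DensityMap, simulate_map
from .geometry import DuplexPath, generate_bdna, _axis_angle_matrix, _rotate_downstream

__all__ = ["FixtureConfig", "make_components", "make_half_maps"]


@dataclass
class FixtureConfig:
    seed: int = 0
    ihf_bend_deg: float = 160.0
    ihf_kink_separation_bp: int = 9
    xis_bend_per_subunit_deg: float = 30.0
    core_arm_length_bp: int = 15
    noise_sigma: float = 0.1
    voxel: float = 2.8
    resolution: float = 11.0

    def validate(self) -> None:
        for name in ("ihf_bend_deg", "xis_bend_per_subunit_deg"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.ihf_kink_separation_bp < 1:
            raise ValueError("kink separation must be at least 1 bp")


def _blob(rng, center, n, spread, radius, chain, res_start) -> dict:
    pos = center + rng.normal(scale=spread, size=(n, 3))
    return {
        "positions": pos,
        "radii": np.full(n, radius),
        "chain_ids": [chain] * n,
        "residue_indices": np.arange(res_start, res_start + n),
    }


def _merge(parts) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
    return (
        np.concatenate([p["positions"] for p in parts]),
        np.concatenate([p["radii"] for p in parts]),
        sum((p["chain_ids"] for p in parts), []),
        np.concatenate([p["residue_indices"] for p in parts]),
    )


def _planar_kinked_duplex(n_bp: int, kink_steps, kink_angles_deg) -> DuplexPath:
    """Straight ideal duplex with coplanar kinks (all about the world y-axis),
    so the end-to-end direction change equals the summed kink angles exactly."""
    path = generate_bdna("A" * n_bp)
    for step, ang in zip(kink_steps, kink_angles_deg):
        if ang == 0.0:
            continue
        g = _axis_angle_matrix(np.array([0.0, 1.0, 0.0]), ang)
        path = _rotate_downstream(path, step, g, path.origins[step])
    return path


def make_components(config: FixtureConfig | None = None) -> dict[str, Component]:
    """Build the component library: Int CTD tetramer core, an Int NTD blob,
    a doubly-kinked IHF duplex, and a triply-bent Xis segment."""
    cfg = config or FixtureConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib: dict[str, Component] = {}

    # --- Int CTD tetramer: one catalytic/CB-domain cloud per core half-site,
    # arranged around the junction center below the junction plane.
    parts = []
    for name, az in _EXIT_AZIMUTH.items():
        a = np.deg2rad(az)
        center = np.array([24.0 * np.cos(a), 24.0 * np.sin(a), -14.0])
        parts.append(_blob(rng, center, 14, 6.0, 3.5, name, 75))
    pos, rad, chains, resi = _merge(parts)
    lib["IntCTD_tetramer_core"] = Component(
        "IntCTD_tetramer_core", pos, rad, chains, resi,
        anchors={"junction_center": np.zeros(3)},
        meta={"subunits": list(CORE_SUBUNITS)},
    )

    # --- Int NTD: a small arm-site binding domain (residues 1-55).
    b = _blob(rng, np.zeros(3), 8, 4.0, 3.0, "NTD", 1)
    lib["IntNTD"] = Component(
        "IntNTD", b["positions"], b["radii"], b["chain_ids"], b["residue_indices"],
        anchors={"dna": np.zeros(3), "linker": b["positions"].mean(axis=0)},
    )

    # --- IHF-bent duplex: two kinks, `ihf_kink_separation_bp` apart, splitting
    # the configured total bend; heterodimer cloud at the bend vertex.
    n_bp = 21
    k1 = (n_bp - cfg.ihf_kink_separation_bp) // 2
    k2 = k1 + cfg.ihf_kink_separation_bp
    half = cfg.ihf_bend_deg / 2.0
    duplex = _planar_kinked_duplex(n_bp, (k1, k2), (half, half))
    vertex = 0.5 * (duplex.origins[k1] + duplex.origins[k2])
    parts = [
        _blob(rng, vertex + np.array([4.0, 0.0, 2.0]), 10, 4.5, 3.2, "alpha", 1),
        _blob(rng, vertex + np.array([-4.0, 0.0, 2.0]), 10, 4.5, 3.2, "beta", 1),
    ]
    pos, rad, chains, resi = _merge(parts)
    lib["IHF_duplex"] = Component(
        "IHF_duplex", pos, rad, chains, resi,
        anchors={"vertex": vertex},
        duplex=duplex, kink_steps=(k1, k2),
        meta={"total_bend_deg": cfg.ihf_bend_deg},
    )

    # --- Xis segment: three tandem bend units on a duplex; per-subunit bend 0
    # leaves it straight.
    n_bp = 33
    steps = (8, 16, 24)
    duplex = _planar_kinked_duplex(
        n_bp, steps, (cfg.xis_bend_per_subunit_deg,) * 3
    )
    b = _blob(rng, duplex.origins[16] + np.array([5.0, 0.0, 0.0]), 7, 3.5, 3.0,
              "subunit", 1)
    lib["Xis_segment"] = Component(
        "Xis_segment", b["positions"], b["radii"], b["chain_ids"],
        b["residue_indices"],
        duplex=duplex, kink_steps=steps,
        meta={"bend_per_subunit_deg": cfg.xis_bend_per_subunit_deg},
    )
    return lib


def make_half_maps(
    model, config: FixtureConfig | None = None
) -> tuple[DensityMap, DensityMap]:
    """Two independent noisy reconstructions of the same model: the simulated
    map plus white Gaussian voxel noise with per-half seeds derived from the
    config seed.  (Real reconstruction noise is colored; white noise is enough
    to exercise the FSC mechanics.)"""
    cfg = config or FixtureConfig()
    clean = simulate_map(model, voxel=cfg.voxel, resolution=cfg.resolution)
    scale = float(np.abs(clean.data).max())
    halves = []
    for k in (1, 2):
        rng = np.random.default_rng((cfg.seed, k))
        noisy = clean.data + cfg.noise_sigma * scale * rng.standard_normal(clean.shape)
        halves.append(clean.like(noisy))
    return halves[0], halves[1]
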