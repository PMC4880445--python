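"""Base-pair-frame DNA geometry: ideal B-DNA, splicing, bending, kinks.

The universal DNA representation is :class:`DuplexPath`, an ordered list of
base-pair frames (origin + right-handed orthonormal triad, one frame per bp).
The helical step convention is a symmetric mid-step one:

* frame z-axis (triad column 2) is the local helical axis,
* one step applies ``Rz(twist/2) . Ry(roll) . Rz(twist/2)`` to the triad,
* the origin advances by ``rise`` along the mid-step axis
  ``Rz(twist/2) . Ry(roll/2) . z``.

With zero roll the helical axis is exactly straight regardless of twist, and a
run of N equal rolls at zero twist traces a planar circular arc with total
direction change N*roll.  Only twist/roll/rise are modeled; tilt, slide and
shift are zero at this coarse grain (kinks introduced by proteins are applied
as explicit frame rotations, not as step parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "IDEAL_TWIST_DEG",
    "IDEAL_RISE",
    "BasePairFrame",
    "DuplexPath",
    "RigidTransform",
    "generate_bdna",
    "superpose",
    "splice",
    "bend_roll",
    "kink_rotate",
]

#: Canonical ideal B-DNA helical parameters (per step).
IDEAL_TWIST_DEG = 36.0
IDEAL_RISE = 3.38

_VALID_BASES = set("ACGT")


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be nonzero")
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()


@dataclass
class BasePairFrame:
    """One base pair: origin (A), right-handed orthonormal triad, index, base."""

    origin: np.ndarray
    triad: np.ndarray
    bp_index: int
    base: str = "N"

    def validate(self, tol: float = 1e-8) -> None:
        t = np.asarray(self.triad)
        if not np.allclose(t.T @ t, np.eye(3), atol=tol):
            raise ValueError(f"triad of bp {self.bp_index} is not orthonormal")
        if np.linalg.det(t) < 0:
            raise ValueError(f"triad of bp {self.bp_index} is not proper (det<0)")


@dataclass
class RigidTransform:
    """Proper rotation + translation; acts as ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


class DuplexPath:
    """An ordered run of base-pair frames with helical-parameter accessors.

    Frames are stored as an (N, 3) origin array and an (N, 3, 3) triad array
    (triad columns = x, y, z unit vectors of the bp frame; z is the helical
    axis).  ``bp_index`` increments by one along the path.
    """

    def __init__(
        self,
        origins: np.ndarray,
        triads: np.ndarray,
        sequence: str | None = None,
        start_index: int = 0,
    ):
        self.origins = np.atleast_2d(np.asarray(origins, dtype=float)).copy()
        self.triads = np.asarray(triads, dtype=float).reshape(-1, 3, 3).copy()
        n = len(self.origins)
        if len(self.triads) != n:
            raise ValueError("origins and triads disagree in length")
        self.sequence = (sequence or "N" * n).upper()
        if len(self.sequence) != n:
            raise ValueError("sequence length does not match frame count")
        self.start_index = int(start_index)

    def __len__(self) -> int:
        return len(self.origins)

    @property
    def bp_indices(self) -> np.ndarray:
        return np.arange(self.start_index, self.start_index + len(self))

    def frame(self, i: int) -> BasePairFrame:
        return BasePairFrame(
            self.origins[i], self.triads[i], int(self.bp_indices[i]), self.sequence[i]
        )

    def copy(self) -> "DuplexPath":
        return DuplexPath(self.origins, self.triads, self.sequence, self.start_index)

    def validate(self, tol: float = 1e-8) -> None:
        for i in range(len(self)):
            self.frame(i).validate(tol)
        if len(self) > 1 and not np.all(self.step_rise() > 0):
            raise ValueError("non-positive rise step in duplex path")

    # -- helical parameter accessors -------------------------------------

    def step_rise(self) -> np.ndarray:
        """Per-step rise, the origin-to-origin distance (A)."""
        return np.linalg.norm(np.diff(self.origins, axis=0), axis=1)

    def _step_twist_roll(self) -> tuple[np.ndarray, np.ndarray]:
        """Decompose each step rotation as Rz(t/2) Ry(r) Rz(t/2).

        The (twist, roll) pair is ambiguous up to (t+360, ...) and the branch
        (t+180, -r); the branch with twist nearest the ideal B-DNA value is
        returned, which is unique for |roll| < 90 deg.
        """
        n = len(self) - 1
        tw = np.empty(n)
        ro = np.empty(n)
        for i in range(n):
            s = self.triads[i].T @ self.triads[i + 1]
            cb = np.clip(s[2, 2], -1.0, 1.0)
            sb = float(np.hypot(s[0, 2], s[1, 2]))
            if sb < 1e-12:
                ro[i] = 0.0 if cb > 0 else 180.0
                tw[i] = np.rad2deg(np.arctan2(s[1, 0], s[0, 0])) / 2.0 * 2.0
                # pure Rz(2a): full twist angle
                tw[i] = np.rad2deg(np.arctan2(s[1, 0], s[0, 0]))
            else:
                a = np.rad2deg(np.arctan2(s[1, 2], s[0, 2]))  # twist/2, roll>0 branch
                b = np.rad2deg(np.arctan2(sb, cb))
                cand = [(2 * a, b), (2 * a + 360.0, b), (2 * a - 360.0, b),
                        (2 * (a + 180.0), -b), (2 * (a - 180.0), -b)]
                tw[i], ro[i] = min(
                    cand, key=lambda p: abs(_wrap_deg(p[0]) - IDEAL_TWIST_DEG)
                )
                tw[i] = _wrap_deg(tw[i])
        return tw, ro

    def step_twist(self) -> np.ndarray:
        return self._step_twist_roll()[0]

    def step_roll(self) -> np.ndarray:
        return self._step_twist_roll()[1]

    def transformed(self, t: RigidTransform) -> "DuplexPath":
        return DuplexPath(
            t.apply(self.origins),
            np.einsum("ij,njk->nik", t.rotation, self.triads),
            self.sequence,
            self.start_index,
        )


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _step_transform(twist_deg: float, roll_deg: float, rise: float):
    """(rotation, displacement) of one helical step in the upstream frame."""
    half = _rot_z(twist_deg / 2.0)
    rot = half @ _rot_y(roll_deg) @ half
    disp = half @ _rot_y(roll_deg / 2.0) @ np.array([0.0, 0.0, rise])
    return rot, disp


def generate_bdna(
    sequence: str,
    twist_deg: float = IDEAL_TWIST_DEG,
    rise: float = IDEAL_RISE,
) -> DuplexPath:
    """Build a straight ideal B-DNA path, frame 0 at the origin (identity triad)."""
    sequence = str(sequence).upper()
    if not sequence:
        raise ValueError("sequence must be nonempty")
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    n = len(sequence)
    origins = np.zeros((n, 3))
    origins[:, 2] = rise * np.arange(n)
    triads = np.empty((n, 3, 3))
    step = _rot_z(twist_deg)
    triads[0] = np.eye(3)
    for i in range(1, n):
        triads[i] = triads[i - 1] @ step
    return DuplexPath(origins, triads, sequence)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of `mobile` onto `reference` (Kabsch).

    Returns the rigid transform T minimizing ||T(mobile) - reference|| and the
    residual RMSD.  Reflections are never returned.
    """
    mob = np.atleast_2d(np.asarray(mobile, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if mob.shape != ref.shape:
        raise ValueError("point sets must have equal cardinality")
    if len(mob) < 3:
        raise ValueError("need at least 3 points to superpose")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    dm, dr = mob - cm, ref - cr
    if np.linalg.matrix_rank(dm.T @ dm, tol=1e-9) < 2 or np.linalg.matrix_rank(
        dr.T @ dr, tol=1e-9
    ) < 2:
        raise ValueError("degenerate (collinear) point set; superposition ill-posed")
    rot, rssd = Rotation.align_vectors(dr, dm)
    r = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(len(mob))
    return RigidTransform(r, cr - r @ cm), rmsd


def _frame_markers(origins: np.ndarray, triads: np.ndarray) -> np.ndarray:
    """Represent frames as point sets (origin + x/y axis tips) for superposition."""
    pts = [origins, origins + triads[:, :, 0], origins + triads[:, :, 1]]
    return np.concatenate(pts, axis=0)


def splice(
    upstream: DuplexPath,
    downstream: DuplexPath,
    splint_len: int = 4,
    twist_deg: float = IDEAL_TWIST_DEG,
    rise: float = IDEAL_RISE,
) -> DuplexPath:
    """Join two duplexes via an ideal B-DNA splint, preserving twist continuity.

    An ideal splint of 2*splint_len bp is superposed, by its first half, onto
    the last `splint_len` bp of `upstream`; `downstream` is then rigidly moved
    so its first `splint_len` bp superpose onto the splint's second half.  The
    upstream path never moves and the result has length len(up) + len(down).
    """
    if splint_len < 2:
        raise ValueError("splint_len must be >= 2")
    if len(upstream) < splint_len or len(downstream) < splint_len:
        raise ValueError("both paths must be at least splint_len bp long")
    splint = generate_bdna("A" * (2 * splint_len), twist_deg, rise)
    t_splint, _ = superpose(
        _frame_markers(splint.origins[:splint_len], splint.triads[:splint_len]),
        _frame_markers(upstream.origins[-splint_len:], upstream.triads[-splint_len:]),
    )
    placed = splint.transformed(t_splint)
    t_down, _ = superpose(
        _frame_markers(downstream.origins[:splint_len], downstream.triads[:splint_len]),
        _frame_markers(placed.origins[splint_len:], placed.triads[splint_len:]),
    )
    moved = downstream.transformed(t_down)
    return DuplexPath(
        np.concatenate([upstream.origins, moved.origins]),
        np.concatenate([upstream.triads, moved.triads]),
        upstream.sequence + moved.sequence,
        upstream.start_index,
    )


def _rotate_downstream(
    path: DuplexPath,
    first_moving: int,
    rotation: np.ndarray,
    pivot: np.ndarray,
    new_first_origin: np.ndarray | None = None,
) -> DuplexPath:
    """Rigidly move frames >= first_moving: rotate about `pivot`, optionally
    re-anchoring the first moving origin at an explicit position."""
    out = path.copy()
    sl = slice(first_moving, None)
    if new_first_origin is None:
        out.origins[sl] = (out.origins[sl] - pivot) @ rotation.T + pivot
    else:
        rel = out.origins[sl] - out.origins[first_moving]
        out.origins[sl] = new_first_origin + rel @ rotation.T
    out.triads[sl] = np.einsum("ij,njk->nik", rotation, out.triads[sl])
    return out


def bend_roll(duplex: DuplexPath, step_index: int, roll_deg: float) -> DuplexPath:
    """Add `roll_deg` of roll at step `step_index` (between bp step_index-1 and
    step_index); everything downstream follows rigidly, all other step
    parameters are untouched."""
    n = len(duplex)
    if not (0 < step_index < n):
        raise IndexError(f"step_index {step_index} out of range (0, {n})")
    if roll_deg == 0.0:
        return duplex.copy()
    i = step_index
    r_prev = duplex.triads[i - 1]
    s = r_prev.T @ duplex.triads[i]
    # current step parameters in the mid-step convention
    path_tmp = DuplexPath(duplex.origins[i - 1 : i + 1], duplex.triads[i - 1 : i + 1])
    tw = float(path_tmp.step_twist()[0])
    ro = float(path_tmp.step_roll()[0])
    h = float(np.linalg.norm(duplex.origins[i] - duplex.origins[i - 1]))
    w = r_prev @ _rot_z(tw / 2.0)
    g = w @ _rot_y(roll_deg) @ w.T
    new_origin = duplex.origins[i - 1] + w @ _rot_y((ro + roll_deg) / 2.0) @ np.array(
        [0.0, 0.0, h]
    )
    return _rotate_downstream(duplex, i, g, duplex.origins[i], new_origin)


def _kink_axis(duplex: DuplexPath, kink: int) -> np.ndarray:
    """Bend axis of the step arriving at bp `kink` (rotation axis of the step
    rotation, orthogonalized against pure twist); falls back to the local
    y-axis for an unbent step."""
    s = duplex.triads[kink - 1].T @ duplex.triads[kink]
    rotvec = Rotation.from_matrix(s).as_rotvec()
    # remove the twist (local z) component to get the bending direction
    bend = rotvec - np.array([0.0, 0.0, rotvec[2]])
    if np.linalg.norm(bend) < 1e-9:
        bend = np.array([0.0, 1.0, 0.0])
    axis_local = bend / np.linalg.norm(bend)
    return duplex.triads[kink - 1] @ axis_local


def kink_rotate(
    duplex: DuplexPath,
    kink_a: int,
    kink_b: int,
    mode: str,
    angle_deg: float,
    warn_limit: float = 10.0,
) -> DuplexPath:
    """Adjust a doubly-kinked (protein-bent) duplex about its existing kinks.

    ``in_plane`` rotates the arm beyond `kink_b` about the bend axis of the
    kink at `kink_b` (through its origin): both kink origins stay fixed and
    the existing bend is deepened/shallowed.  ``torsion`` rotates the arm from
    `kink_b` on about the axis connecting the two kink origins, preserving
    every frame's distance to that axis.
    """
    n = len(duplex)
    if not (0 <= kink_a < kink_b < n):
        raise IndexError("kink indices out of range or not ordered")
    if kink_a == kink_b:
        raise ValueError("kink positions must differ")
    if abs(angle_deg) >= warn_limit:
        import warnings

        warnings.warn(
            f"kink adjustment of {angle_deg:g} deg exceeds the typical "
            f"<{warn_limit:g} deg range of protein-bent DNA deformations",
            stacklevel=2,
        )
    if angle_deg == 0.0:
        return duplex.copy()
    if mode == "in_plane":
        if kink_b == 0:
            raise IndexError("kink_b must have an upstream step")
        axis = _kink_axis(duplex, kink_b)
        pivot = duplex.origins[kink_b]
        g = _axis_angle_matrix(axis, angle_deg)
        return _rotate_downstream(duplex, kink_b, g, pivot)
    if mode == "torsion":
        axis = duplex.origins[kink_b] - duplex.origins[kink_a]
        if np.linalg.norm(axis) < 1e-9:
            raise ValueError("kink origins coincide; torsion axis undefined")
        g = _axis_angle_matrix(axis, angle_deg)
        return _rotate_downstream(duplex, kink_b, g, duplex.origins[kink_b])
    raise ValueError(f"unknown mode {mode!r}; expected 'in_plane' or 'torsion'")
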