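"""Idealized spectrin-repeat structures.

A spectrin repeat is a ~106-residue antiparallel three-helix bundle
(helices A, B, C in an up-down-up topology) roughly 4.5 nm long and
2.5 nm wide, delimited by two conserved leucine anchors whose Cα–Cα
axis defines the repeat's long axis.  This module builds coarse
backbone-only (N, CA, C) models of such repeats and of multi-repeat
chains joined by 5-residue linkers, so that every downstream stage of
the pipeline can run on synthetic structures.

Internally all coordinates are in Å (PDB convention); user-facing
summary lengths are reported in nm elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HELIX_CA_RADIUS = 2.3  # Å, Cα helical radius of an ideal alpha helix
HELIX_TWIST = 100.0  # degrees per residue
PAIR_GAP = 4.5  # Å, half-separation of the A/C helix pair
DEFAULT_LINKER_SEQ = "EQKDW"  # five bulky residues, leucine-flanked by anchors


@dataclass
class RepeatStructure:
    """Backbone model of one (possibly linker-bearing) spectrin repeat.

    ``coords`` holds (n_res, 3, 3) backbone coordinates ordered
    (N, CA, C) per residue; ``res_ids`` are 1-based, strictly
    increasing.  ``anchor_n``/``anchor_c`` are the residue ids of the
    two leucine anchors delimiting the folded bundle, and
    ``linker_range`` the inclusive id interval of a trailing 5-residue
    linker (``None`` when the repeat carries no linker).
    """

    repeat_id: str
    res_ids: np.ndarray
    sequence: str
    coords: np.ndarray
    anchor_n: int
    anchor_c: int
    linker_range: tuple[int, int] | None = None
    chain_label: str = "A"

    def __post_init__(self) -> None:
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.res_ids), 3, 3):
            raise ValueError("coords must be (n_res, 3, 3) matching res_ids")
        if len(self.sequence) != len(self.res_ids):
            raise ValueError("sequence length must match residue count")

    # -- accessors ---------------------------------------------------------
    @property
    def n_res(self) -> int:
        return len(self.res_ids)

    @property
    def ca(self) -> np.ndarray:
        """(n_res, 3) Cα coordinates."""
        return self.coords[:, 1, :]

    def _index_of(self, res_id: int) -> int:
        idx = np.searchsorted(self.res_ids, res_id)
        if idx >= len(self.res_ids) or self.res_ids[idx] != res_id:
            raise KeyError(f"residue {res_id} not present in repeat {self.repeat_id}")
        return int(idx)

    def ca_of(self, res_id: int) -> np.ndarray:
        return self.ca[self._index_of(res_id)]

    @property
    def anchor_coords(self) -> tuple[np.ndarray, np.ndarray]:
        return self.ca_of(self.anchor_n), self.ca_of(self.anchor_c)

    @property
    def anchor_axis(self) -> np.ndarray:
        """Unit vector from the N-side to the C-side leucine anchor."""
        a, b = self.anchor_coords
        v = b - a
        return v / np.linalg.norm(v)

    @property
    def anchor_midpoint(self) -> np.ndarray:
        a, b = self.anchor_coords
        return 0.5 * (a + b)

    @property
    def bundle_mask(self) -> np.ndarray:
        """Boolean mask selecting the folded bundle (non-linker) residues."""
        if self.linker_range is None:
            return np.ones(self.n_res, dtype=bool)
        lo, hi = self.linker_range
        return ~((self.res_ids >= lo) & (self.res_ids <= hi))

    def transformed(self, transform) -> "RepeatStructure":
        """Copy of this repeat with a rigid transform applied."""
        new_coords = transform.apply(self.coords.reshape(-1, 3)).reshape(self.coords.shape)
        return replace(self, coords=new_coords)

    def renumbered(self, offset: int) -> "RepeatStructure":
        linker = None
        if self.linker_range is not None:
            linker = (self.linker_range[0] + offset, self.linker_range[1] + offset)
        return replace(
            self,
            res_ids=self.res_ids + offset,
            anchor_n=self.anchor_n + offset,
            anchor_c=self.anchor_c + offset,
            linker_range=linker,
        )

    # -- validation --------------------------------------------------------
    def validate(self, ideal: bool = False) -> None:
        """Raise ``ValueError`` on violated structural invariants."""
        if self.anchor_n >= self.anchor_c:
            raise ValueError("anchor_n must precede anchor_c")
        if not np.all(np.diff(self.res_ids) > 0):
            raise ValueError("residue ids must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all coordinates must be finite")
        if self.linker_range is not None:
            lo, hi = self.linker_range
            if hi - lo + 1 != 5:
                raise ValueError("linker_range must span 0 or 5 residues")
        if ideal:
            a, b = self.anchor_coords
            sep = np.linalg.norm(b - a)
            if not 40.0 <= sep <= 50.0:
                raise ValueError(
                    f"anchor separation {sep:.1f} Å outside [40, 50] Å"
                )


def _helix_backbone(axis_xy: np.ndarray, z_points: np.ndarray, phases: np.ndarray,
                    ascending: bool) -> np.ndarray:
    """Backbone atoms for one straight helix parallel to z.

    Cα sit on a cylinder of radius ``HELIX_CA_RADIUS`` about
    ``axis_xy``; N and C are placed on the same helical path slightly
    behind/ahead of each Cα (schematic backbone, adequate for a
    Cα-resolution model).
    """
    n = len(z_points)
    out = np.empty((n, 3, 3))
    rise = (z_points[-1] - z_points[0]) / max(n - 1, 1)
    for j, (z, ph) in enumerate(zip(z_points, phases)):
        for k, (dphase, dz, radius) in enumerate(
            ((-38.0, -0.55, 1.6), (0.0, 0.0, HELIX_CA_RADIUS), (33.0, 0.45, 1.7))
        ):
            ang = np.deg2rad(ph + dphase)
            out[j, k, 0] = axis_xy[0] + radius * np.cos(ang)
            out[j, k, 1] = axis_xy[1] + radius * np.sin(ang)
            out[j, k, 2] = z + dz * np.sign(rise if rise != 0 else 1.0)
    return out


def make_ideal_repeat(n_res: int = 106, length: float = 45.0, diameter: float = 25.0,
                      seed: int = 0, jitter_sd: float = 0.05,
                      repeat_id: str = "R1") -> RepeatStructure:
    """Build one idealized three-helix-bundle repeat.

    Parameters
    ----------
    n_res:
        Number of residues (>= 9); split into helices A, B, C.
    length:
        Cα–Cα distance between the two leucine anchors, Å.
    diameter:
        Maximal cross-sectional Cα–Cα extent perpendicular to the
        bundle axis, Å.
    seed:
        Seed for the small coordinate jitter that keeps distinct seeds
        distinguishable; a fixed seed is fully deterministic.
    """
    if n_res < 9:
        raise ValueError(f"n_res must be >= 9, got {n_res}")
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    lateral = 2 * PAIR_GAP  # x-offset between the A and C helix axes
    if length <= lateral:
        raise ValueError("length too small relative to the A/C helix separation")
    height = np.sqrt(length**2 - lateral**2)
    # B-helix axis height above the A/C pair, set so that the widest
    # Cα–Cα extent (B to A or C) equals `diameter`.
    reach = diameter - 2 * HELIX_CA_RADIUS
    if reach <= PAIR_GAP:
        raise ValueError("diameter too small for a three-helix bundle")
    b_height = np.sqrt(reach**2 - PAIR_GAP**2)

    n_a = n_res // 3
    n_b = n_res // 3
    n_c = n_res - n_a - n_b
    centers = {
        "A": np.array([-PAIR_GAP, 0.0]),
        "B": np.array([0.0, b_height]),
        "C": np.array([PAIR_GAP, 0.0]),
    }
    # Anchor residues (first of A, last of C) are phased to point in -y,
    # putting both anchors on the line y = -HELIX_CA_RADIUS.
    phases_a = -90.0 + HELIX_TWIST * np.arange(n_a)
    phases_b = HELIX_TWIST * np.arange(n_b)
    phases_c = -90.0 - HELIX_TWIST * (n_c - 1 - np.arange(n_c))
    z_a = np.linspace(0.0, height, n_a)
    z_b = np.linspace(height, 0.0, n_b)
    z_c = np.linspace(0.0, height, n_c)

    coords = np.concatenate([
        _helix_backbone(centers["A"], z_a, phases_a, True),
        _helix_backbone(centers["B"], z_b, phases_b, False),
        _helix_backbone(centers["C"], z_c, phases_c, True),
    ])
    rng = np.random.default_rng(seed)
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)

    sequence = "L" + "A" * (n_res - 2) + "L"
    return RepeatStructure(
        repeat_id=repeat_id,
        res_ids=np.arange(1, n_res + 1),
        sequence=sequence,
        coords=coords,
        anchor_n=1,
        anchor_c=n_res,
        linker_range=None,
    )


def _linker_coords(start: np.ndarray, end: np.ndarray, n: int) -> np.ndarray:
    """Schematic 5-residue connector between two anchor Cα positions.

    Residues are spaced evenly along the start→end segment with a small
    helical wobble; this is a coarse connector (stereochemically exact
    linkers are rebuilt with ideal internal coordinates where dihedral
    detail matters, see :mod:`fingertrap.refine`).
    """
    seg = end - start
    length = np.linalg.norm(seg)
    u = seg / length
    # any perpendicular pair
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    p /= np.linalg.norm(p)
    q = np.cross(u, p)
    fracs = (np.arange(1, n + 1)) / (n + 1)
    out = np.empty((n, 3, 3))
    for j, f in enumerate(fracs):
        ang = 2.0 * np.pi * j / max(n, 1)
        ca = start + f * seg + 1.0 * (np.cos(ang) * p + np.sin(ang) * q)
        out[j, 1] = ca
        out[j, 0] = ca - 0.45 * length / (n + 1) * u + 0.4 * p
        out[j, 2] = ca + 0.40 * length / (n + 1) * u - 0.4 * p
    return out


def make_chain(repeat: RepeatStructure, n_repeats: int, linker_len: int = 5,
               rise_per_repeat: float = 50.0,
               linker_seq: str = DEFAULT_LINKER_SEQ) -> list[RepeatStructure]:
    """Stack ``n_repeats`` copies of a repeat into a straight chain.

    Copies are translated along the bundle axis (z) by
    ``rise_per_repeat`` (~5 nm per repeat including one linker region)
    and joined by ``linker_len``-residue connectors; residues are
    globally renumbered.
    """
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    if linker_len != len(linker_seq):
        linker_seq = (linker_seq * linker_len)[:linker_len]
    base = repeat
    n_rep_res = base.n_res
    block = n_rep_res + linker_len
    out: list[RepeatStructure] = []
    rise_vec = np.array([0.0, 0.0, rise_per_repeat])
    for k in range(n_repeats):
        offset = k * block
        coords = base.coords + k * rise_vec
        res_ids = np.arange(1, n_rep_res + 1) + offset
        seq = base.sequence
        linker_range = None
        if k < n_repeats - 1 and linker_len > 0:
            start_ca = coords[base._index_of(base.anchor_c), 1]
            next_start = base.coords[base._index_of(base.anchor_n), 1] + (k + 1) * rise_vec
            lk = _linker_coords(start_ca, next_start, linker_len)
            coords = np.concatenate([coords, lk])
            res_ids = np.concatenate(
                [res_ids, np.arange(n_rep_res + 1, n_rep_res + linker_len + 1) + offset]
            )
            seq = seq + linker_seq
            linker_range = (offset + n_rep_res + 1, offset + n_rep_res + linker_len)
        out.append(
            RepeatStructure(
                repeat_id=f"{base.repeat_id}.{k + 1}",
                res_ids=res_ids,
                sequence=seq,
                coords=coords,
                anchor_n=base.anchor_n + offset,
                anchor_c=base.anchor_c + offset,
                linker_range=linker_range,
                chain_label=base.chain_label,
            )
        )
    return out


def chain_rise(chain: list[RepeatStructure]) -> float:
    """End-to-end extent of a chain along its first principal axis, Å."""
    from .geometry import principal_axis

    ca = np.concatenate([r.ca for r in chain])
    axis = principal_axis(ca)
    proj = ca @ axis
    return float(proj.max() - proj.min())
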