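"""The Chinese Finger Trap construction.

The compact spectrin heterotetramer is modelled as a two-start,
right-handed supercoil of rigid spectrin repeats, four repeats per
turn, arranged as a discontinuous *square* of linear segments: each
repeat is a chord tangent to a circle of radius r, successive repeats
are rotated 90° about the supercoil axis and raised by a quarter pitch.
The geometry is closed by three relations tying the molecular length L
(nm), the per-turn pitch P, the supercoil radius r and the invariant
per-turn contour length C_L (experimentally 19.9 nm, the length of
four repeats):

    P   = 4 L / 37            (37 repeats per strand)
    C_L² = P² + (8 r)²        (square-perimeter contour)
    r   = sqrt(C_L² - P²) / 8

Extension is therefore a pure pitch increase at fixed contour length:
as L grows, r shrinks, reaching r = 0 (a straight filament) at
L = 37 C_L / 4 ≈ 184 nm.  No energy terms enter; the construction is
purely geometric and models are screened only for steric clashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .assembly import StrandModel
from .geometry import RigidTransform, angle_between, principal_axis
from .repeats import RepeatStructure

logger = logging.getLogger(__name__)

#: Roll value (degrees) at which the bundle's B helix faces directly away
#: from the supercoil axis.  This constant anchors the package's roll scale
#: to the reported steric-window convention; the absolute sign of "roll"
#: carries no physical meaning beyond this choice.
ROLL_REFERENCE = -30.0

DEFAULT_CONTOUR_LENGTH = 19.9  # nm, per-turn contour length (four repeats)
DEFAULT_N_REPEATS = 37
DEFAULT_REPEATS_PER_TURN = 4
DEFAULT_ROLL = -30.0
CLASH_THRESHOLD = 4.0  # Å, Cα-Cα exclusion distance
JOINT_EXEMPT_SEPARATION = 12  # through-linker residue separation exempt from clashes


@dataclass(frozen=True)
class SupercoilParams:
    """Geometric state of the supercoil; lengths in nm."""

    total_length: float
    contour_length: float = DEFAULT_CONTOUR_LENGTH
    n_repeats_per_strand: int = DEFAULT_N_REPEATS
    repeats_per_turn: int = DEFAULT_REPEATS_PER_TURN
    roll: float = DEFAULT_ROLL
    handedness: str = "right"
    pitch: float = field(init=False)
    radius: float = field(init=False)

    def __post_init__(self) -> None:
        if self.handedness not in ("right", "left"):
            raise ValueError(f"handedness must be 'right' or 'left', got {self.handedness!r}")
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        max_length = self.n_repeats_per_strand * self.contour_length / self.repeats_per_turn
        pitch = self.repeats_per_turn * self.total_length / self.n_repeats_per_strand
        if pitch > self.contour_length + 1e-12:
            raise ValueError(
                f"over-extended: total_length {self.total_length} nm exceeds the "
                f"full extension {max_length:.3f} nm (pitch would exceed the "
                f"contour length)"
            )
        radius = np.sqrt(max(self.contour_length**2 - pitch**2, 0.0)) / 8.0
        object.__setattr__(self, "pitch", float(pitch))
        object.__setattr__(self, "radius", float(radius))

    @property
    def rise_per_repeat(self) -> float:
        return self.pitch / self.repeats_per_turn

    @property
    def segment_length(self) -> float:
        """Contour length of one repeat's segment, C_L / repeats_per_turn (nm)."""
        return self.contour_length / self.repeats_per_turn

    @property
    def bend_angle(self) -> float:
        """Ideal bend between consecutive repeat segments, degrees."""
        cos_bend = (self.rise_per_repeat / self.segment_length) ** 2
        return float(np.degrees(np.arccos(np.clip(cos_bend, -1.0, 1.0))))

    def check(self) -> None:
        resid = self.contour_length**2 - self.pitch**2 - (8 * self.radius) ** 2
        if abs(resid) > 1e-9 * self.contour_length**2:
            raise AssertionError("contour closure violated")


def compute_params(total_length: float,
                   contour_length: float = DEFAULT_CONTOUR_LENGTH,
                   n_repeats: int = DEFAULT_N_REPEATS,
                   repeats_per_turn: int = DEFAULT_REPEATS_PER_TURN,
                   roll: float = DEFAULT_ROLL,
                   handedness: str = "right") -> SupercoilParams:
    """Supercoil parameters for a molecule of ``total_length`` nm."""
    return SupercoilParams(
        total_length=total_length,
        contour_length=contour_length,
        n_repeats_per_strand=n_repeats,
        repeats_per_turn=repeats_per_turn,
        roll=roll,
        handedness=handedness,
    )


def full_extension_length(contour_length: float = DEFAULT_CONTOUR_LENGTH,
                          n_repeats: int = DEFAULT_N_REPEATS,
                          repeats_per_turn: int = DEFAULT_REPEATS_PER_TURN) -> float:
    """Molecular length (nm) at which the supercoil radius reaches zero."""
    return n_repeats * contour_length / repeats_per_turn


def min_compact_length(stacked_repeats: int = 20, repeat_width: float = 2.5) -> float:
    """Lower bound (nm) for the compact molecular length.

    With ``stacked_repeats`` repeats stacked along the molecule's length
    and each repeat ``repeat_width`` nm wide, sequential coils in
    contact cannot compress below their summed widths.
    """
    if stacked_repeats < 0 or repeat_width <= 0:
        raise ValueError("stacked_repeats must be >= 0 and repeat_width > 0")
    return stacked_repeats * repeat_width


def _placement_transform(repeat: RepeatStructure, params: SupercoilParams,
                         k: int) -> RigidTransform:
    """Rigid transform placing repeat ``k`` of strand A."""
    sign = 1.0 if params.handedness == "right" else -1.0
    pitch = params.pitch * 10.0  # Å
    radius = params.radius * 10.0
    rise = pitch / params.repeats_per_turn

    # Local frame: x along the anchor axis, y the seam normal (towards
    # the B helix), z completing a right-handed set.
    x_l = repeat.anchor_axis
    centroid = repeat.ca[repeat.bundle_mask].mean(axis=0)
    v = centroid - repeat.anchor_midpoint
    y_l = v - np.dot(v, x_l) * x_l
    y_l /= np.linalg.norm(y_l)
    z_l = np.cross(x_l, y_l)

    # Target frame at azimuth 0: segment direction u (tangential + rise),
    # outward radial o, and their cross product.
    u = np.array([0.0, sign * 2.0 * radius, rise])
    norm_u = np.linalg.norm(u)
    if norm_u == 0.0:
        u = np.array([0.0, sign, 0.0])
    else:
        u = u / norm_u
    o = np.array([1.0, 0.0, 0.0])  # exactly perpendicular to u
    rot0 = np.column_stack([u, o, np.cross(u, o)]) @ np.column_stack([x_l, y_l, z_l]).T
    # Roll about the repeat's own (placed) axis, measured from the
    # B-outward reference orientation.
    roll_rot = RigidTransform.about_axis(u, params.roll - ROLL_REFERENCE).rotation
    rot = roll_rot @ rot0
    base = RigidTransform(rot, np.array([radius, 0.0, 0.0]) - rot @ repeat.anchor_midpoint)

    step = RigidTransform.about_axis([0.0, 0.0, 1.0], sign * 90.0 * k)
    lift = RigidTransform(np.eye(3), np.array([0.0, 0.0, rise * k]))
    return lift.compose(step).compose(base)


def place_repeat(repeat: RepeatStructure, params: SupercoilParams,
                 k: int) -> tuple[RepeatStructure, RigidTransform]:
    """Place repeat ``k`` (0-based) of strand A on the supercoil."""
    if not 0 <= k < params.n_repeats_per_strand:
        raise ValueError(f"repeat index {k} outside [0, {params.n_repeats_per_strand})")
    tf = _placement_transform(repeat, params, k)
    return repeat.transformed(tf), tf


@dataclass
class TetramerModel:
    """Two placed antiparallel strands plus per-repeat placements."""

    params: SupercoilParams
    strand_a: StrandModel
    strand_b: StrandModel

    @property
    def strands(self) -> tuple[StrandModel, StrandModel]:
        return self.strand_a, self.strand_b

    @property
    def n_repeats(self) -> int:
        return self.strand_a.n_repeats + self.strand_b.n_repeats

    @property
    def ca(self) -> np.ndarray:
        return np.concatenate([self.strand_a.ca, self.strand_b.ca])

    @property
    def symmetry_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(point, direction) of the model's 2-fold axis."""
        n = self.params.n_repeats_per_strand
        rise = self.params.pitch * 10.0 / self.params.repeats_per_turn
        h = ((n - 1) * rise + 2.0 * rise) / 2.0
        return np.array([0.0, 0.0, h]), np.array([1.0, 0.0, 0.0])

    def repeats(self):
        """Iterate (strand_index, repeat_index, RepeatStructure)."""
        for s, strand in enumerate(self.strands):
            for k, rep in enumerate(strand.repeats):
                yield s, k, rep


def build_tetramer(repeat: RepeatStructure, params: SupercoilParams,
                   check_clashes: bool = False) -> TetramerModel:
    """Assemble the full two-strand supercoil model.

    Strand A places ``n_repeats_per_strand`` copies of ``repeat`` on the
    supercoil; strand B is the duplicate rotated 180° about a line
    perpendicular to the long axis through the centre of mass, which
    interleaves the two strands diametrically with a half-pitch axial
    offset (two repeats).  With ``check_clashes`` a clash-free model is
    required and a structured failure raised otherwise.
    """
    template = repeat
    if template.linker_range is not None:
        from .assembly import _strip_linker

        template = _strip_linker(template)
    placed, transforms = [], []
    for k in range(params.n_repeats_per_strand):
        rep_k, tf = place_repeat(template, params, k)
        rep_k = rep_k.renumbered(k * (template.n_res + 5))
        rep_k.chain_label = "A"
        rep_k.repeat_id = f"A{k + 1}"
        placed.append(rep_k)
        transforms.append(tf)
    strand_a = StrandModel(placed, transforms, "composite")

    n = params.n_repeats_per_strand
    rise = params.pitch * 10.0 / params.repeats_per_turn
    # 2-fold axis height: places strand B centres at z = m*rise + 2*rise
    # (half-pitch interdigitation) while keeping the axis through the
    # centre of mass of the pair.
    h = ((n - 1) * rise + 2.0 * rise) / 2.0
    flip = RigidTransform.about_axis([1.0, 0.0, 0.0], 180.0, point=[0.0, 0.0, h])
    strand_b = strand_a.transformed(flip)
    for k, rep in enumerate(strand_b.repeats):
        rep.chain_label = "B"
        rep.repeat_id = f"B{k + 1}"
    model = TetramerModel(params, strand_a, strand_b)
    if check_clashes:
        clashes = detect_clashes(model)
        if clashes:
            raise ClashError(params, clashes)
    return model


class ClashError(RuntimeError):
    """Structured failure: clash-free placement unsatisfiable at this roll."""

    def __init__(self, params: SupercoilParams, clashes: list):
        self.params = params
        self.clashes = clashes
        super().__init__(
            f"{len(clashes)} steric clash(es) at roll {params.roll}°, "
            f"length {params.total_length} nm; first: {clashes[0]}"
        )


def detect_clashes(model: TetramerModel, threshold: float = CLASH_THRESHOLD,
                   exempt_separation: int = JOINT_EXEMPT_SEPARATION) -> list:
    """All Cα pairs from different repeats closer than ``threshold`` Å.

    Pairs from consecutive repeats of the same strand whose
    through-linker sequence separation is at most ``exempt_separation``
    residues are exempt (they are covalently connected through the
    5-residue linker and necessarily proximal).  Uses a k-d tree; the
    result matches an all-pairs scan.
    """
    coords, labels = [], []
    for s, k, rep in model.repeats():
        n = rep.n_res
        for j in range(n):
            labels.append((s, k, j, n))
        coords.append(rep.ca)
    coords = np.concatenate(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    clashes = []
    for i, j in pairs:
        s1, k1, r1, n1 = labels[i]
        s2, k2, r2, n2 = labels[j]
        if s1 == s2 and k1 == k2:
            continue
        if s1 == s2 and abs(k1 - k2) == 1:
            if k2 < k1:
                (k1, r1, n1), (k2, r2, n2) = (k2, r2, n2), (k1, r1, n1)
            sep = (n1 - 1 - r1) + 5 + (r2 + 1)
            if sep <= exempt_separation:
                continue
        clashes.append(((s1, k1, r1), (s2, k2, r2)))
    return clashes


def _brute_force_clashes(model: TetramerModel, threshold: float = CLASH_THRESHOLD,
                         exempt_separation: int = JOINT_EXEMPT_SEPARATION) -> list:
    """O(n²) reference implementation of :func:`detect_clashes` (tests)."""
    entries = []
    for s, k, rep in model.repeats():
        for j in range(rep.n_res):
            entries.append(((s, k, j, rep.n_res), rep.ca[j]))
    clashes = []
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            (s1, k1, r1, n1), c1 = entries[a]
            (s2, k2, r2, n2), c2 = entries[b]
            if s1 == s2 and k1 == k2:
                continue
            if np.linalg.norm(c1 - c2) >= threshold:
                continue
            if s1 == s2 and abs(k1 - k2) == 1:
                if k2 < k1:
                    (k1, r1, n1), (k2, r2, n2) = (k2, r2, n2), (k1, r1, n1)
                if (n1 - 1 - r1) + 5 + (r2 + 1) <= exempt_separation:
                    continue
            clashes.append(((s1, k1, r1), (s2, k2, r2)))
    return clashes


def scan_roll(repeat: RepeatStructure, total_length: float,
              rolls=None, **param_kwargs) -> pd.DataFrame:
    """Clash counts across roll values (steric window scan).

    Returns a DataFrame with columns ``roll`` and ``clashes`` plus the
    maximal contiguous zero-clash window in ``DataFrame.attrs['window']``
    (``None`` when every roll clashes).
    """
    if rolls is None:
        rolls = np.arange(-180.0, 180.0, 30.0)
    rolls = np.asarray(list(rolls), dtype=float)
    counts = []
    for roll in rolls:
        params = compute_params(total_length, roll=roll, **param_kwargs)
        model = build_tetramer(repeat, params)
        counts.append(len(detect_clashes(model)))
    table = pd.DataFrame({"roll": rolls, "clashes": counts})
    window = None
    best = 0
    i = 0
    counts_arr = np.array(counts)
    while i < len(rolls):
        if counts_arr[i] == 0:
            j = i
            while j + 1 < len(rolls) and counts_arr[j + 1] == 0:
                j += 1
            if j - i + 1 > best:
                best = j - i + 1
                window = (float(rolls[i]), float(rolls[j]))
            i = j + 1
        else:
            i += 1
    table.attrs["window"] = window
    return table


def _segment_corners(strand: StrandModel) -> np.ndarray:
    """Intersection points of consecutive repeat axis lines (supercoil
    'square' corners), from closest-approach midpoints."""
    corners = []
    reps = strand.repeats
    for a, b in zip(reps[:-1], reps[1:]):
        p1, d1 = a.anchor_midpoint, a.anchor_axis
        p2, d2 = b.anchor_midpoint, b.anchor_axis
        w0 = p1 - p2
        a11, a12 = 1.0, -np.dot(d1, d2)
        a22 = 1.0
        b1, b2 = -np.dot(w0, d1), np.dot(w0, d2)
        det = a11 * a22 - a12 * a12
        if abs(det) < 1e-12:
            corners.append(0.5 * (a.anchor_coords[1] + b.anchor_coords[0]))
            continue
        t1 = (b1 * a22 - b2 * a12) / det
        t2 = (a11 * b2 - a12 * b1) / det
        corners.append(0.5 * ((p1 + t1 * d1) + (p2 + t2 * d2)))
    return np.array(corners)


def measure_geometry(model: TetramerModel) -> dict:
    """Measured observables of a built model.

    Returns length (nm), mean supercoil radius (nm), mean inter-repeat
    bend (degrees), contour length per turn (nm) and the chirality sign
    (+1 right-handed, -1 left-handed, 0 straight).
    """
    if model.strand_a.n_repeats < 5:
        raise ValueError("geometry measurement needs at least 5 repeats per strand")
    axis = principal_axis(model.ca)
    com = model.ca.mean(axis=0)

    lengths = []
    for strand in model.strands:
        proj = strand.ca @ axis
        lengths.append(proj.max() - proj.min())
    length_nm = max(lengths) / 10.0

    mids = np.array([rep.anchor_midpoint for _, _, rep in model.repeats()])
    rel = mids - com
    radial = rel - np.outer(rel @ axis, axis)
    radius_nm = float(np.mean(np.linalg.norm(radial, axis=1))) / 10.0

    bends = []
    turns_contour = []
    chir = 0.0
    for strand in model.strands:
        vecs = np.array([r.anchor_coords[1] - r.anchor_coords[0] for r in strand.repeats])
        for v1, v2 in zip(vecs[:-1], vecs[1:]):
            bends.append(angle_between(v1, v2))
        corners = _segment_corners(strand)
        seg_lengths = np.linalg.norm(np.diff(corners, axis=0), axis=1)
        if len(seg_lengths) >= 4:
            turns_contour.append(np.mean(seg_lengths) * 4.0)
        # chirality: azimuthal advance vs axial advance of repeat midpoints
        smids = np.array([r.anchor_midpoint for r in strand.repeats]) - com
        z = smids @ axis
        xy = smids - np.outer(z, axis)
        e1 = xy[0] / max(np.linalg.norm(xy[0]), 1e-9)
        e2 = np.cross(axis, e1)
        u = xy @ e1
        v = xy @ e2
        cross = u[:-1] * v[1:] - u[1:] * v[:-1]
        chir += float(np.sum(cross * np.sign(np.diff(z))))

    radius_A = radius_nm * 10.0
    chirality = 0 if abs(chir) < 1e-6 or radius_A < 0.5 else int(np.sign(chir))
    return {
        "length_nm": float(length_nm),
        "mean_radius_nm": radius_nm,
        "bend_deg": float(np.mean(bends)),
        "contour_per_turn_nm": float(np.mean(turns_contour)) / 10.0,
        "chirality": chirality,
    }


def sweep(repeat: RepeatStructure, lengths=None, roll: float = DEFAULT_ROLL,
          build_models: bool = False, **param_kwargs):
    """Extension–contraction sweep over molecular lengths.

    Returns ``(table, models)``: a DataFrame of (length_nm, pitch_nm,
    radius_nm, bend_deg) and, when ``build_models`` is set, one built
    tetramer per valid length.  Invalid (over-extended) lengths are
    skipped with a logged warning.
    """
    if lengths is None:
        lengths = np.arange(55.0, 185.0, 1.0)
    rows, models = [], []
    for length in lengths:
        try:
            params = compute_params(float(length), roll=roll, **param_kwargs)
        except ValueError as exc:
            logger.warning("skipping length %.3f nm: %s", length, exc)
            continue
        rows.append(
            {
                "length_nm": params.total_length,
                "pitch_nm": params.pitch,
                "radius_nm": params.radius,
                "bend_deg": params.bend_angle,
            }
        )
        if build_models:
            models.append(build_tetramer(repeat, params))
    return pd.DataFrame(rows), models
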