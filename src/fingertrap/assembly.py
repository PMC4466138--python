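"""Rigid superposition and extended (crystallographic-style) strand assembly.

The extended heterotetramer model is built by helix-C-onto-helix-C
concatenation: a two-repeat template exposes the Cα window of its
leading and trailing C helices, and fresh copies are appended by
superposing the leading window onto the trailing window of the growing
strand until the chain holds the full repeat count (20 full α repeats +
16 full β repeats + 1 tetramerization repeat = 37).  The second strand
of the tetramer is an antiparallel duplicate, rotated 180° about a line
through the centre of mass perpendicular to the long axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import RigidTransform, principal_axis, superpose
from .repeats import RepeatStructure

__all__ = [
    "StrandModel",
    "superpose",
    "helix_c_ids",
    "build_extended_strand",
    "make_antiparallel_partner",
    "count_strand_repeats",
]


@dataclass
class StrandModel:
    """One placed strand of spectrin repeats plus the per-repeat transforms."""

    repeats: list[RepeatStructure]
    transforms: list[RigidTransform]
    chain_label: str = "composite"

    def __post_init__(self) -> None:
        if len(self.repeats) < 1:
            raise ValueError("a strand needs at least one repeat")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def ca(self) -> np.ndarray:
        return np.concatenate([r.ca for r in self.repeats])

    @property
    def long_axis(self) -> np.ndarray:
        """First principal axis of the strand's Cα cloud (unit vector)."""
        return principal_axis(self.ca)

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from the strand's first anchor to its last anchor (N→C)."""
        start = self.repeats[0].anchor_coords[0]
        end = self.repeats[-1].anchor_coords[1]
        v = end - start
        return v / np.linalg.norm(v)

    @property
    def length(self) -> float:
        """End-to-end extent along the long axis, Å."""
        proj = self.ca @ self.long_axis
        return float(proj.max() - proj.min())

    def anchor_gaps(self) -> np.ndarray:
        """Distances between consecutive repeats' facing anchors, Å."""
        gaps = []
        for a, b in zip(self.repeats[:-1], self.repeats[1:]):
            gaps.append(np.linalg.norm(b.anchor_coords[0] - a.anchor_coords[1]))
        return np.array(gaps)

    def transformed(self, transform: RigidTransform) -> "StrandModel":
        return StrandModel(
            [r.transformed(transform) for r in self.repeats],
            [transform.compose(t) for t in self.transforms],
            self.chain_label,
        )


def helix_c_ids(repeat: RepeatStructure) -> np.ndarray:
    """Residue ids of the repeat's C helix (last third of the bundle)."""
    bundle_ids = repeat.res_ids[repeat.bundle_mask]
    n = len(bundle_ids)
    n_a = n // 3
    return bundle_ids[2 * n_a:]


def _helix_ca(repeat: RepeatStructure, ids: np.ndarray) -> np.ndarray:
    return np.array([repeat.ca_of(i) for i in ids])


def _strip_linker(repeat: RepeatStructure) -> RepeatStructure:
    if repeat.linker_range is None:
        return repeat
    mask = repeat.bundle_mask
    return replace(
        repeat,
        res_ids=repeat.res_ids[mask],
        sequence="".join(np.array(list(repeat.sequence))[mask]),
        coords=repeat.coords[mask],
        linker_range=None,
    )


def build_extended_strand(template: list[RepeatStructure], n_repeats: int = 37,
                          chain_label: str = "composite") -> StrandModel:
    """Concatenate a two-repeat template into an ``n_repeats`` strand.

    Each appended copy is placed by superposing its leading C-helix Cα
    window onto the trailing C helix of the previous copy; with a
    straight synthetic template the resulting strand is straight.
    """
    if len(template) < 2:
        raise ValueError("template must contain two consecutive repeats")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rep1, rep2 = template[0], template[1]
    lead_ids = helix_c_ids(rep1)
    trail_ids = helix_c_ids(rep2)
    if len(lead_ids) != len(trail_ids):
        raise ValueError("template helix-C windows have mismatched lengths")
    block = rep2.res_ids[0] - rep1.res_ids[0]

    placed = [_strip_linker(rep1).renumbered(0)]
    transforms = [RigidTransform.identity()]
    current = rep2
    current_tf = RigidTransform.identity()
    for k in range(1, n_repeats):
        placed.append(
            _strip_linker(current).transformed(current_tf).renumbered((k - 1) * block)
        )
        transforms.append(current_tf)
        # Align a fresh template copy's leading C helix onto the trailing
        # C helix of the repeat just placed.
        trailing = _helix_ca(current.transformed(current_tf), trail_ids)
        tf, _ = superpose(_helix_ca(rep1, lead_ids), trailing)
        current_tf = tf
    return StrandModel(placed[:n_repeats], transforms[:n_repeats], chain_label)


def make_antiparallel_partner(strand: StrandModel,
                              chain_label: str | None = None) -> StrandModel:
    """Duplicate a strand, rotated 180° about a line through its centre of
    mass perpendicular to its long axis (antiparallel partner)."""
    ca = strand.ca
    com = ca.mean(axis=0)
    centered = ca - com
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    perp = vt[1]  # second principal axis: perpendicular, reproducible
    flip = RigidTransform.about_axis(perp, 180.0, point=com)
    partner = strand.transformed(flip)
    partner.chain_label = chain_label or strand.chain_label
    return partner


def count_strand_repeats(alpha_full: int = 20, beta_full: int = 16,
                         tetramerization: int = 1) -> int:
    """Repeat count of one strand of the heterotetramer.

    20 full α repeats and 16 full β repeats joined through the
    tetramerization repeat (β helices A+B with α helix C) give the
    uninterrupted 37-repeat chain.
    """
    for name, v in (("alpha_full", alpha_full), ("beta_full", beta_full),
                    ("tetramerization", tetramerization)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return alpha_full + beta_full + tetramerization
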