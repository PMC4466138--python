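"""One-call generation of the full synthetic test universe.

Produces every artifact the pipeline and its tests consume — an ideal
repeat, a 37-repeat chain, compact and extended tetramer models, a
reference bent di-repeat with derived restraints, the protein-census
CSV and the end-on image set (29 rings at the measured 2.2 nm radius
plus control radii, a filled disk and pure noise) — under a single
seed, with a checksummed manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import make_endon_image
from .lattice import reproduce_table1
from .pdbio import write_image_grid, write_model_pdb
from .refine import build_linear_direpeat, default_restraints, direpeat_to_repeats
from .repeats import make_ideal_repeat, make_chain
from .supercoil import build_tetramer, compute_params

TETRAMER_LENGTHS_NM = (55.0, 60.0, 65.0, 184.0)
RING_RADII_A = (22.0, 15.0, 30.0)  # measured 2.2 nm plus control radii
N_RING_PARTICLES = 29


@dataclass
class FixtureManifest:
    """Paths, parameters and checksums of one fixture generation run."""

    seed: int
    outdir: str
    artifacts: dict = field(default_factory=dict)  # name -> {path, sha256}
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "outdir": self.outdir,
                "parameters": self.parameters,
                "artifacts": self.artifacts,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def generate_all(seed: int, outdir: str | Path) -> FixtureManifest:
    """Generate every synthetic fixture under ``outdir``.

    Regeneration with the same seed reproduces byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RuntimeError(f"cannot create fixture directory {outdir}: {exc}") from exc
    manifest = FixtureManifest(seed=int(seed), outdir=str(outdir))
    manifest.parameters = {
        "repeat": {"n_res": 106, "length_A": 45.0, "diameter_A": 25.0},
        "chain_repeats": 37,
        "tetramer_lengths_nm": list(TETRAMER_LENGTHS_NM),
        "ring_radii_A": list(RING_RADII_A),
        "n_ring_particles": N_RING_PARTICLES,
        "crosslink_upper_bound_A": 11.0,
    }

    def register(name: str, path: Path) -> None:
        manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    repeat = make_ideal_repeat(seed=seed)
    path = outdir / "repeat_ideal.pdb"
    write_model_pdb([repeat], path)
    register("repeat_ideal", path)

    chain = make_chain(repeat, 37)
    path = outdir / "chain_37.pdb"
    write_model_pdb(chain, path)
    register("chain_37", path)

    for length in TETRAMER_LENGTHS_NM:
        params = compute_params(length)
        model = build_tetramer(repeat, params)
        path = outdir / f"tetramer_{int(length)}nm.pdb"
        write_model_pdb(model.strand_a.repeats + model.strand_b.repeats, path)
        register(f"tetramer_{int(length)}nm", path)

    # reference di-repeat (linear) plus the crosslink restraint table
    direpeat = build_linear_direpeat(repeat)
    path = outdir / "direpeat_linear.pdb"
    write_model_pdb(direpeat_to_repeats(direpeat), path)
    register("direpeat_linear", path)
    restraints = default_restraints(direpeat)
    path = outdir / "restraints.csv"
    pd.DataFrame(
        [
            {
                "repeat_a": r.site_a[0], "res_a": r.site_a[1],
                "repeat_b": r.site_b[0], "res_b": r.site_b[1],
                "upper_bound_A": r.upper_bound,
            }
            for r in restraints
        ]
    ).to_csv(path, index=False)
    register("restraints", path)

    path = outdir / "protein_census.csv"
    reproduce_table1().to_csv(path, index=False)
    register("protein_census", path)

    rng = np.random.default_rng(seed)
    for i in range(N_RING_PARTICLES):
        img = make_endon_image(ring_radius=22.0, noise_sd=0.5,
                               seed=int(rng.integers(0, 2**31)))
        path = outdir / f"ring_22A_{i:02d}.txt"
        write_image_grid(path, img.pixels)
        register(f"ring_22A_{i:02d}", path)
    for radius in RING_RADII_A[1:]:
        img = make_endon_image(ring_radius=radius, noise_sd=0.5,
                               seed=int(rng.integers(0, 2**31)))
        path = outdir / f"ring_{int(radius)}A.txt"
        write_image_grid(path, img.pixels)
        register(f"ring_{int(radius)}A", path)
    for shape in ("disk", "flat"):
        img = make_endon_image(ring_radius=22.0, noise_sd=0.5, shape=shape,
                               seed=int(rng.integers(0, 2**31)))
        path = outdir / f"control_{shape}.txt"
        write_image_grid(path, img.pixels)
        register(f"control_{shape}", path)

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
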