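"""Synthetic data and mock backends.

Everything the MD and docking engines would produce is emulated here with
known ground truth, so every later pipeline stage is testable end to end:

* Gaussian forward/reverse work distributions that satisfy the Crooks
  fluctuation theorem exactly — for equal-variance Gaussians the unique
  CFT-consistent pair is W_f ~ N(ΔG + σ²/2k_BT, σ²) and
  W_r ~ N(−ΔG + σ²/2k_BT, σ²) (reverse recorded along the B→A switch);
* noisy edge-ΔΔG graphs over known node free energies;
* pose sets displaced from a reference by known rigid translations.

All generators are bit-reproducible under a fixed seed.  The mock NES
backend writes the same two-column work files (kJ/mol) the real pipeline
reads, so mock and real inputs are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chemdata import AffinityTable
from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_PER_MOL_K, KJ_PER_KCAL
from .fepmap import Edge, PerturbationMap
from .neswork import EdgeResult, WorkSet

__all__ = [
    "SyntheticStudy",
    "gen_cft_gaussian_works",
    "gen_map_study",
    "perturb_poses",
    "mock_nes_backend",
    "write_work_file",
]


@dataclass
class SyntheticStudy:
    """A perturbation map with known node truth, noisy edges and noisy
    'experimental' affinities."""

    map: PerturbationMap
    true_dg: dict[str, float]          # kcal/mol
    edge_results: list[EdgeResult]     # truth + Gaussian noise, se = noise SD
    affinities: AffinityTable          # truth + experimental noise
    edge_noise_sd: float
    exp_noise_sd: float
    seed: int

    def true_ddg(self, edge: Edge) -> float:
        return self.true_dg[edge.b] - self.true_dg[edge.a]


def gen_cft_gaussian_works(
    dg_true: float,
    sigma: float,
    n_f: int,
    n_r: int,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int | np.random.Generator = 0,
    edge_id: str = "synthetic",
    leg: str = "complex",
    replica: int = 1,
) -> WorkSet:
    """Crooks-consistent Gaussian work samples for a known ΔG.

    ``sigma`` is the work SD (kcal/mol), i.e. the dissipation scale: both
    directions dissipate σ²/2k_BT on average.  σ = 0 collapses to delta
    functions at ±ΔG.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kbt = KB_KCAL_PER_MOL_K * temperature
    dissipation = sigma**2 / (2.0 * kbt)
    w_f = rng.normal(dg_true + dissipation, sigma, size=n_f)
    w_r = rng.normal(-dg_true + dissipation, sigma, size=n_r)
    return WorkSet(edge_id, leg, replica, w_f, w_r)


def _ring_with_chords(
    ids: list[str], target_degree: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Connected topology with cycles: an n-cycle plus random chords until
    every node reaches the target degree."""
    n = len(ids)
    pairs = {tuple(sorted((ids[i], ids[(i + 1) % n]))) for i in range(n)}
    degree = {x: 2 for x in ids}
    # candidate chords in rng-shuffled order for reproducibility
    chords = [(i, j) for i in range(n) for j in range(i + 2, n) if (i, j) != (0, n - 1)]
    rng.shuffle(chords)
    for i, j in chords:
        a, b = sorted((ids[i], ids[j]))
        if degree[a] < target_degree or degree[b] < target_degree:
            pairs.add((a, b))
            degree[a] += 1
            degree[b] += 1
    return sorted(pairs)


def gen_map_study(
    n_ligands: int,
    dg_range: tuple[float, float] = (-12.0, -7.7),
    edge_noise_sd: float = 0.3,
    exp_noise_sd: float = 0.43,
    target_degree: int = 3,
    seed: int = 0,
) -> SyntheticStudy:
    """Synthetic perturbation-map study with known node truth.

    True node ΔG are uniform over ``dg_range`` (default spans 4.3 kcal/mol,
    the scale of the benchmark congeneric series); the map is an n-cycle
    with chords to ``target_degree`` (default 3: enough redundancy that the
    graph solve averages edge noise down, as real map generators provide);
    edge ΔΔG are node differences plus N(0, edge_noise_sd); experimental
    affinities are truth plus N(0, exp_noise_sd).
    """
    if n_ligands < 3:
        raise ValueError("need at least 3 ligands")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_ligands)))
    ids = [f"lig{i + 1:0{width}d}" for i in range(n_ligands)]
    truth = {x: float(v) for x, v in zip(ids, rng.uniform(*dg_range, size=n_ligands))}

    pairs = _ring_with_chords(ids, target_degree, rng)
    edges = [Edge(a, b, float(rng.uniform(0.5, 1.0))) for a, b in pairs]
    edges.sort(key=lambda e: e.id)
    pmap = PerturbationMap(ids, edges)

    edge_results = []
    for e in pmap.edges:
        true_ddg = truth[e.b] - truth[e.a]
        noisy = true_ddg + float(rng.normal(0.0, edge_noise_sd))
        edge_results.append(
            EdgeResult(
                edge_id=e.id,
                dg_complex=noisy,
                dg_water=0.0,
                ddg=noisy,
                se=edge_noise_sd,
            )
        )

    entries = {
        x: (truth[x] + float(rng.normal(0.0, exp_noise_sd)), exp_noise_sd) for x in ids
    }
    return SyntheticStudy(
        map=pmap,
        true_dg=truth,
        edge_results=edge_results,
        affinities=AffinityTable(entries),
        edge_noise_sd=edge_noise_sd,
        exp_noise_sd=exp_noise_sd,
        seed=seed if isinstance(seed, int) else -1,
    )


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    ux, uy, uz = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array(
        [
            [c + ux**2 * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy**2 * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz**2 * (1 - c)],
        ]
    )


def perturb_poses(
    reference_coords: np.ndarray,
    displacement_scales,
    seed: int | np.random.Generator = 0,
    rotation_deg: float = 0.0,
) -> list[np.ndarray]:
    """Rigidly displaced copies of a reference pose with known ranking.

    Pose k is the reference translated along a random direction by exactly
    ``displacement_scales[k]`` Å (so its mapped RMSD under the identity
    mapping equals the scale exactly and the displacement ranking is the
    scale ranking).  A rotation about the centroid, of angle
    ``rotation_deg × scale_k`` degrees per Å, can be added for rougher pose
    sets; it is off by default because it breaks the exact-RMSD identity.
    """
    ref = np.asarray(reference_coords, dtype=float)
    scales = np.asarray(displacement_scales, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dirs = _random_unit_vectors(scales.size, rng)
    axes = _random_unit_vectors(scales.size, rng)
    poses = []
    for k, scale in enumerate(scales):
        coords = ref.copy()
        if rotation_deg != 0.0 and scale != 0.0:
            centroid = coords.mean(axis=0)
            rot = _rotation_matrix(axes[k], np.deg2rad(rotation_deg * scale))
            coords = (coords - centroid) @ rot.T + centroid
        poses.append(coords + scale * dirs[k])
    return poses


def write_work_file(path: str | Path, works_kcal: np.ndarray) -> None:
    """Write works (kcal/mol) as a two-column file in kJ/mol (pmx-style)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# snapshot  work_kJ_per_mol\n")
        for i, w in enumerate(np.atleast_1d(works_kcal), start=1):
            fh.write(f"{i} {w * KJ_PER_KCAL:.10f}\n")


def mock_nes_backend(
    edge_id: str,
    true_ddg: float,
    dissipation_sigma: float,
    n_transitions: int,
    n_replicas: int,
    outdir: str | Path,
    temperature: float = DEFAULT_TEMPERATURE_K,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Stand-in for the MD stages of one edge: writes work files for both legs.

    The water leg is generated with leg ΔG = 0 and the complex leg with
    leg ΔG = ``true_ddg`` — a modelling convenience; the estimator sees
    only work values, never leg physics.  Layout under ``outdir``::

        <edge_id>/<leg>/replica_<k>/{forward.dat,reverse.dat}

    files in the two-column kJ/mol format.  Returns a manifest of paths.
    """
    if n_transitions < 2:
        raise ValueError("n_transitions must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    outdir = Path(outdir)
    manifest: dict = {"edge_id": edge_id, "legs": {}}
    for leg, leg_dg in (("complex", true_ddg), ("water", 0.0)):
        manifest["legs"][leg] = []
        for rep in range(1, n_replicas + 1):
            ws = gen_cft_gaussian_works(
                leg_dg, dissipation_sigma, n_transitions, n_transitions,
                temperature, rng, edge_id, leg, rep,
            )
            rep_dir = outdir / edge_id / leg / f"replica_{rep}"
            write_work_file(rep_dir / "forward.dat", ws.w_forward)
            write_work_file(rep_dir / "reverse.dat", ws.w_reverse)
            manifest["legs"][leg].append(str(rep_dir))
    return manifest
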