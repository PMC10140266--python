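"""Maximum-common-substructure pose filtering.

Docking engines that cannot constrain poses to a reference binding mode can
still be steered towards it after the fact: generate many poses per ligand,
compute the maximum common substructure (MCS) between the ligand and a
reference ligand whose pose is trusted, and keep the pose whose mapped atoms
deviate least from the reference coordinates.  All RMSDs here are computed in
the shared receptor frame *without* superposition — docked and reference
poses live in the same crystal frame, and superposing would hide exactly the
binding-mode flips this filter exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .exceptions import InsufficientCommonSubstructureError, McsTimeoutError

__all__ = [
    "AtomMapping",
    "PoseSet",
    "McsOptions",
    "compute_mcs",
    "compute_mcs_mappings",
    "mapped_rmsd",
    "select_best_pose",
    "match_core",
]


@dataclass(frozen=True)
class AtomMapping:
    """Injective atom-index mapping (query index, reference index), 0-based."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if len(self.pairs) == 0:
            raise ValueError("atom mapping is empty")
        q = [p[0] for p in self.pairs]
        r = [p[1] for p in self.pairs]
        if len(set(q)) != len(q) or len(set(r)) != len(r):
            raise ValueError("atom mapping is not injective")
        if min(q) < 0 or min(r) < 0:
            raise ValueError("negative atom index in mapping")

    def __len__(self) -> int:
        return len(self.pairs)

    def inverted(self) -> "AtomMapping":
        return AtomMapping(tuple((r, q) for q, r in self.pairs))


@dataclass
class PoseSet:
    """Ordered poses of one ligand sharing a single topology.

    ``coords`` are (n_atoms, 3) arrays in Å, in the order the docking engine
    emitted them (rank order); ``props`` keeps any engine score tags as
    opaque strings.
    """

    ligand_id: str
    mol: Chem.Mol
    coords: list[np.ndarray]
    props: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.coords) < 1:
            raise ValueError(f"pose set for '{self.ligand_id}' has no poses")
        n = self.coords[0].shape[0]
        for k, c in enumerate(self.coords):
            if c.shape != (n, 3):
                raise ValueError(
                    f"pose {k} of '{self.ligand_id}' has shape {c.shape}, "
                    f"expected ({n}, 3)"
                )
        if not self.props:
            self.props = [{} for _ in self.coords]

    @property
    def n_poses(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class McsOptions:
    """MCS search options.

    Defaults are deliberately strict: heavy atoms only, element-exact
    matching, ring atoms match only ring atoms and ring bonds only ring
    bonds.  Chemically loose mappings (aryl onto alkyl and the like) produce
    meaningless pose RMSDs and, downstream, meaningless perturbation edges.
    """

    min_heavy_atoms: int = 3
    timeout_s: int = 10
    ring_matches_ring_only: bool = True
    complete_rings_only: bool = False
    max_matches: int = 256


def _heavy_copy(mol: Chem.Mol) -> tuple[Chem.Mol, list[int]]:
    """Hydrogen-free copy plus heavy-index → original-index lookup.

    RemoveHs preserves the relative order of heavy atoms, so position k in
    the stripped molecule corresponds to ``index_map[k]`` in the original.
    """
    index_map = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    stripped = Chem.RemoveHs(Chem.Mol(mol), sanitize=False)
    Chem.SanitizeMol(stripped, catchErrors=True)
    if stripped.GetNumAtoms() != len(index_map):  # pragma: no cover
        raise RuntimeError("hydrogen stripping changed heavy-atom count")
    return stripped, index_map


def _mcs_query(query: Chem.Mol, reference: Chem.Mol, opts: McsOptions) -> Chem.Mol:
    res = rdFMCS.FindMCS(
        [query, reference],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=opts.ring_matches_ring_only,
        completeRingsOnly=opts.complete_rings_only,
        timeout=opts.timeout_s,
    )
    if res.canceled:
        raise McsTimeoutError(f"MCS search timed out after {opts.timeout_s} s")
    if res.numAtoms < opts.min_heavy_atoms:
        raise InsufficientCommonSubstructureError(
            f"insufficient common substructure: {res.numAtoms} heavy atoms "
            f"(minimum {opts.min_heavy_atoms})"
        )
    patt = Chem.MolFromSmarts(res.smartsString)
    if patt is None:  # pragma: no cover
        raise RuntimeError(f"MCS produced unparseable SMARTS {res.smartsString!r}")
    return patt


def compute_mcs_mappings(
    query: Chem.Mol, reference: Chem.Mol, opts: McsOptions | None = None
) -> list[AtomMapping]:
    """All symmetry-equivalent MCS atom mappings between two molecules.

    One substructure match is fixed on the query side and every automorphic
    match is enumerated on the reference side; the automorphism group of the
    MCS acts equivalently on either side, so this covers all distinct
    query↔reference pairings.  Indices refer to the molecules as given;
    hydrogens are ignored by the search.
    """
    opts = opts or McsOptions()
    q_heavy, q_map = _heavy_copy(query)
    r_heavy, r_map = _heavy_copy(reference)
    patt = _mcs_query(q_heavy, r_heavy, opts)
    q_match = q_heavy.GetSubstructMatch(patt)
    r_matches = r_heavy.GetSubstructMatches(
        patt, uniquify=False, maxMatches=opts.max_matches
    )
    if not q_match or not r_matches:
        raise InsufficientCommonSubstructureError(
            "MCS pattern failed to match back onto the inputs"
        )
    mappings = []
    for rm in r_matches:
        mappings.append(
            AtomMapping(
                tuple((q_map[qi], r_map[ri]) for qi, ri in zip(q_match, rm))
            )
        )
    return mappings


def compute_mcs(
    query: Chem.Mol, reference: Chem.Mol, opts: McsOptions | None = None
) -> AtomMapping:
    """One maximum-common-substructure mapping (deterministic for fixed inputs).

    Raises
    ------
    InsufficientCommonSubstructureError
        If the MCS has fewer heavy atoms than ``opts.min_heavy_atoms``.
    McsTimeoutError
        If the search exceeds ``opts.timeout_s``.
    """
    return compute_mcs_mappings(query, reference, opts)[0]


def mapped_rmsd(
    query_coords: np.ndarray, reference_coords: np.ndarray, mapping: AtomMapping
) -> float:
    """RMSD (Å) over mapped atom pairs, without superposition."""
    q = np.asarray(query_coords, dtype=float)
    r = np.asarray(reference_coords, dtype=float)
    qi = np.array([p[0] for p in mapping.pairs])
    ri = np.array([p[1] for p in mapping.pairs])
    if qi.max() >= q.shape[0] or ri.max() >= r.shape[0]:
        raise ValueError("mapping index out of range for the coordinate blocks")
    d = q[qi] - r[ri]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def _pose_rmsd(
    pose: np.ndarray, reference_coords: np.ndarray, mappings: list[AtomMapping]
) -> float:
    # minimum over automorphic mappings, so aromatic-ring flips do not
    # inflate the RMSD arbitrarily
    return min(mapped_rmsd(pose, reference_coords, m) for m in mappings)


def select_best_pose(
    poses: PoseSet,
    reference_coords: np.ndarray,
    mapping: AtomMapping | list[AtomMapping],
) -> tuple[int, float]:
    """Index and RMSD of the pose closest to the reference over the mapping.

    ``mapping`` may be a single mapping or the list of symmetry-equivalent
    mappings from :func:`compute_mcs_mappings`; with a list, each pose scores
    its minimum over the mappings.  Ties break to the lowest pose index, i.e.
    the engine's own rank order.
    """
    mappings = [mapping] if isinstance(mapping, AtomMapping) else list(mapping)
    if not mappings:
        raise ValueError("no atom mappings supplied")
    rmsds = [_pose_rmsd(c, reference_coords, mappings) for c in poses.coords]
    best = int(np.argmin(rmsds))
    return best, float(rmsds[best])


def match_core(mol: Chem.Mol, core_smarts: str) -> tuple[bool, list[int]]:
    """Test a fixed-core SMARTS constraint against a molecule.

    Returns ``(True, atom_indices_of_first_match)`` or ``(False, [])``.
    """
    patt = Chem.MolFromSmarts(core_smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS pattern: {core_smarts!r}")
    match = mol.GetSubstructMatch(patt)
    return (True, list(match)) if match else (False, [])
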