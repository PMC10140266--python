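"""Ligand ingestion, identity and charge bookkeeping, SDF/SMILES/CSV I/O.

A relative free energy series must be charge-consistent: an alchemical edge
between ligands of different net charge is not meaningful without special
treatment, so series are filtered to a single (modal) formal charge before
any map is built.  Formal charge is taken from the parsed structure itself —
protonation-state enumeration is out of scope and delegated upstream.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .exceptions import ChargeTieError, ParseError
from .posesel import PoseSet

__all__ = [
    "LigandRecord",
    "AffinityTable",
    "read_ligands",
    "filter_to_single_net_charge",
    "read_poses",
    "write_poses",
    "read_affinities",
    "write_affinities",
]


@dataclass
class LigandRecord:
    """One ligand: identity, structure, net formal charge, optional conformer."""

    id: str
    smiles: str
    net_charge: int
    conformer: np.ndarray | None = None  # (n_atoms, 3) in Å
    props: dict[str, str] = field(default_factory=dict)

    def to_mol(self) -> Chem.Mol:
        """RDKit molecule; carries the conformer if one is attached."""
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ParseError(f"ligand '{self.id}': unparseable SMILES {self.smiles!r}")
        if self.conformer is not None:
            if self.conformer.shape[0] != mol.GetNumAtoms():
                raise ValueError(
                    f"ligand '{self.id}': conformer has {self.conformer.shape[0]} "
                    f"atoms, molecule has {mol.GetNumAtoms()}"
                )
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(self.conformer):
                conf.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.AddConformer(conf, assignId=True)
        return mol

    def embed(self, seed: int = 2023) -> "LigandRecord":
        """Attach a single low-energy 3D conformer (ETKDG + UFF relaxation).

        Pluggable stand-in for an external embedding stage; deterministic for
        a fixed seed.
        """
        mol = Chem.AddHs(Chem.MolFromSmiles(self.smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise RuntimeError(f"embedding failed for ligand '{self.id}'")
        AllChem.UFFOptimizeMolecule(mol)
        mol = Chem.RemoveHs(mol)
        coords = mol.GetConformer().GetPositions().astype(float)
        return LigandRecord(self.id, self.smiles, self.net_charge, coords, dict(self.props))


@dataclass
class AffinityTable:
    """Experimental binding free energies, ΔG in kcal/mol with σ ≥ 0."""

    entries: dict[str, tuple[float, float]]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("affinity table is empty")
        for lig, (dg, sigma) in self.entries.items():
            if sigma < 0:
                raise ValueError(f"ligand '{lig}': negative sigma_exp {sigma}")
            if not np.isfinite(dg):
                raise ValueError(f"ligand '{lig}': non-finite dg_exp")

    def __contains__(self, lig: str) -> bool:
        return lig in self.entries

    def dg(self, lig: str) -> float:
        return self.entries[lig][0]

    def sigma(self, lig: str) -> float:
        return self.entries[lig][1]


def _parse_smiles(lig_id: str, smiles: str, row: int) -> LigandRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(
            f"row {row}: ligand '{lig_id}' has unparseable SMILES {smiles!r}"
        )
    return LigandRecord(id=lig_id, smiles=smiles, net_charge=Chem.GetFormalCharge(mol))


def read_ligands(path: str | Path) -> list[LigandRecord]:
    """Read ligands from a ``.smi`` ("id SMILES" per line) or CSV (id,smiles) file.

    Records come back in file order; ``net_charge`` is computed from the
    parsed structure.  Unparseable SMILES and duplicate ids are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[LigandRecord] = []
    seen: set[str] = set()

    def _add(lig_id: str, smiles: str, row: int):
        if lig_id in seen:
            raise ParseError(f"row {row}: duplicate ligand id '{lig_id}'")
        seen.add(lig_id)
        records.append(_parse_smiles(lig_id, smiles, row))

    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
                raise ParseError(f"{path}: CSV must have header columns id,smiles")
            for i, row in enumerate(reader, start=2):
                _add(row["id"].strip(), row["smiles"].strip(), i)
    else:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"row {i}: expected 'id SMILES', got {line!r}")
                _add(parts[0], parts[1], i)
    if not records:
        raise ParseError(f"{path}: no ligands found")
    return records


def filter_to_single_net_charge(
    records: list[LigandRecord],
) -> tuple[list[LigandRecord], list[LigandRecord]]:
    """Partition a series into (kept, dropped) by modal net charge.

    A tie for the modal charge is an error rather than an arbitrary pick —
    silently mixing charge states invalidates every downstream perturbation.
    """
    if not records:
        raise ValueError("empty ligand list")
    counts = Counter(r.net_charge for r in records)
    top = counts.most_common()
    best_count = top[0][1]
    tied = sorted(c for c, n in top if n == best_count)
    if len(tied) > 1:
        raise ChargeTieError(
            f"tie for modal net charge between charges {tied}; "
            "choose the charge state to keep explicitly"
        )
    modal = tied[0]
    kept = [r for r in records if r.net_charge == modal]
    dropped = [r for r in records if r.net_charge != modal]
    return kept, dropped


def read_poses(path: str | Path) -> dict[str, PoseSet]:
    """Read a multi-record SDF into per-ligand pose sets, keyed by ligand id.

    The ligand id is the molecule title line; consecutive records with the
    same id become one ordered pose set.  Any engine property tags (docking
    scores etc.) are preserved as strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        return {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    out: dict[str, PoseSet] = {}
    order: dict[str, list[np.ndarray]] = {}
    props: dict[str, list[dict[str, str]]] = {}
    mols: dict[str, Chem.Mol] = {}
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"{path}: SDF record {i} failed to parse")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if not name.strip():
            raise ParseError(f"{path}: SDF record {i} has no ligand id (empty title)")
        name = name.strip()
        coords = mol.GetConformer().GetPositions().astype(float)
        ptags = {k: mol.GetProp(k) for k in mol.GetPropNames()}
        if name not in order:
            order[name] = []
            props[name] = []
            mols[name] = mol
        elif coords.shape[0] != order[name][0].shape[0]:
            raise ParseError(
                f"{path}: record {i} of ligand '{name}' has a different atom count"
            )
        order[name].append(coords)
        props[name].append(ptags)
    for name in order:
        out[name] = PoseSet(name, mols[name], order[name], props[name])
    return out


def write_poses(path: str | Path, pose_sets: dict[str, PoseSet] | list[PoseSet]) -> None:
    """Write pose sets to a V2000 SDF (coordinates at 4 decimals, Å)."""
    if isinstance(pose_sets, dict):
        pose_sets = list(pose_sets.values())
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    try:
        for ps in pose_sets:
            for k, coords in enumerate(ps.coords):
                mol = Chem.Mol(ps.mol)
                mol.RemoveAllConformers()
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, (x, y, z) in enumerate(coords):
                    conf.SetAtomPosition(i, (float(x), float(y), float(z)))
                mol.AddConformer(conf, assignId=True)
                mol.SetProp("_Name", ps.ligand_id)
                for key, val in ps.props[k].items():
                    mol.SetProp(key, str(val))
                writer.write(mol)
    finally:
        writer.close()


def read_affinities(path: str | Path) -> AffinityTable:
    """Read an experimental affinity CSV with header id,dg_exp_kcal,sigma_exp_kcal."""
    path = Path(path)
    entries: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"id", "dg_exp_kcal", "sigma_exp_kcal"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: CSV must have header columns id,dg_exp_kcal,sigma_exp_kcal"
            )
        for i, row in enumerate(reader, start=2):
            lig = row["id"].strip()
            if lig in entries:
                raise ParseError(f"row {i}: duplicate ligand id '{lig}'")
            try:
                dg = float(row["dg_exp_kcal"])
                sigma = float(row["sigma_exp_kcal"])
            except ValueError as exc:
                raise ParseError(f"row {i}: non-numeric affinity entry") from exc
            entries[lig] = (dg, sigma)
    return AffinityTable(entries)


def write_affinities(path: str | Path, table: AffinityTable) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "dg_exp_kcal", "sigma_exp_kcal"])
        for lig, (dg, sigma) in table.entries.items():
            writer.writerow([lig, repr(float(dg)), repr(float(sigma))])
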