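"""Compound standardization and the four matching descriptors.

Every downstream stage (decoy matching, screening, reporting) works on
libraries that have passed :func:`standardize_library` and carry a
:class:`PropertyVector` of the four descriptors used for decoy matching:
molecular weight, Crippen logP, hydrogen-bond-donor count and
hydrogen-bond-acceptor count (Lipinski-style N/O perception).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

ROLES = ("active", "pool", "decoy", "query")


@dataclass(frozen=True)
class PropertyVector:
    """The four decoy-matching descriptors.

    mw is the average-atomic-mass molecular weight in Da; logp the Crippen
    fragment-additive octanol/water partition estimate; hbd the count of
    N/O heavy atoms bearing at least one hydrogen; hba the count of N and O
    atoms (Lipinski acceptor perception).
    """

    mw: float
    logp: float
    hbd: int
    hba: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"mw must be positive, got {self.mw}")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("hbd and hba must be non-negative")

    def as_tuple(self) -> tuple[float, float, int, int]:
        return (self.mw, self.logp, self.hbd, self.hba)


@dataclass
class MoleculeRecord:
    """One compound: identifier, SMILES, role and (optionally) properties."""

    id: str
    smiles: str
    role: str = "pool"
    props: PropertyVector | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class Removal:
    """One entry of the standardization removal log."""

    id: str
    reason: str  # parse_error | multi_component | inorganic | duplicate


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None when RDKit cannot parse the input."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def standardize_library(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[Removal]]:
    """Canonicalize a library, dropping unparseable, multi-component,
    carbon-free and duplicate structures.

    Rules, applied in order per record:

    * unparseable SMILES -> dropped, reason ``parse_error``;
    * more than one connected component (salt / fragment) -> ``multi_component``;
    * no carbon atom (operational "inorganic" proxy) -> ``inorganic``;
    * canonical structure already seen -> ``duplicate`` (first occurrence wins).

    Survivors keep their input order and have their SMILES replaced by the
    RDKit canonical form, which makes the operation idempotent.
    """
    kept: list[MoleculeRecord] = []
    removals: list[Removal] = []
    seen: set[str] = set()
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            removals.append(Removal(rec.id, "parse_error"))
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            removals.append(Removal(rec.id, "multi_component"))
            continue
        if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
            removals.append(Removal(rec.id, "inorganic"))
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            removals.append(Removal(rec.id, "duplicate"))
            continue
        seen.add(can)
        kept.append(replace(rec, smiles=can))
    return kept, removals


def compute_properties(record: MoleculeRecord) -> PropertyVector:
    """Descriptor vector for a standardized record.

    Deterministic for a fixed canonical structure; raises ValueError when
    the structure cannot be parsed (callers exclude such records and log
    the reason).
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"cannot parse structure for {record.id!r}")
    # recanonicalize so descriptor float summation order is independent of
    # how the input SMILES was written (logP is an atom-wise sum)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NOCount(mol),
    )


def annotate_properties(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], list[Removal]]:
    """Attach PropertyVectors to a standardized library.

    Records whose properties cannot be computed are excluded and logged
    with reason ``property_error``.
    """
    kept: list[MoleculeRecord] = []
    failed: list[Removal] = []
    for rec in records:
        try:
            props = compute_properties(rec)
        except ValueError:
            failed.append(Removal(rec.id, "property_error"))
            continue
        kept.append(replace(rec, props=props))
    return kept, failed


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_smi(path: str | Path, role: str = "pool") -> list[MoleculeRecord]:
    """Read a .smi file: one ``SMILES<whitespace>id`` per line, '#' comments
    and blank lines ignored. A missing id becomes ``mol<lineno>``."""
    records: list[MoleculeRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        records.append(MoleculeRecord(id=mol_id, smiles=smiles, role=role))
    return records


def write_smi(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_sdf(path: str | Path, role: str = "pool", id_tag: str | None = None) -> list[MoleculeRecord]:
    """Read an SDF; id from `id_tag` when given, else the molecule title."""
    records: list[MoleculeRecord] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        if id_tag and mol.HasProp(id_tag):
            mol_id = mol.GetProp(id_tag)
        else:
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
        records.append(MoleculeRecord(id=mol_id or f"mol{i + 1}", smiles=Chem.MolToSmiles(mol), role=role))
    return records


def write_property_table(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """CSV with header ``id,smiles,role,mw,logp,hbd,hba``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "role", "mw", "logp", "hbd", "hba"])
        for rec in records:
            p = rec.props
            if p is None:
                raise ValueError(f"record {rec.id!r} has no properties")
            writer.writerow([rec.id, rec.smiles, rec.role, f"{p.mw:.3f}", f"{p.logp:.4f}", p.hbd, p.hba])


def read_property_table(path: str | Path) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                MoleculeRecord(
                    id=row["id"],
                    smiles=row["smiles"],
                    role=row.get("role", "pool"),
                    props=PropertyVector(
                        mw=float(row["mw"]),
                        logp=float(row["logp"]),
                        hbd=int(row["hbd"]),
                        hba=int(row["hba"]),
                    ),
                )
            )
    return records


def write_removal_log(removals: Iterable[Removal], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "reason"])
        for rem in removals:
            writer.writerow([rem.id, rem.reason])
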