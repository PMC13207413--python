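"""Simplified ligand-based pharmacophore representation, perception, mapping
and fit scoring.

A pharmacophore model is a small set (3-5) of typed feature spheres:
H (hydrophobic centroid), D (H-bond donor), A (H-bond acceptor),
R (aromatic-ring centroid), each with a 3D center, a tolerance radius and a
weight. A ligand conformer is abstracted to a FeatureCloud of typed points.
Mapping enumerates every kind-compatible injective assignment of model
features to cloud points, rigidly superposes the assigned points onto the
feature centers (Kabsch least squares) and accepts the assignment when every
residual distance lies within its tolerance. The fit value is

    fit = sum_i w_i * (1 - (d_i/t_i)^2)

maximal (sum of weights) at perfect overlay; contributions are floored at 0
when tolerance acceptance is relaxed. The screening rule permits no omitted
model features: only complete assignments are ever considered.
"""

from __future__ import annotations

import csv
import itertools
import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .screen_eval import LABEL_ACTIVE, LABEL_DECOY, RankedEntry, RankedScreen, rank_screen

FEATURE_KINDS = ("H", "D", "A", "R")
DEFAULT_TOLERANCE = 1.6  # Angstrom
DEFAULT_WEIGHT = 1.0


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    center: tuple[float, float, float]
    tolerance: float = DEFAULT_TOLERANCE
    weight: float = DEFAULT_WEIGHT

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}, got {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class PharmacophoreModel:
    name: str
    features: list[PharmacophoreFeature]
    require_all: bool = True

    def __post_init__(self) -> None:
        if len(self.features) < 3:
            raise ValueError("a model needs at least 3 features")

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([f.center for f in self.features], dtype=float)

    @property
    def max_fit(self) -> float:
        return float(sum(f.weight for f in self.features))

    @property
    def composition(self) -> str:
        """Kind string, e.g. 'HHDA' for two hydrophobes, one donor, one acceptor."""
        return "".join(f.kind for f in self.features)


@dataclass
class FeatureCloud:
    mol_id: str
    points: list[tuple[str, np.ndarray]]
    conf_id: int = 0

    def kinds(self) -> list[str]:
        return [k for k, _ in self.points]

    def coords(self) -> np.ndarray:
        return np.asarray([p for _, p in self.points], dtype=float)


@dataclass
class MappingResult:
    assignment: list[tuple[int, int]]  # (model feature index, cloud point index)
    rotation: np.ndarray               # 3x3, applied to the centered cloud
    translation: np.ndarray            # 3-vector
    residuals: np.ndarray              # per-feature distance after superposition, A
    fit: float
    complete: bool


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def perceive_features(mol, conf_id: int = 0) -> FeatureCloud:
    """Perceive typed feature points from an RDKit molecule with 3D coordinates.

    D at N/O heavy atoms bearing >= 1 hydrogen; A at every N/O atom; R at
    aromatic-ring centroids; H at centroids of connected groups of >= 3
    non-aromatic carbons. Deterministic for a fixed conformer.
    """
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ValueError("no_3d")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else "mol"

    points: list[tuple[str, np.ndarray]] = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            xyz = pos[atom.GetIdx()]
            if atom.GetTotalNumHs() >= 1:
                points.append(("D", np.array(xyz)))
            points.append(("A", np.array(xyz)))

    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            points.append(("R", pos[list(ring)].mean(axis=0)))

    # connected non-aromatic carbon groups of size >= 3 -> hydrophobic centroids
    g: dict[int, set[int]] = defaultdict(set)
    carbons = {
        a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 6 and not a.GetIsAromatic()
    }
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in carbons and j in carbons:
            g[i].add(j)
            g[j].add(i)
    seen: set[int] = set()
    for start in sorted(carbons):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(g[node] - seen)
        if len(comp) >= 3:
            points.append(("H", pos[sorted(comp)].mean(axis=0)))

    return FeatureCloud(mol_id=mol_id, points=points, conf_id=conf_id)


# ---------------------------------------------------------------------------
# rigid superposition + mapping
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation R and translation t with R@P_i + t ~ Q_i."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _assignments(model: PharmacophoreModel, cloud: FeatureCloud):
    """All injective kind-compatible assignments of model features to points."""
    candidates = [
        [i for i, k in enumerate(cloud.kinds()) if k == f.kind] for f in model.features
    ]
    if any(not c for c in candidates):
        return
    for combo in itertools.product(*candidates):
        if len(set(combo)) == len(combo):
            yield list(combo)


def _score_assignment(
    model: PharmacophoreModel, cloud: FeatureCloud, point_idx: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, bool]:
    P = cloud.coords()[list(point_idx)]
    Q = model.centers
    R, t = kabsch(P, Q)
    residuals = np.linalg.norm((P @ R.T + t) - Q, axis=1)
    tol = np.asarray([f.tolerance for f in model.features])
    w = np.asarray([f.weight for f in model.features])
    within = bool(np.all(residuals <= tol))
    fit = float(np.sum(w * np.maximum(0.0, 1.0 - (residuals / tol) ** 2)))
    return fit, R, t, residuals, within


def map_to_model(cloud: FeatureCloud, model: PharmacophoreModel) -> MappingResult | None:
    """Best-fit complete mapping of a feature cloud onto a model, or None.

    Every model feature must be matched (no omitted features). With
    require_all (the default) an assignment is accepted only when all
    post-superposition residuals are within tolerance; otherwise the best
    complete assignment is returned regardless of tolerance.
    """
    if not cloud.points:
        return None
    best: MappingResult | None = None
    for combo in _assignments(model, cloud):
        fit, R, t, residuals, within = _score_assignment(model, cloud, combo)
        if model.require_all and not within:
            continue
        if best is None or fit > best.fit:
            best = MappingResult(
                assignment=[(i, j) for i, j in enumerate(combo)],
                rotation=R,
                translation=t,
                residuals=residuals,
                fit=fit,
                complete=True,
            )
    return best


def screen_library(
    clouds: Mapping[str, Sequence[FeatureCloud]],
    model: PharmacophoreModel,
    labels: Mapping[str, str],
) -> tuple[RankedScreen, list[str]]:
    """Score a library of per-molecule conformer clouds against a model.

    Each molecule's score is the best fit over its clouds; molecules where
    no conformer maps are appended with a -inf sentinel score (they rank
    below every mapped molecule) and returned in the unmapped list. The
    RankedScreen feeds screen_eval unchanged.
    """
    entries: list[RankedEntry] = []
    unmapped: list[str] = []
    for mol_id in clouds:
        label = labels[mol_id]
        if label not in (LABEL_ACTIVE, LABEL_DECOY):
            label = LABEL_ACTIVE if str(label) == "2" else LABEL_DECOY
        fits = [r.fit for r in (map_to_model(c, model) for c in clouds[mol_id]) if r is not None]
        if fits:
            entries.append(RankedEntry(id=mol_id, score=max(fits), label=label))
        else:
            unmapped.append(mol_id)
            entries.append(RankedEntry(id=mol_id, score=-math.inf, label=label))
    return rank_screen(entries), unmapped


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_model(path: str | Path) -> PharmacophoreModel:
    """Model document (JSON or YAML): name, require_all,
    features[{kind, center:[x,y,z], tolerance, weight}]."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    features = [
        PharmacophoreFeature(
            kind=f["kind"],
            center=tuple(float(x) for x in f["center"]),
            tolerance=float(f.get("tolerance", DEFAULT_TOLERANCE)),
            weight=float(f.get("weight", DEFAULT_WEIGHT)),
        )
        for f in doc["features"]
    ]
    return PharmacophoreModel(
        name=doc.get("name", Path(path).stem),
        features=features,
        require_all=bool(doc.get("require_all", True)),
    )


def save_model(model: PharmacophoreModel, path: str | Path) -> None:
    doc = {
        "name": model.name,
        "require_all": model.require_all,
        "features": [
            {
                "kind": f.kind,
                "center": list(f.center),
                "tolerance": f.tolerance,
                "weight": f.weight,
            }
            for f in model.features
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_cloud_csv(path: str | Path) -> dict[str, list[FeatureCloud]]:
    """Cloud table ``mol_id,conf_id,kind,x,y,z`` -> per-molecule cloud lists."""
    rows: dict[tuple[str, int], list[tuple[str, np.ndarray]]] = defaultdict(list)
    order: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["mol_id"], int(row["conf_id"]))
            if key not in rows:
                order.append(key)
            rows[key].append(
                (row["kind"], np.array([float(row["x"]), float(row["y"]), float(row["z"])]))
            )
    clouds: dict[str, list[FeatureCloud]] = defaultdict(list)
    for mol_id, conf_id in order:
        clouds[mol_id].append(FeatureCloud(mol_id=mol_id, points=rows[(mol_id, conf_id)], conf_id=conf_id))
    return dict(clouds)


def write_cloud_csv(clouds: Mapping[str, Sequence[FeatureCloud]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "conf_id", "kind", "x", "y", "z"])
        for mol_id in clouds:
            for cloud in clouds[mol_id]:
                for kind, xyz in cloud.points:
                    writer.writerow([mol_id, cloud.conf_id, kind, repr(float(xyz[0])), repr(float(xyz[1])), repr(float(xyz[2]))])
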