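"""Property-matched decoy construction (DUD-E-style protocol).

Given a set of actives and a candidate pool, every pool member whose
canonical structure equals an active's is removed first, then each active
greedily claims the closest remaining candidates (z-normalized Euclidean
distance over the four descriptors) that fall inside the matching windows,
round-robin over actives so early actives cannot monopolize the pool.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_props import MoleculeRecord, canonical_smiles

PROPERTY_NAMES = ("mw", "logp", "hbd", "hba")


@dataclass(frozen=True)
class MatchingConfig:
    """Matching windows and target ratio.

    The windows are artifact defaults (the protocol the field uses leaves
    them to the builder): +/-25 Da mw, +/-1.0 logP, +/-1 HBD, +/-2 HBA.
    ``decoys_per_active`` presets for the two published validation sets are
    2080/1352 ~ 1.54 and 2162/1389 ~ 1.56.
    """

    window_mw: float = 25.0
    window_logp: float = 1.0
    window_hbd: int = 1
    window_hba: int = 2
    decoys_per_active: float = 1.0
    seed: int = 0
    exclusion_mode: str = "canonical_structure"

    def __post_init__(self) -> None:
        if min(self.window_mw, self.window_logp, self.window_hbd, self.window_hba) < 0:
            raise ValueError("matching windows must be non-negative")
        if self.decoys_per_active <= 0:
            raise ValueError("decoys_per_active must be positive")

    def windows(self) -> tuple[float, float, float, float]:
        return (self.window_mw, self.window_logp, float(self.window_hbd), float(self.window_hba))


@dataclass(frozen=True)
class DecoyProvenance:
    decoy_id: str
    active_id: str
    d_mw: float
    d_logp: float
    d_hbd: int
    d_hba: int


@dataclass
class DecoySet:
    actives: list[MoleculeRecord]
    decoys: list[MoleculeRecord]
    provenance: list[DecoyProvenance]
    config: MatchingConfig
    target_count: int
    shortfall: int = 0

    @property
    def warning(self) -> str | None:
        if self.shortfall:
            return f"pool exhausted: {self.shortfall} of {self.target_count} decoys missing"
        return None


def _props_matrix(records: Sequence[MoleculeRecord]) -> np.ndarray:
    rows = []
    for rec in records:
        if rec.props is None:
            raise ValueError(f"record {rec.id!r} has no properties; run chem_props first")
        rows.append(rec.props.as_tuple())
    return np.asarray(rows, dtype=float)


def build_decoy_set(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    config: MatchingConfig | None = None,
) -> DecoySet:
    """Select ceil(decoys_per_active * |actives|) property-matched decoys.

    Candidates for an active are the pool members (actives structurally
    removed) within all four windows, ordered by z-normalized Euclidean
    property distance with lexicographic-id tie-breaking; selection is
    greedy without replacement, round-robin over actives in input order.
    Deterministic for fixed inputs and config. When the pool runs out the
    DecoySet carries a shortfall warning instead of raising.
    """
    config = config or MatchingConfig()
    if not actives:
        raise ValueError("no_actives")

    active_structs = {canonical_smiles(a.smiles) for a in actives}
    active_structs.discard(None)
    candidates = [p for p in pool if canonical_smiles(p.smiles) not in active_structs]

    target = math.ceil(config.decoys_per_active * len(actives))
    if not candidates:
        return DecoySet(list(actives), [], [], config, target, shortfall=target)

    pool_props = _props_matrix(candidates)
    active_props = _props_matrix(actives)
    # z-normalization over the (exclusion-filtered) pool; constant columns get unit scale
    scale = pool_props.std(axis=0)
    scale[scale == 0] = 1.0

    windows = np.asarray(config.windows())
    # per-active candidate queues, closest first, id as deterministic tie-break
    queues: list[list[int]] = []
    for a_idx in range(len(actives)):
        deltas = np.abs(pool_props - active_props[a_idx])
        inside = np.all(deltas <= windows, axis=1)
        idxs = np.flatnonzero(inside)
        dists = np.linalg.norm(deltas[idxs] / scale, axis=1)
        order = sorted(range(len(idxs)), key=lambda k: (dists[k], candidates[idxs[k]].id))
        queues.append([int(idxs[k]) for k in order])

    chosen: list[tuple[int, int]] = []  # (pool index, active index)
    used: set[int] = set()
    cursors = [0] * len(actives)
    live = set(range(len(actives)))
    while len(chosen) < target and live:
        for a_idx in list(range(len(actives))):
            if a_idx not in live or len(chosen) >= target:
                continue
            q, c = queues[a_idx], cursors[a_idx]
            while c < len(q) and q[c] in used:
                c += 1
            cursors[a_idx] = c
            if c >= len(q):
                live.discard(a_idx)
                continue
            used.add(q[c])
            chosen.append((q[c], a_idx))
            cursors[a_idx] = c + 1

    decoys: list[MoleculeRecord] = []
    provenance: list[DecoyProvenance] = []
    for p_idx, a_idx in chosen:
        rec = candidates[p_idx]
        decoys.append(MoleculeRecord(id=rec.id, smiles=rec.smiles, role="decoy", props=rec.props))
        d = pool_props[p_idx] - active_props[a_idx]
        provenance.append(
            DecoyProvenance(
                decoy_id=rec.id,
                active_id=actives[a_idx].id,
                d_mw=float(d[0]),
                d_logp=float(d[1]),
                d_hbd=int(round(d[2])),
                d_hba=int(round(d[3])),
            )
        )
    return DecoySet(
        actives=list(actives),
        decoys=decoys,
        provenance=provenance,
        config=config,
        target_count=target,
        shortfall=target - len(decoys),
    )


def audit_decoy_set(ds: DecoySet) -> dict:
    """Quantify how similar actives and decoys are on the four descriptors.

    Returns per-property means/SDs for both sets, the per-property maximum
    absolute matching delta, the active/decoy structural overlap count
    (always expected 0) and the raw counts.
    """
    report: dict = {
        "n_actives": len(ds.actives),
        "n_decoys": len(ds.decoys),
        "target_count": ds.target_count,
        "shortfall": ds.shortfall,
        "properties": {},
    }
    a_structs = {canonical_smiles(a.smiles) for a in ds.actives}
    report["overlap_with_actives"] = sum(
        1 for d in ds.decoys if canonical_smiles(d.smiles) in a_structs
    )
    if ds.decoys:
        ap = _props_matrix(ds.actives)
        dp = _props_matrix(ds.decoys)
        deltas = np.asarray(
            [[p.d_mw, p.d_logp, p.d_hbd, p.d_hba] for p in ds.provenance], dtype=float
        )
        for j, name in enumerate(PROPERTY_NAMES):
            report["properties"][name] = {
                "active_mean": float(ap[:, j].mean()),
                "active_sd": float(ap[:, j].std()),
                "decoy_mean": float(dp[:, j].mean()),
                "decoy_sd": float(dp[:, j].std()),
                "mean_difference": float(dp[:, j].mean() - ap[:, j].mean()),
                "max_abs_delta": float(np.abs(deltas[:, j]).max()),
            }
    return report


def write_provenance(ds: DecoySet, path: str | Path) -> None:
    """Provenance CSV ``decoy_id,active_id,d_mw,d_logp,d_hbd,d_hba``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["decoy_id", "active_id", "d_mw", "d_logp", "d_hbd", "d_hba"])
        for p in ds.provenance:
            writer.writerow([p.decoy_id, p.active_id, f"{p.d_mw:.3f}", f"{p.d_logp:.4f}", p.d_hbd, p.d_hba])


def serialize(ds: DecoySet) -> str:
    """Canonical JSON serialization, used for byte-level determinism checks."""
    payload = {
        "config": {
            "window_mw": ds.config.window_mw,
            "window_logp": ds.config.window_logp,
            "window_hbd": ds.config.window_hbd,
            "window_hba": ds.config.window_hba,
            "decoys_per_active": ds.config.decoys_per_active,
            "seed": ds.config.seed,
        },
        "actives": [a.id for a in ds.actives],
        "decoys": [[d.id, d.smiles] for d in ds.decoys],
        "provenance": [
            [p.decoy_id, p.active_id, round(p.d_mw, 6), round(p.d_logp, 6), p.d_hbd, p.d_hba]
            for p in ds.provenance
        ],
        "shortfall": ds.shortfall,
    }
    return json.dumps(payload, sort_keys=True)
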