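"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of (config, seed):

* :func:`gen_score_list` — equal-variance binormal score lists with a known
  closed-form expected AUC, Phi((mu_a - mu_d)/(sigma*sqrt(2)));
* :func:`gen_compound_pool` — property-realistic compound records with
  drug-like marginals and parseable template SMILES;
* :func:`gen_feature_cloud` — jittered, rigidly moved copies of a
  pharmacophore model's feature centers (optionally kind-mutated so that
  complete mapping fails at small jitter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .chem_props import MoleculeRecord, PropertyVector
from .pharmacophore import FeatureCloud, PharmacophoreModel
from .screen_eval import LABEL_ACTIVE, LABEL_DECOY, RankedEntry

# Curated drug-like template bank, sampled with replacement so that every
# generated record round-trips through parsing/standardization. Property
# vectors are simulated from the configured distributions, not recomputed
# from these structures.
SMILES_TEMPLATES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",           # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",      # ibuprofen
    "CN1CCC[C@H]1c1cccnc1",            # nicotine
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",      # caffeine
    "NCC(=O)O",                        # glycine
    "CC(N)Cc1ccccc1",                  # amphetamine
    "Oc1ccc(cc1)CCN",                  # tyramine-like
    "COc1ccc(cc1)CCN",                 # methoxyphenethylamine
    "CC(=O)Nc1ccc(O)cc1",              # paracetamol
    "Clc1ccccc1-c1ccccc1",             # chlorobiphenyl
    "c1ccc2ccccc2c1",                  # naphthalene
    "OCC1OC(O)C(O)C(O)C1O",            # pyranose
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",      # procainamide
    "CC(C)NCC(O)COc1ccccc1",           # propranolol-like fragment
    "O=C(O)c1ccccc1O",                 # salicylic acid
    "NC(=O)c1ccccc1",                  # benzamide
    "CCOC(=O)c1ccccc1N",               # benzocaine-like
    "CN(C)CCc1ccccc1",                 # dimethylphenethylamine
    "OC(=O)CCc1ccccc1",                # hydrocinnamic acid
    "Cc1ccc(C)cc1",                    # xylene
    "CCCCCCCCC(=O)O",                  # nonanoic acid
    "OCCN1CCN(CCO)CC1",                # piperazine diol
    "c1ccc(cc1)C(=O)Nc1ccccc1",        # benzanilide
    "CC1CCC(CC1)C(C)C",                # menthane
    "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",  # catechin core
    "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21",      # benzodiazepine core
    "COc1cc2c(cc1OC)CCN(C)C2",         # tetrahydroisoquinoline
    "CC(C)(C)NCC(O)c1ccc(O)c(O)c1",    # catecholamine-like
    "O=C1CCCCC1",                      # cyclohexanone
    "N#Cc1ccccc1",                     # benzonitrile
    "OC(=O)C1CCCN1",                   # proline
    "CSCCC(N)C(=O)O",                  # methionine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",     # tryptophan
    "OCc1ccccc1",                      # benzyl alcohol
    "CC(=O)c1ccccc1",                  # acetophenone
    "CCOc1ccc(cc1)NC(C)=O",            # phenacetin
    "Nc1ccc(cc1)S(N)(=O)=O",           # sulfanilamide
    "OC(c1ccccc1)c1ccccc1",            # benzhydrol
    "CC(C)=CCCC(C)=CCO",               # geraniol
    "O=C(Nc1ccccc1)c1cccnc1",          # nicotinanilide
)


@dataclass(frozen=True)
class ScoreSimConfig:
    """Equal-variance binormal score model for active vs decoy fit values."""

    n_active: int
    n_decoy: int
    mu_active: float = 1.0
    mu_decoy: float = 0.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_decoy < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def expected_auc(self) -> float:
        """Closed-form binormal AUC: Phi((mu_a - mu_d)/(sigma*sqrt(2)))."""
        return float(norm.cdf((self.mu_active - self.mu_decoy) / (self.sigma * math.sqrt(2))))


def separation_for_auc(auc: float, sigma: float = 1.0) -> float:
    """Score-mean separation whose binormal expected AUC equals ``auc``."""
    if not 0 < auc < 1:
        raise ValueError("auc must lie in (0,1)")
    return float(norm.ppf(auc) * sigma * math.sqrt(2))


def gen_score_list(cfg: ScoreSimConfig) -> list[RankedEntry]:
    """Simulated score table with known active/decoy separability."""
    rng = np.random.default_rng(cfg.seed)
    a = rng.normal(cfg.mu_active, cfg.sigma, cfg.n_active)
    d = rng.normal(cfg.mu_decoy, cfg.sigma, cfg.n_decoy)
    entries = [
        RankedEntry(id=f"act{i + 1}", score=float(s), label=LABEL_ACTIVE) for i, s in enumerate(a)
    ]
    entries += [
        RankedEntry(id=f"dec{i + 1}", score=float(s), label=LABEL_DECOY) for i, s in enumerate(d)
    ]
    return entries


@dataclass(frozen=True)
class PoolSimConfig:
    """Drug-like property marginals for a simulated compound pool.

    Defaults: mw ~ N(350, 80) Da truncated at 60, logp ~ N(2.5, 1.5),
    hbd categorical on 0..5, hba categorical on 0..10; properties drawn
    independently (real libraries correlate them — see the methods note).
    """

    n: int
    mw_mean: float = 350.0
    mw_sd: float = 80.0
    logp_mean: float = 2.5
    logp_sd: float = 1.5
    hbd_probs: tuple[float, ...] = (0.15, 0.30, 0.25, 0.15, 0.10, 0.05)
    hba_probs: tuple[float, ...] = (0.04, 0.08, 0.14, 0.18, 0.18, 0.14, 0.10, 0.06, 0.04, 0.02, 0.02)
    active_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.mw_sd <= 0 or self.logp_sd <= 0:
            raise ValueError("SDs must be positive")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must lie in [0,1]")


def gen_compound_pool(cfg: PoolSimConfig) -> list[MoleculeRecord]:
    """Simulated compound records with property vectors attached.

    The first round(active_fraction * n) records are flagged ``active``;
    SMILES are sampled from the curated template bank so downstream parsing
    works; molecular weight is truncated below at 60 Da.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.n == 0:
        return []
    mw = np.maximum(rng.normal(cfg.mw_mean, cfg.mw_sd, cfg.n), 60.0)
    logp = rng.normal(cfg.logp_mean, cfg.logp_sd, cfg.n)
    hbd_p = np.asarray(cfg.hbd_probs) / sum(cfg.hbd_probs)
    hba_p = np.asarray(cfg.hba_probs) / sum(cfg.hba_probs)
    hbd = rng.choice(len(hbd_p), size=cfg.n, p=hbd_p)
    hba = rng.choice(len(hba_p), size=cfg.n, p=hba_p)
    smiles = rng.choice(np.asarray(SMILES_TEMPLATES, dtype=object), size=cfg.n)
    n_active = int(round(cfg.active_fraction * cfg.n))
    records = []
    for i in range(cfg.n):
        role = "active" if i < n_active else "pool"
        records.append(
            MoleculeRecord(
                id=f"{'act' if role == 'active' else 'cmpd'}{i + 1}",
                smiles=str(smiles[i]),
                role=role,
                props=PropertyVector(mw=float(mw[i]), logp=float(logp[i]), hbd=int(hbd[i]), hba=int(hba[i])),
            )
        )
    return records


def gen_model(
    composition: str = "HDAA",
    seed: int = 0,
    tolerance: float = 1.6,
    weight: float = 1.0,
    name: str | None = None,
) -> PharmacophoreModel:
    """Synthetic pharmacophore model with a given kind composition.

    The published models are characterized only by their feature-kind
    compositions (e.g. HDAA: one hydrophobe, one donor, two acceptors);
    their geometry is unpublished, so centers are drawn uniformly in an
    8 A cube with >= 3 A pairwise separation.
    """
    from .pharmacophore import PharmacophoreFeature

    for k in composition:
        if k not in ("H", "D", "A", "R"):
            raise ValueError(f"unknown feature kind {k!r} in composition")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    while len(centers) < len(composition):
        c = rng.uniform(-4.0, 4.0, size=3)
        if all(np.linalg.norm(c - o) >= 3.0 for o in centers):
            centers.append(c)
    features = [
        PharmacophoreFeature(kind=k, center=tuple(float(x) for x in centers[i]),
                             tolerance=tolerance, weight=weight)
        for i, k in enumerate(composition)
    ]
    return PharmacophoreModel(name=name or f"synthetic-{composition}", features=features)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform proper rotation via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_feature_cloud(
    model: PharmacophoreModel,
    jitter_sigma: float = 0.0,
    decoy_kind_swap: bool = False,
    seed: int = 0,
    mol_id: str = "sim",
) -> FeatureCloud:
    """Model centers + isotropic Gaussian jitter + a random rigid motion.

    With ``decoy_kind_swap`` one feature's kind is mutated to a different
    kind, so complete ("no omitted features") mapping fails at small jitter.
    """
    rng = np.random.default_rng(seed)
    coords = model.centers + rng.normal(0.0, jitter_sigma, size=(len(model.features), 3)) if jitter_sigma > 0 else model.centers.copy()
    R = _random_rotation(rng)
    t = rng.uniform(-10.0, 10.0, size=3)
    coords = coords @ R.T + t
    kinds = [f.kind for f in model.features]
    if decoy_kind_swap:
        i = int(rng.integers(len(kinds)))
        others = [k for k in ("H", "D", "A", "R") if k != kinds[i]]
        kinds[i] = others[int(rng.integers(len(others)))]
    return FeatureCloud(mol_id=mol_id, points=[(k, coords[j]) for j, k in enumerate(kinds)], conf_id=0)


def gen_cloud_library(
    model: PharmacophoreModel,
    n_active: int,
    n_decoy: int,
    jitter_active: float = 0.2,
    jitter_decoy: float = 1.5,
    seed: int = 0,
) -> tuple[dict[str, list[FeatureCloud]], dict[str, str]]:
    """Planted-separation screening fixture: actives are lightly jittered
    copies of the model, decoys heavily jittered ones."""
    rng = np.random.default_rng(seed)
    clouds: dict[str, list[FeatureCloud]] = {}
    labels: dict[str, str] = {}
    for i in range(n_active):
        mid = f"act{i + 1}"
        clouds[mid] = [gen_feature_cloud(model, jitter_active, seed=int(rng.integers(2**31)), mol_id=mid)]
        labels[mid] = LABEL_ACTIVE
    for i in range(n_decoy):
        mid = f"dec{i + 1}"
        clouds[mid] = [gen_feature_cloud(model, jitter_decoy, seed=int(rng.integers(2**31)), mol_id=mid)]
        labels[mid] = LABEL_DECOY
    return clouds, labels
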