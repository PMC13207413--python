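"""End-to-end orchestration: standardize -> decoys -> score -> evaluate.

Two scoring modes mirror the two ways a validation screen is produced:
an external score table (``scores`` mode, when a screening engine already
ranked the library) or the built-in pharmacophore fit scorer applied to a
model plus feature-cloud library (``pharmacophore`` mode). The run writes
every intermediate artifact plus a deterministic report JSON (config hash
included, no timestamps) and a stage-granular run log with record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path
from typing import Sequence

from . import chem_props, decoy_builder, pharmacophore, screen_eval

logger = logging.getLogger("screenvalid")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str
    actives_path: str | None = None
    pool_path: str | None = None
    scores_path: str | None = None
    model_path: str | None = None
    library_path: str | None = None  # cloud CSV or SDF with 3D coordinates
    labels_path: str | None = None   # CSV id,label (needed for pharmacophore mode)
    matching: decoy_builder.MatchingConfig = field(default_factory=decoy_builder.MatchingConfig)
    fractions: tuple[float, ...] = (0.01, 0.05, 0.10)
    alpha: float = 20.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        matching = decoy_builder.MatchingConfig(**doc.get("matching", {}))
        return cls(
            out_dir=doc.get("out_dir", "screenvalid_out"),
            actives_path=doc.get("actives"),
            pool_path=doc.get("pool"),
            scores_path=doc.get("scores"),
            model_path=doc.get("model"),
            library_path=doc.get("library"),
            labels_path=doc.get("labels"),
            matching=matching,
            fractions=tuple(doc.get("fractions", (0.01, 0.05, 0.10))),
            alpha=float(doc.get("alpha", 20.0)),
            seed=int(doc.get("seed", 0)),
        )

    def mode(self) -> str:
        if self.scores_path:
            return "scores"
        if self.model_path and self.library_path:
            return "pharmacophore"
        raise PipelineError("config", "no_scoring_source: provide scores or model+library")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "actives": self.actives_path,
                "pool": self.pool_path,
                "scores": self.scores_path,
                "model": self.model_path,
                "library": self.library_path,
                "labels": self.labels_path,
                "matching": self.matching.__dict__,
                "fractions": list(self.fractions),
                "alpha": self.alpha,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_labels(path: str | Path) -> dict[str, str]:
    import csv

    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels[row["id"]] = row["label"].strip()
    return labels


def _curate(path: str, role: str, out_dir: Path, log: list[str]) -> list[chem_props.MoleculeRecord]:
    if path.endswith(".sdf"):
        raw = chem_props.read_sdf(path, role=role)
    else:
        raw = chem_props.read_smi(path, role=role)
    std, removed = chem_props.standardize_library(raw)
    std, failed = chem_props.annotate_properties(std)
    chem_props.write_property_table(std, out_dir / f"{role}_properties.csv")
    chem_props.write_removal_log(removed + failed, out_dir / f"{role}_removals.csv")
    log.append(f"curate[{role}]: {len(raw)} in, {len(std)} kept, {len(removed) + len(failed)} removed")
    return std


def run_pipeline(cfg: PipelineConfig) -> screen_eval.EnrichmentReport:
    """Run the configured validation analysis and write all artifacts.

    Deterministic for identical config + seed: rerunning produces a
    byte-identical report.json.
    """
    mode = cfg.mode()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = [f"mode: {mode}", f"config_hash: {cfg.config_hash()}"]

    decoy_set = None
    if cfg.actives_path and cfg.pool_path:
        try:
            actives = _curate(cfg.actives_path, "active", out_dir, stage_log)
            pool = _curate(cfg.pool_path, "pool", out_dir, stage_log)
        except (OSError, ValueError) as exc:
            raise PipelineError("curation", str(exc)) from exc
        try:
            decoy_set = decoy_builder.build_decoy_set(actives, pool, cfg.matching)
        except ValueError as exc:
            raise PipelineError("decoy_building", str(exc)) from exc
        chem_props.write_smi(decoy_set.decoys, out_dir / "decoys.smi")
        decoy_builder.write_provenance(decoy_set, out_dir / "decoy_provenance.csv")
        (out_dir / "decoy_audit.json").write_text(
            json.dumps(decoy_builder.audit_decoy_set(decoy_set), sort_keys=True, indent=2)
        )
        stage_log.append(
            f"decoys: {len(decoy_set.decoys)} selected of target {decoy_set.target_count}"
            + (f" (WARNING {decoy_set.warning})" if decoy_set.warning else "")
        )

    try:
        if mode == "scores":
            entries = screen_eval.read_scores_csv(cfg.scores_path)
            stage_log.append(f"scores: {len(entries)} entries read")
        else:
            model = pharmacophore.load_model(cfg.model_path)
            if cfg.library_path.endswith(".sdf"):
                from rdkit import Chem

                clouds = {}
                for i, mol in enumerate(Chem.SDMolSupplier(cfg.library_path, removeHs=False)):
                    if mol is None:
                        continue
                    mid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
                    cloud = pharmacophore.perceive_features(mol)
                    cloud.mol_id = mid
                    clouds.setdefault(mid, []).append(cloud)
            else:
                clouds = pharmacophore.read_cloud_csv(cfg.library_path)
            if not cfg.labels_path:
                raise PipelineError("screening", "labels CSV required in pharmacophore mode")
            labels = _read_labels(cfg.labels_path)
            screen, unmapped = pharmacophore.screen_library(clouds, model, labels)
            entries = screen.entries
            screen_eval.write_scores_csv(entries, out_dir / "scores.csv")
            stage_log.append(
                f"pharm-screen: {len(clouds)} molecules, {len(unmapped)} unmapped (sentinel-ranked)"
            )
    except PipelineError:
        raise
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("scoring", str(exc)) from exc

    try:
        screen = screen_eval.rank_screen(entries)
        report = screen_eval.evaluate_screen(screen, fractions=cfg.fractions, alpha=cfg.alpha)
    except ValueError as exc:
        raise PipelineError("evaluation", str(exc)) from exc

    payload = report.to_dict()
    payload["mode"] = mode
    payload["config_hash"] = cfg.config_hash()
    payload["package_version"] = _safe_version()
    if decoy_set is not None:
        payload["decoy_shortfall"] = decoy_set.shortfall
    (out_dir / "report.json").write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    (out_dir / "report.txt").write_text(report.format_text() + "\n")
    (out_dir / "run.log").write_text("\n".join(stage_log) + "\n")
    for line in stage_log:
        logger.info(line)
    return report


def _safe_version() -> str:
    try:
        return pkg_version("screenvalid")
    except Exception:
        return "unknown"
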