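"""End-to-end orchestration: scores -> p-values -> target matrix -> regulator
screen -> CRM calling, with a JSON manifest that records every parameter,
seed and input checksum. Rerunning the same config byte-reproduces every
TSV/BED output, and any stage can be resumed from the previous stage's file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .crm import CRMParams, call_crm, write_crm
from .discovery import ScreenConfig, run_screen, select_top_regulators, write_ranking
from .io import GeneAnnotation, PeakSet, read_gene_annotation, read_peaks
from .potential import (
    DecayParams,
    build_target_matrix,
    empirical_pvalues,
    read_target_matrix,
    score_matrix,
    write_matrix,
)
from .simulate import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Union of all stage parameters plus input/output paths."""

    annotation: str | None = None
    peaks_dir: str | None = None
    foreground: str | None = None
    evidence_dir: str | None = None
    out_dir: str = "results"
    target_cutoff: float = 0.01
    decay: DecayParams = field(default_factory=DecayParams)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    crm: CRMParams = field(default_factory=CRMParams)
    sim: SimConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "annotation": self.annotation,
            "peaks_dir": self.peaks_dir,
            "foreground": self.foreground,
            "evidence_dir": self.evidence_dir,
            "out_dir": self.out_dir,
            "target_cutoff": self.target_cutoff,
            "decay": dataclasses.asdict(self.decay),
            "screen": dataclasses.asdict(self.screen),
            "crm": dataclasses.asdict(self.crm),
        }
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["planted_tfs"] = list(self.sim.planted_tfs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "decay" in kwargs:
            kwargs["decay"] = DecayParams(**kwargs["decay"])
        if "screen" in kwargs:
            kwargs["screen"] = ScreenConfig(**kwargs["screen"])
        if "crm" in kwargs:
            kwargs["crm"] = CRMParams(**kwargs["crm"])
        if kwargs.get("sim") is not None:
            sim = dict(kwargs["sim"])
            sim["planted_tfs"] = tuple(sim.get("planted_tfs", ()))
            kwargs["sim"] = SimConfig(**sim)
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or TOML, selected by extension."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    elif path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        raise ValueError(f"config must be .yaml/.yml or .toml, got {path.suffix}")
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_foreground(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def read_peaks_dir(peaks_dir: str | Path) -> list[PeakSet]:
    """One PeakSet per *.bed file, named by file stem, in sorted file order."""
    files = sorted(Path(peaks_dir).glob("*.bed"))
    if not files:
        raise FileNotFoundError(f"no .bed files in {peaks_dir}")
    return [read_peaks(f, tf_name=f.stem) for f in files]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage in order and return the paths of the written outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("read inputs")
        if config.annotation is None or config.peaks_dir is None or config.foreground is None:
            raise ValueError("annotation, peaks_dir and foreground are required")
        annotation = read_gene_annotation(config.annotation)
        inputs[str(config.annotation)] = _sha256(Path(config.annotation))
        peaksets = read_peaks_dir(config.peaks_dir)
        for f in sorted(Path(config.peaks_dir).glob("*.bed")):
            inputs[str(f)] = _sha256(f)
        foreground = read_foreground(config.foreground)
        inputs[str(config.foreground)] = _sha256(Path(config.foreground))
        evidence = None
        if config.evidence_dir is not None:
            evidence = read_peaks_dir(config.evidence_dir)
            for f in sorted(Path(config.evidence_dir).glob("*.bed")):
                inputs[str(f)] = _sha256(f)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'read inputs': {e}") from e

    paths: dict[str, Path] = {}
    try:
        _stage("regulatory potential scores")
        scores = score_matrix(annotation, peaksets, config.decay)
        paths["scores"] = out / "scores.tsv"
        write_matrix(scores, paths["scores"])

        _stage("empirical p-values")
        pvals = empirical_pvalues(scores)
        paths["pvalues"] = out / "pvalues.tsv"
        write_matrix(pvals, paths["pvalues"])

        _stage("target matrix")
        targets = build_target_matrix(pvals, config.target_cutoff)
        paths["targets"] = out / "targets.tsv"
        write_matrix(targets.values, paths["targets"], cutoff=targets.cutoff)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'scoring': {e}") from e

    try:
        _stage("regulator screen")
        ranking = run_screen(targets, annotation, foreground, config.screen)
        paths["ranking"] = out / "ranking.tsv"
        write_ranking(ranking, paths["ranking"])
        selected = select_top_regulators(ranking, config.screen.q_cutoff)
        logger.info("selected top regulators: %s", selected or "(none)")
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'screen': {e}") from e

    try:
        _stage("CRM calling")
        top_peaks = [ps for ps in peaksets if ps.tf_name in set(selected)]
        candidates = (
            call_crm(foreground, annotation, top_peaks, evidence, config.crm)
            if top_peaks
            else []
        )
        paths["crm_bed"] = out / "crm.bed"
        paths["crm_tsv"] = out / "crm_details.tsv"
        write_crm(candidates, paths["crm_bed"], paths["crm_tsv"], config.crm)
        logger.info("called %d CRM candidates", len(candidates))
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage 'crm': {e}") from e

    manifest = {
        "package": "crmscreen",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.screen.seed,
        "inputs_sha256": inputs,
        "outputs": {k: str(v) for k, v in sorted(paths.items())},
        "selected_regulators": selected,
        "n_crm": len(candidates),
    }
    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def config_from_manifest(path: str | Path) -> PipelineConfig:
    """Reconstruct the run's config from its manifest (round-trip property)."""
    with open(path) as fh:
        manifest = json.load(fh)
    return PipelineConfig.from_dict(manifest["config"])


def screen_from_target_file(
    targets_path: str | Path,
    annotation: GeneAnnotation,
    foreground: list[str],
    config: ScreenConfig,
):
    """Resume the screen from a saved target matrix; equals end-to-end exactly."""
    targets = read_target_matrix(targets_path)
    return run_screen(targets, annotation, foreground, config)
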