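"""Configured, logged, reproducible orchestration: simulate -> QC -> analyses.

``run_pipeline`` produces, per design x stage: a QC report, the positional
preference matrix, the second-codon table (downstream design only), the 6-mer
table with KPM/KPM_relative and its grid (TSV + heat map), the SD analyses
(upstream designs), and the construct-level MFE summary.  All TSV floats are
written with 6 significant digits so repeated runs with the same seed are
bitwise identical; every output file is recorded in a JSON run manifest with
a SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .designs import (
    DESIGNS,
    LibraryDesign,
    ReadSet,
    get_design,
    qc_filter,
    read_sequences,
    QCReport,
)
from .folding import InternalFold, ViennaFold, mfe_summary
from .kmers import all_kmers, count_kmers, kmer_grid, kpm_normalize, kpm_relative, render_grid
from .positional import relative_positional_preference, second_codon_table, group_means
from .sd import (
    ANTI_SD_TARGET,
    all_6mer_duplex_energies,
    antisd_windows,
    duplex_energy,
    energy_preference_r2,
    motif_fraction,
    motif_start_profile,
    relative_preference,
)
from .simulate import (
    DEFAULT_N_CONTROL,
    DEFAULT_N_SELECTED,
    SelectionModel,
    make_control_library,
    select_reads,
)
from .thermo import RNA_BASES

__all__ = ["PipelineConfig", "ConfigError", "RunManifest", "validate_config", "run_pipeline"]

logger = logging.getLogger("riboselect")

_FLOAT_FMT = "%.6g"

_KNOWN_KEYS = {
    "designs",
    "stages",
    "k",
    "motif",
    "anti_sd_target",
    "seed",
    "outdir",
    "simulate",
    "inputs",
    "qc",
    "folding",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message lists offending keys."""


@dataclass
class PipelineConfig:
    designs: list[str] = field(default_factory=lambda: ["N20U"])
    stages: list[str] = field(default_factory=lambda: ["30S", "30SIC", "70SIC"])
    k: int = 6
    motif: str = "AGGAGG"
    anti_sd_target: str = ANTI_SD_TARGET
    seed: int = 1
    outdir: str = "riboselect_out"
    n_control: int = DEFAULT_N_CONTROL
    n_selected: int = DEFAULT_N_SELECTED
    inputs: dict[str, dict[str, str]] = field(default_factory=dict)
    min_mean_quality: float = 20.0
    rrna_reference: str = ""
    contaminant_kmer_len: int = 20
    max_flank_mismatch: int = 0
    folding_engine: str = "internal"
    bin_width: float = 1.0


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Load and normalize a YAML/JSON config; fill defaults, cross-check keys."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, dict) or not doc:
        raise ConfigError("empty or non-mapping configuration document")
    unknown = set(doc) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = PipelineConfig()
    cfg.designs = list(doc.get("designs", cfg.designs))
    cfg.stages = list(doc.get("stages", cfg.stages))
    cfg.k = int(doc.get("k", cfg.k))
    cfg.motif = str(doc.get("motif", cfg.motif)).upper().replace("T", "U")
    cfg.anti_sd_target = str(doc.get("anti_sd_target", cfg.anti_sd_target)).upper().replace("T", "U")
    cfg.seed = int(doc.get("seed", cfg.seed))
    cfg.outdir = str(doc.get("outdir", cfg.outdir))
    sim = doc.get("simulate", {}) or {}
    cfg.n_control = int(sim.get("n_control", cfg.n_control))
    cfg.n_selected = int(sim.get("n_selected", cfg.n_selected))
    cfg.inputs = doc.get("inputs", {}) or {}
    qc = doc.get("qc", {}) or {}
    cfg.min_mean_quality = float(qc.get("min_mean_quality", cfg.min_mean_quality))
    cfg.rrna_reference = str(qc.get("rrna_reference", cfg.rrna_reference))
    cfg.contaminant_kmer_len = int(qc.get("contaminant_kmer_len", cfg.contaminant_kmer_len))
    cfg.max_flank_mismatch = int(qc.get("max_flank_mismatch", cfg.max_flank_mismatch))
    fold = doc.get("folding", {}) or {}
    cfg.folding_engine = str(fold.get("engine", cfg.folding_engine))
    cfg.bin_width = float(fold.get("bin_width", cfg.bin_width))

    errors = []
    for d in cfg.designs:
        if d not in DESIGNS:
            errors.append(f"unknown design {d!r}")
    for s in cfg.stages:
        if s not in ("30S", "30SIC", "70SIC"):
            errors.append(f"unknown stage {s!r}")
    if cfg.k <= 0:
        errors.append("k must be positive")
    if set(cfg.motif) - set(RNA_BASES):
        errors.append(f"motif {cfg.motif!r} has invalid alphabet")
    if set(cfg.anti_sd_target) - set(RNA_BASES):
        errors.append(f"anti_sd_target {cfg.anti_sd_target!r} has invalid alphabet")
    if cfg.folding_engine not in ("internal", "vienna"):
        errors.append(f"unknown folding engine {cfg.folding_engine!r}")
    for d, stages in cfg.inputs.items():
        if d not in DESIGNS:
            errors.append(f"inputs reference unknown design {d!r}")
        for stage, path in stages.items():
            if not Path(path).exists():
                errors.append(f"missing input file for {d}/{stage}: {path}")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


@dataclass
class RunManifest:
    config: dict[str, Any]
    package_version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: dict[str, str] = field(default_factory=dict)  # relpath -> sha256
    warnings: list[str] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)

    def record(self, outdir: Path, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path.relative_to(outdir))] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def _load_readset(cfg: PipelineConfig, design: LibraryDesign, stage: str, path: str):
    reads = read_sequences(path)
    return qc_filter(
        reads,
        design,
        stage=stage,
        min_mean_quality=cfg.min_mean_quality,
        rrna_reference=cfg.rrna_reference,
        contaminant_kmer_len=cfg.contaminant_kmer_len,
        max_flank_mismatch=cfg.max_flank_mismatch,
    )


def _get_stage_readsets(
    cfg: PipelineConfig, design: LibraryDesign, engine
) -> tuple[dict[str, ReadSet], dict[str, QCReport]]:
    """Control + per-stage ReadSets, either loaded+QC'd or simulated."""
    readsets: dict[str, ReadSet] = {}
    reports: dict[str, QCReport] = {}
    paths = cfg.inputs.get(design.name, {})
    if "control" in paths:
        readsets["control"], reports["control"] = _load_readset(
            cfg, design, "control", paths["control"]
        )
    else:
        readsets["control"] = make_control_library(design, cfg.n_control, cfg.seed)
        reports["control"] = QCReport(n_input=cfg.n_control, passed=cfg.n_control)
    for stage in cfg.stages:
        if stage in paths:
            readsets[stage], reports[stage] = _load_readset(cfg, design, stage, paths[stage])
        else:
            model = SelectionModel.preset(stage)
            if cfg.anti_sd_target != model.anti_sd:
                model = SelectionModel(**{**asdict(model), "anti_sd": cfg.anti_sd_target})
            stage_offset = {"30S": 101, "30SIC": 102, "70SIC": 103}[stage]
            readsets[stage] = select_reads(
                readsets["control"],
                model,
                cfg.n_selected,
                seed=cfg.seed + stage_offset,
                engine=engine,
                design=design,
            )
            reports[stage] = QCReport(n_input=cfg.n_selected, passed=cfg.n_selected)
        logger.info(
            "%s/%s: %d reads (%d unique)",
            design.name,
            stage,
            readsets[stage].n_total,
            readsets[stage].n_unique,
        )
    return readsets, reports


def run_pipeline(config: PipelineConfig | str | Path | dict) -> RunManifest:
    """Run all analyses for every configured design x stage; write the manifest."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg), started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    engine = ViennaFold() if cfg.folding_engine == "vienna" else InternalFold()

    for dname in cfg.designs:
        design = get_design(dname)
        readsets, reports = _get_stage_readsets(cfg, design, engine)
        control = readsets["control"]
        ctrl_table = kpm_normalize(count_kmers(control, cfg.k))
        ddir = outdir / dname
        upstream = design.window[1] < 0

        for stage in ["control", *cfg.stages]:
            rs = readsets[stage]
            sdir = ddir / stage
            sdir.mkdir(parents=True, exist_ok=True)
            reports[stage].to_tsv(sdir / "qc_report.tsv")
            manifest.counters[f"{dname}/{stage}/reads"] = rs.n_total
            if rs.n_total == 0:
                manifest.warnings.append(f"{dname}/{stage}: empty ReadSet, analyses skipped")
                manifest.record(outdir, sdir / "qc_report.tsv")
                continue

            if stage != "control":
                # Fig 1 analogue: positional base preference vs control
                pref = relative_positional_preference(rs, control, design)
                df = pref.to_frame()
                df.insert(0, "base", df.index)
                _write_tsv(df, sdir / "positional_preference.tsv")

                # Fig 2 analogue: second-codon table (downstream design only)
                if design.window[0] == 4:
                    codons = second_codon_table(rs, control)
                    _write_tsv(codons.reset_index(), sdir / "codon_table.tsv")
                    gm = group_means(codons).rename("group_mean").reset_index(names="first_base")
                    _write_tsv(gm, sdir / "codon_group_means.tsv")

                # Fig 3 analogue: 6-mer table + grid
                table = kpm_normalize(count_kmers(rs, cfg.k))
                rel = kpm_relative(table, ctrl_table)
                _write_tsv(table.to_frame(rel.values), sdir / "kmer_table.tsv")
                grid = kmer_grid(rel.values, cfg.k)
                _write_tsv(grid.to_frame(), sdir / "kmer_grid.tsv")
                render_grid(grid, sdir / "kmer_grid.png", title=f"{dname} {stage}")

                # Fig 4 analogue: SD analyses for upstream designs
                if upstream and cfg.k == 6:
                    frac = motif_fraction(rs, cfg.motif)
                    _write_tsv(
                        pd.DataFrame(
                            {"stage": [stage], "motif": [cfg.motif], "fraction": [frac]}
                        ),
                        sdir / "motif_fraction.tsv",
                    )
                    if design.random_len >= len(cfg.motif):
                        profile = motif_start_profile(rs, design, cfg.motif)
                        _write_tsv(profile.to_frame(), sdir / "motif_profile.tsv")
                    windows = antisd_windows(cfg.anti_sd_target)
                    wdf = pd.DataFrame(
                        {
                            "position_n": [w.position_n for w in windows],
                            "window_seq": [w.window_seq for w in windows],
                            "mrna_6mer": [w.mrna_6mer for w in windows],
                            "duplex_energy": [
                                duplex_energy(w.mrna_6mer, cfg.anti_sd_target) for w in windows
                            ],
                            "kpm_relative": [rel[w.mrna_6mer] for w in windows],
                            "relative_preference_pct": [
                                relative_preference(w.mrna_6mer, rel) for w in windows
                            ],
                        }
                    )
                    _write_tsv(wdf, sdir / "antisd_windows.tsv")
                    r2 = energy_preference_r2(
                        rel.values, all_6mer_duplex_energies(cfg.anti_sd_target)
                    )
                    _write_tsv(
                        pd.DataFrame({"stage": [stage], "energy_preference_r2": [r2]}),
                        sdir / "energy_preference_r2.tsv",
                    )

            # Fig 5 analogue: construct MFE summary (all stages incl. control)
            summary = mfe_summary(rs, design, engine=engine, bin_width=cfg.bin_width)
            _write_tsv(summary.to_frame(), sdir / "mfe_values.tsv")
            _write_tsv(
                pd.DataFrame(
                    {
                        "stage": [stage],
                        "engine": [summary.engine],
                        "n": [summary.n],
                        "mean_mfe": [summary.mean],
                        "sd_mfe": [summary.sd],
                    }
                ),
                sdir / "mfe_summary.tsv",
            )
            hist = pd.DataFrame(
                {
                    "bin_left": summary.hist_edges[:-1],
                    "bin_right": summary.hist_edges[1:],
                    "count": summary.hist_counts,
                }
            )
            _write_tsv(hist, sdir / "mfe_histogram.tsv")

            for f in sorted(sdir.iterdir()):
                manifest.record(outdir, f)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    return manifest
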