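"""End-to-end pipeline orchestration from a single config mapping.

Stages (any subset, executed in dependency order):

``simulate``      generate synthetic inputs with ground truth
``mid_correct``   natural-abundance correction of isotopologue spectra
``flux``          bioenergetic metrics from flux traces
``signature``     normalization, signature scores, group comparison
``cytokine``      4PL calibration, interpolation, cell-number correction

Outputs are plain-text tables prefixed with a header line recording the tool
version and a checksum of the config, so re-running with identical config and
seeds yields byte-identical files.  A machine-readable run report (inputs,
seeds, per-output checksums) is written last.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, elisa, flux as flux_mod, io as io_mod, isotopes, signature as sig_mod
from . import simulate as sim_mod

logger = logging.getLogger("immetab")

STAGE_ORDER = ["simulate", "mid_correct", "flux", "signature", "cytokine"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def config_checksum(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header(checksum: str) -> str:
    return f"# immetab {__version__} config_sha256={checksum}\n"


def _write_table(df: pd.DataFrame, path: Path, checksum: str, index: bool = False, sep: str = "\t") -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    body = df.to_csv(sep=sep, index=index, float_format=io_mod.FLOAT_FORMAT, lineterminator="\n")
    path.write_text(_header(checksum) + body)


def _require_path(config: dict, key: str, stage: str) -> Path:
    if key not in config:
        raise StageError(stage, KeyError(f"config key {key!r} required"))
    p = Path(config[key])
    if not p.exists():
        raise StageError(stage, FileNotFoundError(f"input path {p} does not exist"))
    return p


def _stage_simulate(config: dict, out: Path, checksum: str, seed: int) -> dict[str, Path]:
    cfg = config.get("simulate", {})
    outputs: dict[str, Path] = {}
    sim_dir = out / "simulated"

    tracer = sim_mod.TracerScenario(seed=seed, **cfg.get("tracer", {}))
    spectra, truth = sim_mod.gen_isotopologue_spectra(
        tracer, n_samples=cfg.get("tracer_samples", 6)
    )
    outputs["spectra"] = sim_dir / "spectra.tsv"
    outputs["spectra_truth"] = sim_dir / "spectra.tsv.truth.tsv"
    _write_table(spectra, outputs["spectra"], checksum)
    _write_table(truth, outputs["spectra_truth"], checksum)

    flux_cfg = cfg.get("flux", {})
    n_wells = cfg.get("flux_wells", 4)
    traces = []
    truths = []
    for w in range(n_wells):
        scen = sim_mod.FluxScenario(well=f"W{w + 1}", seed=seed + 1000 + w, **flux_cfg)
        trace, ftruth = sim_mod.gen_flux_trace(scen)
        traces.append(trace)
        ftruth.insert(0, "well", scen.well)
        truths.append(ftruth)
    outputs["flux_trace"] = sim_dir / "flux_trace.tsv"
    outputs["flux_truth"] = sim_dir / "flux_trace.tsv.truth.tsv"
    _write_table(pd.concat(traces, ignore_index=True), outputs["flux_trace"], checksum)
    _write_table(pd.concat(truths, ignore_index=True), outputs["flux_truth"], checksum)

    counts_scen = sim_mod.CountScenario(seed=seed + 2000, **cfg.get("counts", {}))
    matrix, groups, ctruth = sim_mod.gen_count_matrix(counts_scen)
    outputs["counts"] = sim_dir / "counts.tsv"
    outputs["groups"] = sim_dir / "groups.tsv"
    outputs["counts_truth"] = sim_dir / "counts.tsv.truth.tsv"
    outputs["signature_genes"] = sim_dir / "signature_genes.txt"
    _write_table(matrix, outputs["counts"], checksum, index=True)
    _write_table(groups.reset_index().rename(columns={"index": "sample"}), outputs["groups"], checksum)
    _write_table(ctruth, outputs["counts_truth"], checksum)
    outputs["signature_genes"].write_text(
        "\n".join(counts_scen.signature_gene_ids) + "\n"
    )

    elisa_scen = sim_mod.ElisaScenario(seed=seed + 3000, **cfg.get("elisa", {}))
    plate, etruth = sim_mod.gen_elisa_plate(elisa_scen)
    outputs["plate"] = sim_dir / "plate.csv"
    outputs["plate_truth"] = sim_dir / "plate.csv.truth.tsv"
    _write_table(plate, outputs["plate"], checksum, sep=",")
    _write_table(etruth, outputs["plate_truth"], checksum)
    return outputs


def _stage_mid_correct(config: dict, out: Path, checksum: str, inputs: dict[str, Path]) -> dict[str, Path]:
    spectra_path = Path(config.get("spectra", inputs.get("spectra", "")))
    if not spectra_path or not spectra_path.exists():
        raise FileNotFoundError(f"spectra input {spectra_path!r} does not exist")
    table = io_mod.read_spectra_tsv(spectra_path)
    formulas = dict(isotopes.FRAGMENT_FORMULAS)
    if "formula_table" in config:
        formulas.update(io_mod.read_formula_tsv(config["formula_table"]))
    abundance = (
        io_mod.read_abundance_tsv(config["abundance_table"])
        if "abundance_table" in config
        else None
    )
    carbon_only = bool(config.get("carbon_only", False))
    rows = []
    for spec in io_mod.spectra_from_table(table):
        if spec.metabolite_id not in formulas:
            raise KeyError(f"no fragment formula for metabolite {spec.metabolite_id!r}")
        formula, n_pos = formulas[spec.metabolite_id]
        K = len(spec.ion_counts) - 1
        M = isotopes.build_correction_matrix(formula, n_pos, abundance, K, carbon_only)
        mid = isotopes.correct_mid(spec, M)
        rel = isotopes.normalize_to_internal_standard(
            float(spec.ion_counts.sum()), spec.internal_standard_count
        )
        row = {"sample": spec.sample_id, "metabolite": spec.metabolite_id}
        for i, frac in enumerate(mid.fractions):
            row[f"M{i}"] = frac
        row["fractional_enrichment"] = isotopes.fractional_enrichment(mid)
        row["relative_abundance"] = rel
        row["labeled_abundance"] = isotopes.total_labeled_abundance(mid, rel)
        rows.append(row)
    result = pd.DataFrame(rows)
    out_path = out / "mids.tsv"
    _write_table(result, out_path, checksum)
    return {"mids": out_path}


def _stage_flux(config: dict, out: Path, checksum: str, inputs: dict[str, Path]) -> dict[str, Path]:
    trace_path = Path(config.get("flux_trace", inputs.get("flux_trace", "")))
    if not trace_path or not trace_path.exists():
        raise FileNotFoundError(f"flux trace input {trace_path!r} does not exist")
    table = io_mod.read_flux_tsv(trace_path)
    constants = flux_mod.AtpRateConstants(**config.get("atp_constants", {}))
    traces = flux_mod.traces_from_table(table)
    metrics = flux_mod.summarize_wells(traces, constants, window=config.get("window", 3))
    out_path = out / "flux_metrics.tsv"
    _write_table(metrics, out_path, checksum)
    return {"flux_metrics": out_path}


def _stage_signature(config: dict, out: Path, checksum: str, inputs: dict[str, Path]) -> dict[str, Path]:
    counts_path = Path(config.get("counts", inputs.get("counts", "")))
    groups_path = Path(config.get("groups", inputs.get("groups", "")))
    genes_path = Path(config.get("signature_genes", inputs.get("signature_genes", "")))
    for p, what in [(counts_path, "counts"), (groups_path, "groups"), (genes_path, "signature gene list")]:
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"{what} input {p!r} does not exist")
    counts = io_mod.read_counts_tsv(counts_path)
    groups = io_mod.read_groups_tsv(groups_path)
    signature = sig_mod.GeneSignature.from_file(genes_path, name="ifng_response")
    factors = sig_mod.size_factors(counts)
    log2 = sig_mod.log2_normalized(counts, factors, pseudocount=config.get("pseudocount", 1.0))
    scores = sig_mod.signature_score(
        log2, signature, groups, allow_missing=bool(config.get("allow_missing", False))
    )
    comparison = sig_mod.compare_groups(scores, method=config.get("test", "wilcoxon"))
    scores_path = out / "signature_scores.tsv"
    _write_table(scores.reset_index(), scores_path, checksum)
    cmp_path = out / "signature_comparison.json"
    cmp_path.write_text(json.dumps(comparison, indent=2, sort_keys=True) + "\n")
    return {"signature_scores": scores_path, "signature_comparison": cmp_path}


def _stage_cytokine(config: dict, out: Path, checksum: str, inputs: dict[str, Path]) -> dict[str, Path]:
    plate_path = Path(config.get("plate", inputs.get("plate", "")))
    if not plate_path or not plate_path.exists():
        raise FileNotFoundError(f"plate input {plate_path!r} does not exist")
    plate = io_mod.read_plate_csv(plate_path)
    standards = plate.loc[plate["role"] == "standard"]
    curve = elisa.fit_4pl(
        list(zip(standards["known_concentration"], standards["od"])),
        seed=int(config.get("fit_seed", 0)),
    )
    reference = float(config.get("reference_count", elisa.DEFAULT_REFERENCE_COUNT))
    rows = []
    for _, r in plate.loc[plate["role"] == "unknown"].iterrows():
        conc = elisa.interpolate_conc(float(r["od"]), curve)
        m = elisa.CytokineMeasurement(
            sample_id=str(r["well"]),
            cytokine=str(r.get("cytokine", "IFN-gamma")),
            concentration=conc,
            input_cell_count=float(r["input_cell_count"]),
            viability_fraction=float(r["viability_fraction"]),
        )
        corrected = elisa.correct_for_cells(m, reference)
        rows.append(
            {
                "well": m.sample_id,
                "cytokine": m.cytokine,
                "raw_concentration": conc,
                "corrected_concentration": corrected,
                "per_1e6_cells": elisa.correct_for_cells(m, 1e6),
            }
        )
    result = pd.DataFrame(rows)
    out_path = out / "cytokine_corrected.tsv"
    _write_table(result, out_path, checksum)
    return {"cytokine_corrected": out_path}


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the enabled stages and write a run report.

    ``config['stages']`` selects stages (default: all); an empty list is a
    no-op that still writes a report.  Returns the report mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGE_ORDER))
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    checksum = config_checksum(config)
    seed = int(config.get("seed", 0))
    outputs: dict[str, Path] = {}
    completed = []
    runners = {
        "simulate": lambda: _stage_simulate(config, out, checksum, seed),
        "mid_correct": lambda: _stage_mid_correct(config, out, checksum, outputs),
        "flux": lambda: _stage_flux(config, out, checksum, outputs),
        "signature": lambda: _stage_signature(config, out, checksum, outputs),
        "cytokine": lambda: _stage_cytokine(config, out, checksum, outputs),
    }
    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        logger.info("running stage %s", stage)
        try:
            outputs.update(runners[stage]())
        except StageError:
            raise
        except Exception as err:
            raise StageError(stage, err) from err
        completed.append(stage)
    report = {
        "version": __version__,
        "config_sha256": checksum,
        "seed": seed,
        "stages": completed,
        "outputs": {
            name: {
                "path": str(path.relative_to(out)),
                "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
            }
            for name, path in sorted(outputs.items())
        },
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
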