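"""End-to-end orchestration: (simulate | ingest) -> QC -> epigenotype ->
diversity -> mixed models -> correlations.

One YAML/dict config drives the whole run; identical config + seed yields
byte-identical outputs (no wall-clock timestamps are written).  Outputs per
run directory:

* ``matrices/`` -- analysis marker matrices per species (CSV)
* ``error_reports/`` -- replicate QC reports per species (JSON)
* ``diversity_table.csv`` -- population x marker-type index table
* ``model_<INDEX>.json`` + ``contrasts.csv`` -- mixed-model results
* ``correlations.csv`` -- group-wise Pearson correlations
* ``run.log`` -- per-stage locus/sample counts (audit trail for filters)
* ``manifest.json`` -- config echo, config hash, stage status, file list
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .comparative import INDEX_FAMILIES, correlate_groups, fit_index_model
from .diversity import build_diversity_table, drop_monomorphic
from .epigenotypes import extract_epigenotypes
from .marker_io import (
    BinaryMarkerMatrix,
    MarkerType,
    read_marker_matrix,
    read_msap_bundle,
    write_marker_matrix,
)
from .replicate_qc import compute_error_report, pair_replicates, qc_bundle
from .simulate import SynthConfig, simulate_dataset

__all__ = ["PipelineConfig", "PipelineStageError", "run_all"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str = "msapdiv_run"
    seed: int = 0
    min_poly: int = 2
    delete_monomorphic: bool = True
    drop_threshold: float = 0.5
    indices: tuple[str, ...] = ("PPOL", "SI", "PPRIV", "RI")
    synthetic: dict[str, Any] = field(default_factory=dict)
    #: file mode: list of {species, aflp, hpa, msp} path entries
    species_files: list[dict[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "indices" in raw:
            raw["indices"] = tuple(raw["indices"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["indices"] = list(self.indices)
        return d


def _config_hash(cfg: PipelineConfig) -> str:
    d = cfg.to_dict()
    d.pop("out_dir", None)  # hash identifies the analysis, not its location
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in fixed order and return the output manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "matrices").mkdir(exist_ok=True)
    (out / "error_reports").mkdir(exist_ok=True)
    log_lines: list[str] = [
        f"msapdiv {__version__}",
        f"seed {cfg.seed}",
        f"config_hash {_config_hash(cfg)}",
    ]
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "stages": {},
        "outputs": [],
        "complete": False,
    }

    def log(msg: str) -> None:
        log_lines.append(msg)

    def finish(stage: str, status: str) -> None:
        manifest["stages"][stage] = status

    def fail(stage: str, exc: Exception) -> PipelineStageError:
        finish(stage, f"failed: {exc}")
        _write_manifest(out, manifest, log_lines)
        return PipelineStageError(stage, str(exc))

    # -- stage 1: inputs ---------------------------------------------------
    stage = "ingest"
    try:
        if cfg.mode == "synthetic":
            synth = SynthConfig(seed=cfg.seed, **cfg.synthetic)
            data = simulate_dataset(synth)
            species_inputs = {
                name: (ds.aflp, ds.msap) for name, ds in data.items()
            }
        elif cfg.mode == "files":
            if not cfg.species_files:
                raise ValueError("file mode needs a non-empty species_files list")
            species_inputs = {}
            for entry in cfg.species_files:
                for key in ("species", "aflp", "hpa", "msp"):
                    if key not in entry:
                        raise ValueError(f"species_files entry missing '{key}': {entry}")
                for key in ("aflp", "hpa", "msp"):
                    if not Path(entry[key]).exists():
                        raise FileNotFoundError(f"{entry['species']}: missing {key} file {entry[key]}")
                aflp = read_marker_matrix(entry["aflp"], MarkerType.AFLP)
                bundle = read_msap_bundle(entry["hpa"], entry["msp"])
                species_inputs[entry["species"]] = (aflp, bundle)
        else:
            raise ValueError(f"unknown mode '{cfg.mode}'")
        for name, (aflp, bundle) in species_inputs.items():
            log(
                f"{stage} {name}: {aflp.n_samples} samples, "
                f"{aflp.n_loci} AFLP loci, {bundle.n_epiloci} epiloci"
            )
        finish(stage, "ok")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise fail(stage, exc) from exc

    # -- stage 2: replicate QC --------------------------------------------
    stage = "replicate_qc"
    try:
        qc_out: dict[str, tuple[BinaryMarkerMatrix, Any]] = {}
        for name, (aflp, bundle) in species_inputs.items():
            pairs = pair_replicates(aflp)
            if pairs:
                rep, aflp_f = compute_error_report(aflp, pairs, cfg.drop_threshold)
                reps_msap, bundle_f = qc_bundle(bundle, pairs, cfg.drop_threshold)
                report = {
                    "aflp": rep.to_dict(),
                    "msap_hpa": reps_msap["hpa"].to_dict(),
                    "msap_msp": reps_msap["msp"].to_dict(),
                }
                log(
                    f"{stage} {name}: {len(pairs)} pairs, AFLP error "
                    f"{rep.overall_error_rate:.4f} ({len(rep.dropped_loci)} loci dropped), "
                    f"MSAP error hpa {reps_msap['hpa'].overall_error_rate:.4f} / "
                    f"msp {reps_msap['msp'].overall_error_rate:.4f} "
                    f"({len(reps_msap['hpa'].dropped_loci)} epiloci dropped)"
                )
            else:
                aflp_f, bundle_f = aflp, bundle
                report = {"warning": "no technical replicates; error-rate stage skipped"}
                log(f"{stage} {name}: no replicates, skipped")
            path = out / "error_reports" / f"{name}.json"
            path.write_text(json.dumps(report, indent=2, sort_keys=True))
            manifest["outputs"].append(str(path.relative_to(out)))
            qc_out[name] = (aflp_f.analysis_subset(), bundle_f.analysis_subset())
        finish(stage, "ok")
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # -- stage 3: epigenotyping + species-level filtering ------------------
    stage = "epigenotype"
    try:
        species_matrices: dict[str, dict[str, BinaryMarkerMatrix]] = {}
        for name, (aflp, bundle) in qc_out.items():
            epi = extract_epigenotypes(
                bundle, min_poly=cfg.min_poly, delete_monomorphic=cfg.delete_monomorphic
            )
            aflp_kept = drop_monomorphic(aflp)
            species_matrices[name] = {
                "AFLP": aflp_kept,
                "U_MSAP": epi.u,
                "M_MSAP": epi.m,
            }
            log(
                f"{stage} {name}: AFLP {aflp.n_loci}->{aflp_kept.n_loci} loci, "
                f"U-MSAP {epi.u.n_loci} markers "
                f"({len(epi.filter_log['U_MSAP'])} dropped), "
                f"M-MSAP {epi.m.n_loci} markers "
                f"({len(epi.filter_log['M_MSAP'])} dropped)"
            )
            for mk, m in species_matrices[name].items():
                path = out / "matrices" / f"{name}_{mk}.csv"
                write_marker_matrix(m, path)
                manifest["outputs"].append(str(path.relative_to(out)))
        finish(stage, "ok")
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # -- stage 4: diversity table -----------------------------------------
    stage = "diversity"
    try:
        table = build_diversity_table(species_matrices)
        tpath = out / "diversity_table.csv"
        table.to_csv(tpath, index=False)
        manifest["outputs"].append(tpath.name)
        log(f"{stage}: {len(table)} records ({table['marker_type'].nunique()} marker types)")
        finish(stage, "ok")
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # -- stage 5: mixed models --------------------------------------------
    stage = "compare"
    try:
        contrast_rows = []
        for index_name in cfg.indices:
            if index_name not in INDEX_FAMILIES:
                raise ValueError(f"unknown index '{index_name}'")
            res = fit_index_model(table, index_name)
            mpath = out / f"model_{index_name}.json"
            mpath.write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
            manifest["outputs"].append(mpath.name)
            for c in res.contrasts:
                contrast_rows.append({"index": index_name, **c})
            lrt_str = ", ".join(
                f"{r['term']} chi2={r['chi_square']:.2f} p={r['p']:.3g}" for r in res.lrt
            )
            log(f"{stage} {index_name} ({res.model_family}): {lrt_str}")
        cpath = out / "contrasts.csv"
        pd.DataFrame(contrast_rows).to_csv(cpath, index=False)
        manifest["outputs"].append(cpath.name)
        finish(stage, "ok")
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    # -- stage 6: correlations --------------------------------------------
    stage = "correlate"
    try:
        cors = correlate_groups(table)
        rows = [
            {
                "group": c.group,
                "index": c.index_name,
                "marker_pair": f"{c.marker_pair[0]}~{c.marker_pair[1]}",
                "n": c.n,
                "r": c.r,
                "t": c.t_stat,
                "p": c.p,
                "flag": c.flagged or "",
            }
            for c in cors
        ]
        rpath = out / "correlations.csv"
        pd.DataFrame(rows).to_csv(rpath, index=False)
        manifest["outputs"].append(rpath.name)
        log(f"{stage}: {len(rows)} correlation rows")
        finish(stage, "ok")
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc) from exc

    manifest["complete"] = True
    _write_manifest(out, manifest, log_lines)
    return manifest


def _write_manifest(out: Path, manifest: dict, log_lines: list[str]) -> None:
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
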