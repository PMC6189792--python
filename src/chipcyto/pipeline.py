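"""Orchestration: simulate -> quantify -> gate -> QC -> report.

A run is driven by one nested config (YAML file or dict) and writes a run
directory containing per-field TIFFs and label maps, the pooled nucleus
table, the histogram, gates, fractions, QC verdicts, a summary, and a
manifest with a SHA-256 checksum of every output.  Runs are deterministic
given (config, seed).
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
import warnings
from dataclasses import replace
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .cytometry import (
    GateWindow,
    HistogramSpec,
    PhaseGates,
    auto_gates,
    build_histogram,
    find_g1_g2_peaks,
    gate_fractions,
    normalize_axes,
    two_peak_score,
    write_fractions,
    write_gates,
    write_histogram,
)
from .errors import InputError, QCFailureError, UnimodalHistogramError
from .qc import exposure_check
from .quantify import (
    estimate_background,
    flag_clumps,
    measure_nuclei,
    records_to_frame,
    segment_nuclei,
)
from .simulate import (
    CellCycleMixture,
    OpticsConfig,
    read_field,
    simulate_dataset,
    write_field,
    write_ground_truth,
)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "simulate_only"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "strict": False,
    "inputs": [],  # TIFF paths; ignored when a simulate block is present
    "simulate": None,  # {"mixture": {...}, "optics": {...}, "n_nuclei": int}
    "analysis": {
        "min_area": 30,
        "max_area": None,
        "threshold_method": "background",
        "grow_px": 2,
        "clump_factor": 1.4,
        "sat_frac": 0.05,
    },
    "histogram": {"interval": 60.0, "origin": 0.0},
    "gating": {"mode": "auto", "width_frac": 0.15, "manual": None},
    "qc": {"clip_threshold": 0.01, "snr_threshold": 3.0},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(source: str | Path | dict | None) -> dict:
    """Merge a YAML file or dict over the package defaults."""
    if source is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    if isinstance(source, dict):
        return _deep_merge(DEFAULT_CONFIG, source)
    path = Path(source)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    return _deep_merge(DEFAULT_CONFIG, yaml.safe_load(path.read_text()) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _optics_from_config(cfg: dict, seed: int) -> OpticsConfig:
    kwargs = dict(cfg or {})
    if isinstance(kwargs.get("nucleus_radius_px"), list):
        kwargs["nucleus_radius_px"] = tuple(kwargs["nucleus_radius_px"])
    if isinstance(kwargs.get("field_shape"), list):
        kwargs["field_shape"] = tuple(kwargs["field_shape"])
    if kwargs.get("saturation_k") in (None, "inf"):
        kwargs["saturation_k"] = math.inf
    kwargs.setdefault("seed", seed)
    return OpticsConfig(**kwargs)


def simulate_only(config: dict | str | Path | None, outdir: str | Path) -> list[Path]:
    """Run just the synthetic-microscope stage; returns written TIFF paths."""
    cfg = load_config(config)
    sim = cfg.get("simulate")
    if not sim:
        raise InputError("config has no simulate block")
    outdir = Path(outdir)
    (outdir / "fields").mkdir(parents=True, exist_ok=True)
    mixture = CellCycleMixture(**sim["mixture"])
    optics = _optics_from_config(sim.get("optics"), cfg["seed"])
    dataset = simulate_dataset(mixture, optics, int(sim["n_nuclei"]), cfg["seed"])
    paths = []
    for i, (image, truth) in enumerate(dataset):
        tif = outdir / "fields" / f"field_{i:03d}.tif"
        write_field(image, tif)
        write_ground_truth(
            truth,
            outdir / "fields" / f"truth_{i:03d}.csv",
            outdir / "fields" / f"truth_labels_{i:03d}.tif",
        )
        paths.append(tif)
    return paths


def run_pipeline(config: dict | str | Path | None, outdir: str | Path) -> dict:
    """Execute the full pipeline per config and write the run directory.

    Returns the summary dict (also written to ``summary.json``).  In strict
    mode a field failing exposure QC raises :class:`QCFailureError` after
    all outputs are written.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- acquire fields -------------------------------------------------
    if cfg.get("simulate"):
        sim = cfg["simulate"]
        mixture = CellCycleMixture(**sim["mixture"])
        optics = _optics_from_config(sim.get("optics"), seed)
        dataset = simulate_dataset(mixture, optics, int(sim["n_nuclei"]), seed)
        images = [img for img, _ in dataset]
        (outdir / "fields").mkdir(exist_ok=True)
        for i, (image, truth) in enumerate(dataset):
            write_field(image, outdir / "fields" / f"field_{i:03d}.tif")
            write_ground_truth(truth, outdir / "fields" / f"truth_{i:03d}.csv")
    elif cfg.get("inputs"):
        images = []
        for p in cfg["inputs"]:
            path = Path(p)
            if not path.exists():
                raise InputError(f"input field not found: {path}")
            try:
                images.append(read_field(path))
            except (OSError, ValueError) as exc:
                raise InputError(f"unreadable TIFF {path}: {exc}") from exc
    else:
        raise InputError("config needs a simulate block or a list of inputs")

    # --- quantify + QC per field ----------------------------------------
    ana = cfg["analysis"]
    qc_cfg = cfg["qc"]
    records = []
    qc_reports = []
    counts = {"fields": len(images)}
    for i, image in enumerate(images):
        labels = segment_nuclei(
            image,
            min_area=int(ana["min_area"]),
            max_area=ana["max_area"],
            threshold_method=ana["threshold_method"],
            grow_px=int(ana["grow_px"]),
        )
        tifffile.imwrite(outdir / f"labels_{i:03d}.tif", labels.astype(np.int32))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = exposure_check(
                image,
                labels,
                clip_threshold=qc_cfg["clip_threshold"],
                snr_threshold=qc_cfg["snr_threshold"],
            )
        qc_reports.append(report)
        background = estimate_background(image, foreground_mask=labels)
        records.extend(
            measure_nuclei(image, labels, background, sat_frac=ana["sat_frac"])
        )
    records = flag_clumps(records, clump_factor=ana["clump_factor"])
    records_to_frame(records).to_csv(outdir / "nuclei.csv", index=False)
    counts["nuclei_segmented"] = len(records)
    clean = [r for r in records if r.ok]
    counts["nuclei_flagged"] = len(records) - len(clean)

    qc_payload = {
        f"field_{i:03d}": rep.as_dict() for i, rep in enumerate(qc_reports)
    }
    qc_ok = all(rep.status == "ok" for rep in qc_reports)
    qc_payload["all_ok"] = qc_ok
    (outdir / "qc.json").write_text(json.dumps(qc_payload, indent=2, sort_keys=True))
    if cfg["strict"] and not qc_ok:
        _write_manifest(outdir)
        raise QCFailureError("one or more fields failed exposure QC")

    # --- histogram + gates + fractions ----------------------------------
    intensities = np.array([r.integrated_intensity for r in clean])
    if intensities.size == 0:
        raise InputError("no unflagged nuclei to analyse")
    spec = HistogramSpec(
        interval=float(cfg["histogram"]["interval"]),
        origin=float(cfg["histogram"]["origin"]),
    )
    hist = build_histogram(intensities, spec)
    gating = cfg["gating"]
    g1_peak = g2_peak = None
    if gating["mode"] == "manual":
        manual = gating.get("manual") or {}
        gates = PhaseGates(
            g1=GateWindow(*manual["g1"]),
            s=GateWindow(*manual["s"]),
            g2m=GateWindow(*manual["g2m"]),
        )
        try:
            g1_peak, g2_peak = find_g1_g2_peaks(hist)
        except (UnimodalHistogramError, ValueError):
            g1_peak = 0.5 * (gates.g1.lo + gates.g1.hi)  # normalisation anchor
    else:
        g1_peak, g2_peak = find_g1_g2_peaks(hist)
        gates = auto_gates(g1_peak, g2_peak, width_frac=gating["width_frac"])
    hist = normalize_axes(hist, g1_peak)
    fractions = gate_fractions(intensities, gates)
    write_histogram(hist, outdir / "histogram.csv")
    write_gates(gates, outdir / "gates.json")
    write_fractions(fractions, outdir / "fractions.json")

    # --- summary + manifest ---------------------------------------------
    summary = {
        "version": __version__,
        "seed": seed,
        "counts": counts,
        "g1_peak": g1_peak,
        "g2_peak": g2_peak,
        "two_peak_score": two_peak_score(hist),
        "fractions": fractions.as_dict(),
        "qc_all_ok": qc_ok,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _write_manifest(outdir)
    return summary


def _write_manifest(outdir: Path) -> None:
    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
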