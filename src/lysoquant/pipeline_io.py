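"""Configuration, orchestration, and file I/O for reproducible runs.

``run_quantify`` drives the full imaging pipeline — synthetic generation (or
loading of per-cell TIFF pairs), background subtraction, Otsu thresholding,
component extraction in both channels, cross-channel pairing and filtering,
4PL calibration, ratio-to-pH inversion, per-cell/per-condition aggregation,
condition shift and ECDFs — and writes CSV/JSON outputs stamped with the
configuration hash and seed, so reruns with an identical config reproduce
identical files.  ``run_ephys`` does the same for simulated voltage-clamp
batches: per-cell family metrics, break-in inhibition ratios, and an
optional dose-response fit across concentration groups.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationCurve, CalibrationPoint, fit_calibration
from .ephys import (
    GatingParams,
    InhibitionModel,
    SweepFamily,
    VoltageProtocol,
    family_metrics,
    fit_dose_response,
    inhibition_ratio,
    simulate_family,
)
from .quantification import (
    ConditionSummary,
    LysosomeMeasurement,
    ShiftResult,
    ecdf,
    measure_lysosomes,
    shift,
    summarize,
)
from .roi_pairing import RoiPair, filter_pairs, pair_rois
from .segmentation import extract_rois, otsu_threshold, subtract_background
from .synth_imaging import (
    DEFAULT_BUFFER_PHS,
    GroundTruthLaw,
    ImagePair,
    NoiseModel,
    SceneConfig,
    make_calibration_series,
    make_scene,
    render_image_pair,
)

__all__ = [
    "SegmentationParams",
    "PairingParams",
    "ConditionSpec",
    "QuantifyConfig",
    "EphysConfig",
    "QuantifyResult",
    "EphysResult",
    "process_image_pair",
    "calibration_from_series",
    "run_quantify",
    "run_ephys",
    "read_sweep_family",
    "write_sweep_family",
    "load_image_pairs",
    "config_hash",
]


@dataclass(frozen=True)
class SegmentationParams:
    background_radius_px: int = 10
    n_bins: int = 256
    min_area_px: int = 4
    connectivity: int = 8


@dataclass(frozen=True)
class PairingParams:
    max_dist_px: float = 3.0
    min_pixel_intensity: float = 5.0


@dataclass(frozen=True)
class ConditionSpec:
    """Ground-truth description of one experimental condition."""

    label: str
    ph_mean: float
    ph_sd: float = 0.15
    radius_px_median: float = 2.0


@dataclass(frozen=True)
class QuantifyConfig:
    """End-to-end synthetic pH experiment: conditions + calibration + analysis.

    The first condition is the control for the shift computation.  Defaults
    describe a vehicle-vs-PIKfyve-inhibitor experiment: control lysosomes at
    pH 4.32, treated at 4.02 with swollen puncta.
    """

    seed: int = 0
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (256, 256)
    cells_per_condition: int = 10
    lysosomes_per_cell: int = 30
    conditions: tuple[ConditionSpec, ...] = (
        ConditionSpec(label="control", ph_mean=4.32, radius_px_median=2.0),
        ConditionSpec(label="apilimod", ph_mean=4.02, radius_px_median=3.5),
    )
    law: GroundTruthLaw = GroundTruthLaw()
    noise: NoiseModel = NoiseModel()
    buffer_phs: tuple[float, ...] = DEFAULT_BUFFER_PHS
    cells_per_buffer: int = 4
    calib_lysosomes_per_cell: int = 15
    calib_image_shape: tuple[int, int] = (160, 160)
    segmentation: SegmentationParams = SegmentationParams()
    pairing: PairingParams = PairingParams()
    min_lysosomes_per_cell: int = 5
    experiment_id: str = "synthetic"


@dataclass(frozen=True)
class EphysConfig:
    """Simulated patch-clamp batch: per-cell early/late families at one
    pipette concentration plus an optional concentration series."""

    seed: int = 0
    gating: GatingParams = GatingParams()
    inhibition: InhibitionModel = InhibitionModel()
    protocol: VoltageProtocol = VoltageProtocol()
    conc_um: float = 100.0
    n_cells: int = 10
    t_early_s: float = 30.0
    t_late_s: float = 180.0
    v_ref: float = 140.0
    noise_sd_pa: float = 20.0
    dose_concentrations_um: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0)
    cells_per_dose: int = 5


def config_hash(cfg) -> str:
    """Short stable hash of a config dataclass (for output provenance)."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Imaging pipeline

def process_image_pair(
    pair: ImagePair,
    seg: SegmentationParams = SegmentationParams(),
    pairing: PairingParams = PairingParams(),
) -> list[RoiPair]:
    """Segment both channels, match ROIs across channels, apply filters."""
    pairs_out: dict[int, list] = {}
    rois = {}
    for channel, img in ((445, pair.ch445), (488, pair.ch488)):
        sub = subtract_background(img, seg.background_radius_px)
        try:
            thr = otsu_threshold(sub, n_bins=seg.n_bins)
        except ValueError:
            rois[channel] = []
            continue
        rois[channel] = extract_rois(
            sub, thr, min_area=seg.min_area_px,
            connectivity=seg.connectivity, channel=channel,
        )
    matched = pair_rois(rois.get(445, []), rois.get(488, []), max_dist_px=pairing.max_dist_px)
    return filter_pairs(matched, min_pixel_intensity=pairing.min_pixel_intensity)


def calibration_from_series(
    series: Sequence[tuple[float, Sequence]],
    seg: SegmentationParams = SegmentationParams(),
    pairing: PairingParams = PairingParams(),
) -> tuple[CalibrationCurve, list[CalibrationPoint]]:
    """Per-cell mean ratios at each buffer pH -> 4PL calibration fit.

    ``series`` holds (buffer_ph, [(scene, image_pair), ...]) groups or
    (buffer_ph, [image_pair, ...]); one calibration point per cell image.
    """
    points: list[CalibrationPoint] = []
    for buffer_ph, group in series:
        for item in group:
            pair = item[1] if isinstance(item, tuple) else item
            matched = process_image_pair(pair, seg, pairing)
            if not matched:
                continue
            mean_ratio = float(np.mean([p.ratio for p in matched]))
            points.append(CalibrationPoint(buffer_ph=float(buffer_ph), cell_mean_ratio=mean_ratio))
    curve = fit_calibration(points)
    return curve, points


@dataclass(frozen=True)
class QuantifyResult:
    curve: CalibrationCurve
    calibration_points: list[CalibrationPoint]
    measurements: list[LysosomeMeasurement]
    cells: pd.DataFrame
    conditions: dict[str, ConditionSummary]
    shift: ShiftResult | None
    ecdfs: dict[str, np.ndarray]
    manifest: dict


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31, size=n)


def run_quantify(cfg: QuantifyConfig, outdir: Path | None = None) -> QuantifyResult:
    """Execute the full synthetic pH experiment described by ``cfg``.

    Order of operations per image: subtract background -> Otsu -> extract
    ROIs (both channels) -> pair -> filter; then calibrate on the clamped
    series, invert ratios to pH, aggregate, and compute the condition shift
    (conditions[1] - conditions[0]) and per-condition ECDFs.
    """
    n_imgs = cfg.cells_per_condition * len(cfg.conditions)
    seeds = _derived_seeds(cfg.seed, 2 * n_imgs + 1)
    calib_seed = int(seeds[-1])

    # calibration series (ionophore-clamped buffers)
    calib_cfg = SceneConfig(
        pixel_size_um=cfg.pixel_size_um,
        image_shape=cfg.calib_image_shape,
        n_cells=1,
        lysosomes_per_cell=cfg.calib_lysosomes_per_cell,
        law=cfg.law,
    )
    series = make_calibration_series(
        calib_cfg, buffer_phs=cfg.buffer_phs, cells_per_buffer=cfg.cells_per_buffer,
        noise=cfg.noise, seed=calib_seed,
    )
    curve, points = calibration_from_series(series, cfg.segmentation, cfg.pairing)

    # experimental conditions, one cell per image pair
    measurements: list[LysosomeMeasurement] = []
    k = 0
    for cond in cfg.conditions:
        scene_cfg = SceneConfig(
            pixel_size_um=cfg.pixel_size_um,
            image_shape=cfg.image_shape,
            n_cells=1,
            lysosomes_per_cell=cfg.lysosomes_per_cell,
            radius_px_median=cond.radius_px_median,
            ph_mean=cond.ph_mean,
            ph_sd=cond.ph_sd,
            law=cfg.law,
            condition_label=cond.label,
        )
        for cell_id in range(1, cfg.cells_per_condition + 1):
            scene = make_scene(scene_cfg, seed=int(seeds[k]))
            pair = render_image_pair(scene, replace(cfg.noise, seed=int(seeds[k + 1])))
            k += 2
            matched = process_image_pair(pair, cfg.segmentation, cfg.pairing)
            measurements.extend(
                measure_lysosomes(
                    {cell_id: matched}, curve, cfg.pixel_size_um,
                    condition=cond.label, experiment_id=cfg.experiment_id,
                )
            )

    cells_rows = []
    conditions: dict[str, ConditionSummary] = {}
    ecdfs: dict[str, np.ndarray] = {}
    for cond in cfg.conditions:
        recs = [m for m in measurements if m.condition == cond.label]
        cell_summaries, cond_summary = summarize(recs, cfg.min_lysosomes_per_cell)
        conditions[cond.label] = cond_summary
        ecdfs[cond.label] = ecdf([m.ph for m in recs])
        for cs in cell_summaries:
            cells_rows.append({"condition": cond.label, **dataclasses.asdict(cs)})
    cells_df = pd.DataFrame(cells_rows)

    shift_result = None
    if len(cfg.conditions) >= 2:
        shift_result = shift(
            conditions[cfg.conditions[0].label], conditions[cfg.conditions[1].label]
        )

    manifest = {
        "tool": "lysoquant",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_calibration_points": len(points),
        "n_measurements": len(measurements),
        "n_cells": int(len(cells_df)),
    }
    result = QuantifyResult(
        curve=curve, calibration_points=points, measurements=measurements,
        cells=cells_df, conditions=conditions, shift=shift_result,
        ecdfs=ecdfs, manifest=manifest,
    )
    if outdir is not None:
        _write_quantify_outputs(result, cfg, Path(outdir))
    return result


def _stamp(path: Path, df: pd.DataFrame, chash: str, seed: int) -> None:
    header = f"# lysoquant config_hash={chash} seed={seed}\n"
    path.write_text(header + df.to_csv(index=False, float_format="%.9g"))


def _write_quantify_outputs(result: QuantifyResult, cfg: QuantifyConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    chash = result.manifest["config_hash"]
    lys_df = pd.DataFrame([dataclasses.asdict(m) for m in result.measurements])
    _stamp(outdir / "lysosomes.csv", lys_df, chash, cfg.seed)
    _stamp(outdir / "cells.csv", result.cells, chash, cfg.seed)
    cond_df = pd.DataFrame([dataclasses.asdict(s) for s in result.conditions.values()])
    _stamp(outdir / "conditions.csv", cond_df, chash, cfg.seed)
    if result.shift is not None:
        shift_df = pd.DataFrame([dataclasses.asdict(result.shift)])
        _stamp(outdir / "shifts.csv", shift_df, chash, cfg.seed)
    ecdf_rows = []
    for cond, arr in result.ecdfs.items():
        for x, frac in arr:
            ecdf_rows.append({"condition": cond, "ph": x, "fraction_below": frac})
    _stamp(outdir / "ecdf.csv", pd.DataFrame(ecdf_rows), chash, cfg.seed)
    pts_df = pd.DataFrame([dataclasses.asdict(p) for p in result.calibration_points])
    _stamp(outdir / "calibration_points.csv", pts_df, chash, cfg.seed)
    calib = {
        "r_min": result.curve.r_min,
        "r_max": result.curve.r_max,
        "ph50": result.curve.ph50,
        "slope_h": result.curve.slope_h,
        "valid_range": list(result.curve.valid_range),
        "fit_rss": result.curve.fit_rss,
        "n_points": result.curve.n_points,
        "config_hash": chash,
        "seed": cfg.seed,
    }
    (outdir / "calibration.json").write_text(json.dumps(calib, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Ephys pipeline

@dataclass(frozen=True)
class EphysResult:
    metrics: pd.DataFrame
    ratios: pd.DataFrame
    dose_response: dict | None
    manifest: dict


def run_ephys(cfg: EphysConfig, outdir: Path | None = None) -> EphysResult:
    """Simulate per-cell early/late families and quantify inhibition.

    One early (t_early_s) and one late (t_late_s) family per simulated cell
    at cfg.conc_um; ratios are late/early per cell.  If the dose design has
    >= 4 concentrations, mean per-cell fractional inhibition (1 - max ratio)
    is fitted with the Hill equation.
    """
    rows, ratio_rows = [], []
    seeds = _derived_seeds(cfg.seed, 2 * cfg.n_cells)
    for cell in range(cfg.n_cells):
        fam_early = simulate_family(
            cfg.gating, cfg.inhibition, cfg.conc_um, cfg.t_early_s,
            cfg.protocol, cfg.noise_sd_pa, seed=int(seeds[2 * cell]),
        )
        fam_late = simulate_family(
            cfg.gating, cfg.inhibition, cfg.conc_um, cfg.t_late_s,
            cfg.protocol, cfg.noise_sd_pa, seed=int(seeds[2 * cell + 1]),
        )
        for tag, fam in (("early", fam_early), ("late", fam_late)):
            m = family_metrics(fam, cfg.v_ref)
            rows.append({
                "cell": cell + 1, "recording": tag, "conc_um": cfg.conc_um,
                "t_breakin_s": fam.t_breakin_s, "i_max_pa": m.i_max_pa,
                "i_tail_pa": m.i_tail_pa, "tau_act_s": m.tau_act_s,
                "tau_deact_s": m.tau_deact_s,
            })
        max_ratio, tail_ratio = inhibition_ratio(fam_late, fam_early, cfg.v_ref)
        ratio_rows.append({
            "cell": cell + 1, "conc_um": cfg.conc_um,
            "max_ratio": max_ratio, "tail_ratio": tail_ratio,
        })

    dose = None
    if len(set(cfg.dose_concentrations_um)) >= 4:
        dose_seeds = _derived_seeds(cfg.seed + 1, 2 * len(cfg.dose_concentrations_um) * cfg.cells_per_dose)
        concs, responses = [], []
        k = 0
        for conc in cfg.dose_concentrations_um:
            for _ in range(cfg.cells_per_dose):
                fe = simulate_family(cfg.gating, cfg.inhibition, conc, cfg.t_early_s,
                                     cfg.protocol, cfg.noise_sd_pa, seed=int(dose_seeds[k]))
                fl = simulate_family(cfg.gating, cfg.inhibition, conc, cfg.t_late_s,
                                     cfg.protocol, cfg.noise_sd_pa, seed=int(dose_seeds[k + 1]))
                k += 2
                max_ratio, _ = inhibition_ratio(fl, fe, cfg.v_ref)
                concs.append(conc)
                responses.append(1.0 - max_ratio)
        fit = fit_dose_response(concs, responses)
        dose = {
            "ec50_um": fit.ec50, "hill_n": fit.hill_n, "floor": fit.floor,
            "ceiling": fit.ceiling, "rmse": fit.rmse,
            "concentrations_um": list(cfg.dose_concentrations_um),
            "n_cells_per_dose": cfg.cells_per_dose,
        }

    manifest = {
        "tool": "lysoquant",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "n_cells": cfg.n_cells,
        "conc_um": cfg.conc_um,
    }
    result = EphysResult(
        metrics=pd.DataFrame(rows), ratios=pd.DataFrame(ratio_rows),
        dose_response=dose, manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = manifest["config_hash"]
        _stamp(outdir / "family_metrics.csv", result.metrics, chash, cfg.seed)
        _stamp(outdir / "inhibition_ratios.csv", result.ratios, chash, cfg.seed)
        if dose is not None:
            (outdir / "dose_response.json").write_text(json.dumps(dose, indent=2))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


# ---------------------------------------------------------------------------
# File formats: sweep CSV + JSON sidecar; per-cell TIFF discovery

def write_sweep_family(fam: SweepFamily, csv_path: Path) -> None:
    """CSV: column 0 time_s, one column per step voltage; JSON sidecar with
    the protocol, break-in time, concentration and seed."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": fam.time_s})
    for k, v in enumerate(fam.protocol.step_voltages):
        df[f"{v:g}mV"] = fam.sweeps[k]
    df.to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "holding_v": fam.protocol.holding_v,
        "step_voltages": list(fam.protocol.step_voltages),
        "pre_s": fam.protocol.pre_s,
        "pulse_s": fam.protocol.pulse_s,
        "tail_s": fam.protocol.tail_s,
        "dt": fam.protocol.dt,
        "t_breakin_s": fam.t_breakin_s,
        "conc_um": fam.conc_um,
        "seed": fam.seed,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_sweep_family(csv_path: Path) -> SweepFamily:
    """Inverse of write_sweep_family; errors name the offending file/field."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path} for {csv_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("holding_v", "step_voltages", "pre_s", "pulse_s", "tail_s",
                "dt", "t_breakin_s", "conc_um"):
        if key not in meta:
            raise ValueError(f"{sidecar_path}: missing metadata field '{key}'")
    protocol = VoltageProtocol(
        holding_v=meta["holding_v"],
        step_voltages=tuple(float(v) for v in meta["step_voltages"]),
        pre_s=meta["pre_s"], pulse_s=meta["pulse_s"], tail_s=meta["tail_s"],
        dt=meta["dt"],
    )
    df = pd.read_csv(csv_path)
    cols = [f"{v:g}mV" for v in protocol.step_voltages]
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"{csv_path}: missing sweep column '{col}'")
    sweeps = df[cols].to_numpy().T
    return SweepFamily(protocol=protocol, sweeps=sweeps,
                       t_breakin_s=meta["t_breakin_s"], conc_um=meta["conc_um"],
                       seed=int(meta.get("seed", 0)))


def quantify_config_from_yaml(path: Path) -> QuantifyConfig:
    """Build a QuantifyConfig from a YAML mapping (keys mirror the dataclass;
    nested sections `law`, `noise`, `segmentation`, `pairing`, `conditions`)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "law": GroundTruthLaw,
        "noise": NoiseModel,
        "segmentation": SegmentationParams,
        "pairing": PairingParams,
    }
    kwargs = {}
    for key, value in data.items():
        if key in nested:
            kwargs[key] = nested[key](**value)
        elif key == "conditions":
            kwargs[key] = tuple(ConditionSpec(**c) for c in value)
        elif key in ("image_shape", "calib_image_shape", "buffer_phs"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return QuantifyConfig(**kwargs)


_TIFF_RE = re.compile(r"^(?P<condition>.+)__cell(?P<cell>\d+)__(?P<chan>445|488)\.tif$")


def load_image_pairs(indir: Path, pixel_size_um: float) -> dict[str, dict[int, ImagePair]]:
    """Discover `{condition}__cell{ID}__{445|488}.tif` pairs in a directory.

    Returns {condition: {cell_id: ImagePair}}.  Calibration images follow the
    same convention with condition `calib_ph{X}`.
    """
    import tifffile

    indir = Path(indir)
    found: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for p in sorted(indir.glob("*.tif")):
        m = _TIFF_RE.match(p.name)
        if not m:
            continue
        key = (m["condition"], int(m["cell"]))
        found.setdefault(key, {})[m["chan"]] = tifffile.imread(p).astype(float)
    out: dict[str, dict[int, ImagePair]] = {}
    for (condition, cell_id), chans in found.items():
        if set(chans) != {"445", "488"}:
            raise ValueError(f"unpaired channels for {condition} cell {cell_id}")
        out.setdefault(condition, {})[cell_id] = ImagePair(
            ch445=chans["445"], ch488=chans["488"], pixel_size_um=pixel_size_um,
            labels={"condition": condition, "cell_id": cell_id},
        )
    return out


def calibration_series_from_images(
    images: dict[str, dict[int, ImagePair]],
) -> list[tuple[float, list[ImagePair]]]:
    """Extract `calib_ph{X}` groups from a load_image_pairs result."""
    series = []
    for condition, cells in images.items():
        m = re.match(r"^calib_ph(?P<ph>[\d.]+)$", condition)
        if m:
            series.append((float(m["ph"]), [cells[c] for c in sorted(cells)]))
    series.sort(key=lambda t: -t[0])
    return series
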