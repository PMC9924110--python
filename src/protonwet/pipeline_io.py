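"""File formats, configuration, reporting, and the end-to-end study driver.

Formats: IDD curves and calibration tables as CSV; voxel grids (phantoms,
masks, doses) as NRRD (gzip-encoded raw, axis order (z, y, x), mm spacing);
study configuration as YAML; reports as CSV/JSON.  All writers round-trip to
full precision through the matching readers.

The bundled ``reference_device_table.csv`` holds clinically measured TPS-vs-
MLIC SPR comparison rows for nine common immobilization devices, so the
reporting path is testable without re-running measurements.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ct_calibration import (
    CalibrationCurve,
    Phantom,
    SPRComparison,
    StructureMask,
    compare_spr,
    default_calibration,
    tps_spr_at_location,
)
from .dvh_stats import (
    beam_specific_metrics,
    dvh_metrics,
    max_dose_pct,
    mean_dose_pct,
    paired_metric_table,
    wilcoxon_signed_rank,
    worst_case_metrics,
)
from .errors import MalformedFileError, ShapeMismatchError, StageError, ValidationError
from .idd_wet import DepthDoseCurve, device_spr, spr_at_location, wet_from_curves
from .override_dose import OverrideRecord, compute_dose, scenario_doses
from .synthetic_data import (
    BraggModelParams,
    CaseSpec,
    DeviceSpec,
    GridSpec,
    OARSpec,
    generate_device_phantom,
    generate_idd,
    generate_patient_phantom,
)

__all__ = [
    "read_idd_csv",
    "write_idd_csv",
    "read_calibration_csv",
    "read_nrrd",
    "write_nrrd",
    "read_config",
    "StudyConfig",
    "Table1Summary",
    "summarize_table1",
    "load_reference_table1",
    "run_study",
]

log = logging.getLogger("protonwet")


# ---------------------------------------------------------------------------
# CSV readers / writers


def write_idd_csv(path, curve: DepthDoseCurve) -> None:
    """Write an IDD as a two-column CSV (``depth_mm,signal``)."""
    pd.DataFrame({"depth_mm": curve.depths_mm, "signal": curve.signal}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_idd_csv(path) -> DepthDoseCurve:
    """Read an IDD CSV; requires columns ``depth_mm`` and ``signal``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"depth_mm", "signal"}.issubset(df.columns):
        raise MalformedFileError(
            f"{path}: IDD CSV must have columns depth_mm,signal; got {list(df.columns)}"
        )
    # strictly-increasing-depth and positivity checks live in the curve type
    return DepthDoseCurve(df["depth_mm"].to_numpy(), df["signal"].to_numpy())


def read_calibration_csv(hu_density_path, density_rsp_path=None) -> CalibrationCurve:
    """Load a calibration curve from node-table CSVs.

    Either two files (``hu,density`` and ``density,rsp``) or a single direct
    ``hu,rsp`` table.  Monotonicity violations raise a calibration error.
    """
    df = pd.read_csv(hu_density_path)
    cols = set(df.columns)
    if {"hu", "rsp"}.issubset(cols) and density_rsp_path is None:
        return CalibrationCurve.from_hu_rsp(df["hu"].to_numpy(), df["rsp"].to_numpy())
    if not {"hu", "density"}.issubset(cols):
        raise MalformedFileError(
            f"{hu_density_path}: expected columns hu,density (or hu,rsp); got {sorted(cols)}"
        )
    if density_rsp_path is None:
        raise MalformedFileError("density->rsp table required with an hu,density table")
    df2 = pd.read_csv(density_rsp_path)
    if not {"density", "rsp"}.issubset(df2.columns):
        raise MalformedFileError(
            f"{density_rsp_path}: expected columns density,rsp; got {list(df2.columns)}"
        )
    return CalibrationCurve(
        hu_nodes=df["hu"].to_numpy(),
        density_nodes=df["density"].to_numpy(),
        rsp_density_nodes=df2["density"].to_numpy(),
        rsp_nodes=df2["rsp"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# NRRD (minimal NRRD0004 subset: raw / gzip encodings, 3-D grids)

_NRRD_TYPES = {"double": np.float64, "float": np.float32, "uint8": np.uint8, "int16": np.int16}


def write_nrrd(path, array: np.ndarray, spacing_mm, origin_mm, encoding: str = "gzip") -> None:
    """Write a 3-D grid as NRRD: text header + raw or gzip-compressed C-order data.

    Axis order (z, y, x); ``space directions`` carry the per-axis spacing and
    ``space origin`` the corner of the first voxel.
    """
    array = np.asarray(array)
    if array.ndim != 3:
        raise ValidationError("NRRD writer handles 3-D grids only")
    if array.dtype == bool:
        array = array.astype(np.uint8)
    dtype_name = {v: k for k, v in _NRRD_TYPES.items()}.get(array.dtype.type)
    if dtype_name is None:
        array = array.astype(np.float64)
        dtype_name = "double"
    spacing = np.asarray(spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    dirs = " ".join(
        "(" + ",".join(f"{spacing[a] if a == i else 0.0:.17g}" for a in range(3)) + ")"
        for i in range(3)
    )
    header = (
        "NRRD0004\n"
        f"type: {dtype_name}\n"
        "dimension: 3\n"
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}\n"
        "endian: little\n"
        f"encoding: {encoding}\n"
        "space: left-posterior-superior\n"
        f"space directions: {dirs}\n"
        f"space origin: ({origin[0]:.17g},{origin[1]:.17g},{origin[2]:.17g})\n"
        "\n"
    )
    payload = array.astype(array.dtype.newbyteorder("<")).tobytes(order="C")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise ValidationError(f"unsupported NRRD encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def read_nrrd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an NRRD grid -> (array, spacing_mm, origin_mm)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    try:
        head, payload = blob.split(b"\n\n", 1)
        lines = head.decode("ascii").splitlines()
    except (ValueError, UnicodeDecodeError) as exc:
        raise MalformedFileError(f"{path}: not a NRRD file") from exc
    if not lines or not lines[0].startswith("NRRD"):
        raise MalformedFileError(f"{path}: missing NRRD magic")
    fields = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise MalformedFileError(f"{path}: malformed header line {line!r}")
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    try:
        dtype = _NRRD_TYPES[fields["type"]]
        sizes = tuple(int(s) for s in fields["sizes"].split())
        encoding = fields["encoding"]
    except KeyError as exc:
        raise MalformedFileError(f"{path}: missing required NRRD field {exc}") from exc
    if fields.get("dimension") != "3" or len(sizes) != 3:
        raise MalformedFileError(f"{path}: only 3-D NRRD grids are supported")

    def _vec(text: str) -> np.ndarray:
        return np.array([float(v) for v in text.strip("()").split(",")])

    spacing = np.ones(3)
    if "space directions" in fields:
        vecs = [_vec(v) for v in fields["space directions"].split(") (")]
        spacing = np.array([np.linalg.norm(v) for v in vecs])
    origin = _vec(fields["space origin"]) if "space origin" in fields else np.zeros(3)
    if encoding == "gzip":
        try:
            payload = gzip.decompress(payload)
        except (OSError, zlib.error) as exc:
            raise MalformedFileError(f"{path}: corrupt gzip payload") from exc
    elif encoding != "raw":
        raise MalformedFileError(f"{path}: unsupported encoding {encoding!r}")
    expected = int(np.prod(sizes)) * np.dtype(dtype).itemsize
    if len(payload) != expected:
        raise MalformedFileError(
            f"{path}: payload size {len(payload)} != expected {expected}"
        )
    array = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<")).reshape(sizes)
    return array.astype(dtype), spacing, origin


def read_mask_nrrd(path, phantom: Phantom, name: str) -> StructureMask:
    """Read a mask grid and attach it to a phantom, enforcing grid agreement."""
    data, spacing, origin = read_nrrd(path)
    if data.shape != phantom.shape:
        raise ShapeMismatchError(
            f"{path}: mask shape {data.shape} != phantom shape {phantom.shape}"
        )
    return StructureMask(name=name, data=data > 0, spacing_mm=spacing, origin_mm=origin)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Fully explicit study description (devices, beam model, case, seeds)."""

    seed: int
    output_dir: str
    bragg: BraggModelParams
    devices: list[DeviceSpec]
    case: CaseSpec
    calibration: CalibrationCurve
    device_grid: GridSpec
    n_cases: int = 5
    dosimetric_device: str | None = None  # default: first device

    def __post_init__(self):
        if len(self.devices) == 0:
            raise ValidationError("study requires at least one device")
        if self.n_cases < 1:
            raise ValidationError("n_cases must be >= 1")


def _device_from_dict(d: dict, calibration: CalibrationCurve) -> DeviceSpec:
    d = dict(d)
    if "reported_hu" not in d:
        if "tps_rsp" not in d:
            raise MalformedFileError("device needs either reported_hu or tps_rsp")
        d["reported_hu"] = calibration.hu_for_rsp(float(d.pop("tps_rsp")))
    else:
        d.pop("tps_rsp", None)
    return DeviceSpec(**d)


def read_config(path) -> StudyConfig:
    """Parse a YAML study configuration; all paths resolve relative to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MalformedFileError(f"{path}: config must be a YAML mapping")
    base = path.parent
    cal_cfg = raw.get("calibration")
    if cal_cfg:
        calibration = read_calibration_csv(
            base / cal_cfg["hu_density"],
            base / cal_cfg["density_rsp"] if "density_rsp" in cal_cfg else None,
        )
    else:
        calibration = default_calibration()
    devices = [_device_from_dict(d, calibration) for d in raw.get("devices", [])]
    case_cfg = dict(raw.get("case", {}))
    if "grid" in case_cfg:
        case_cfg["grid"] = GridSpec(**{k: tuple(v) for k, v in case_cfg["grid"].items()})
    if "oars" in case_cfg:
        case_cfg["oars"] = tuple(
            OARSpec(**{**o, "center_mm": tuple(o["center_mm"])}) for o in case_cfg["oars"]
        )
    for key in ("ctv_center_mm", "beam_angles_deg", "beam_weights"):
        if key in case_cfg and case_cfg[key] is not None:
            case_cfg[key] = tuple(case_cfg[key])
    dev_grid_cfg = raw.get("device_grid", {"shape": (8, 60, 60), "spacing_mm": (2.0, 1.0, 1.0)})
    return StudyConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
        bragg=BraggModelParams(**raw.get("bragg", {})),
        devices=devices,
        case=CaseSpec(**case_cfg),
        calibration=calibration,
        device_grid=GridSpec(**{k: tuple(v) for k, v in dev_grid_cfg.items()}),
        n_cases=int(raw.get("n_cases", 5)),
        dosimetric_device=raw.get("dosimetric_device"),
    )


# ---------------------------------------------------------------------------
# Table-1-style reporting


@dataclass(frozen=True)
class Table1Summary:
    """Per-device comparison rows plus the headline summary statistics."""

    rows: tuple[SPRComparison, ...]
    mean_percent_diff: float
    min_percent_diff: float
    max_percent_diff: float
    max_abs_wet_diff_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "device": r.device,
                    "tps_spr": r.tps_spr,
                    "tps_spr_sd": r.tps_spr_sd,
                    "measured_spr": r.measured_spr,
                    "measured_spr_sd": r.measured_spr_sd,
                    "spr_percent_diff": r.percent_diff,
                    "wet_diff_mm": r.wet_diff_mm,
                }
                for r in self.rows
            ]
        )


def summarize_table1(comparisons: list[SPRComparison]) -> Table1Summary:
    """Mean/min/max of the SPR percent differences and the largest |WET error|."""
    if len(comparisons) == 0:
        raise ValidationError("need at least one device comparison")
    pct = np.array([c.percent_diff for c in comparisons])
    wet = np.array([c.wet_diff_mm for c in comparisons])
    return Table1Summary(
        rows=tuple(comparisons),
        mean_percent_diff=float(pct.mean()),
        min_percent_diff=float(pct.min()),
        max_percent_diff=float(pct.max()),
        max_abs_wet_diff_mm=float(np.abs(wet).max()),
    )


def load_reference_table1() -> list[SPRComparison]:
    """The bundled nine-device reference comparison table.

    Percent differences in this table are per-location means as published for
    each device, so they are carried verbatim rather than recomputed from the
    aggregate SPR columns (the two differ in the last digit for some devices).
    """
    with resources.files("protonwet.data").joinpath("reference_device_table.csv").open() as fh:
        df = pd.read_csv(fh)
    rows = []
    for _, r in df.iterrows():
        rows.append(
            SPRComparison(
                device=r["device"],
                tps_spr=float(r["tps_spr"]),
                measured_spr=float(r["measured_spr"]),
                percent_diff=float(r["percent_diff"]),
                wet_diff_mm=float(r["wet_diff_mm"]),
                tps_spr_sd=None if pd.isna(r["tps_spr_sd"]) else float(r["tps_spr_sd"]),
                measured_spr_sd=None if pd.isna(r["measured_spr_sd"]) else float(r["measured_spr_sd"]),
                percent_diff_sd=None if pd.isna(r["percent_diff_sd"]) else float(r["percent_diff_sd"]),
                wet_diff_sd_mm=None if pd.isna(r["wet_diff_sd_mm"]) else float(r["wet_diff_sd_mm"]),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# end-to-end study


def _measure_device(config: StudyConfig, spec: DeviceSpec, rng: np.random.Generator):
    """MLIC + TPS measurement loop for one device; returns an SPRComparison."""
    phantom, mask, truth = generate_device_phantom(spec, config.device_grid, config.calibration)
    measured, tps = [], []
    for loc in truth.locations:
        reference = generate_idd(config.bragg, 0.0, rng=rng)
        sample = generate_idd(config.bragg, loc.true_wet_mm, rng=rng)
        wet = wet_from_curves(reference, sample)
        measured.append(spr_at_location(wet, loc.thickness_mm, location_id=loc.location_id))
        tps.append(
            tps_spr_at_location(
                phantom, mask, loc.ray, config.calibration, location_id=loc.location_id
            )
        )
    return compare_spr(
        device_spr(tps, device=spec.name),
        device_spr(measured, device=spec.name),
        thickness_mm=truth.thickness_mm,
    )


def _vary_case(case: CaseSpec, rng: np.random.Generator) -> CaseSpec:
    """Per-case anatomical variation: jittered CTV radius and OAR positions."""
    from dataclasses import replace

    oars = tuple(
        OARSpec(
            name=o.name,
            center_mm=tuple(np.asarray(o.center_mm) + rng.uniform(-2.0, 2.0, 3) * [0, 1, 1]),
            radius_mm=o.radius_mm * rng.uniform(0.9, 1.1),
            relation=o.relation,
        )
        for o in case.oars
    )
    return replace(case, ctv_radius_mm=case.ctv_radius_mm * rng.uniform(0.9, 1.1), oars=oars)


METRIC_NAMES = ("v95_pct", "d95_pct", "max_dose_pct", "mean_dose_pct", "conformity_index")


def run_study(config: StudyConfig):
    """Execute simulate -> measure -> compare -> override -> dose -> DVH -> stats.

    Writes ``table1_summary.csv``, ``dvh_metrics.csv``, ``comparison_report.json``
    and ``run_log.txt`` to the configured output directory and returns the
    report dictionary.  Fully deterministic for a fixed config seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seedseq = np.random.SeedSequence(config.seed)
    rng_meas, rng_cases = [np.random.default_rng(s) for s in seedseq.spawn(2)]
    log_lines = [f"protonwet {__version__} | seed {config.seed}"]

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        digest = hashlib.sha256(repr(result).encode()).hexdigest()[:12]
        log_lines.append(f"stage={name} ok hash={digest}")
        return result

    # --- measurement + comparison ---------------------------------------
    comparisons = [
        stage(f"measure:{spec.name}", _measure_device, config, spec, rng_meas)
        for spec in config.devices
    ]
    table1 = stage("summarize", summarize_table1, comparisons)
    table1.to_frame().to_csv(out / "table1_summary.csv", index=False)

    # --- dosimetric study -------------------------------------------------
    target_name = config.dosimetric_device or config.devices[0].name
    comparison = next(c for c in comparisons if c.device == target_name)
    spec = next(s for s in config.devices if s.name == target_name)
    base_case = config.case if config.case.device is not None else None
    if base_case is None:
        from dataclasses import replace

        base_case = replace(config.case, device=spec)

    dvh_rows, paired_records = [], []
    for i in range(config.n_cases):
        case = _vary_case(base_case, rng_cases) if config.n_cases > 1 else base_case
        phantom, masks, plan = stage(
            f"phantom:case{i}", generate_patient_phantom, case, config.calibration
        )
        record = OverrideRecord(
            device=target_name,
            tps_spr=comparison.tps_spr,
            measured_spr=comparison.measured_spr,
        )
        overrides = [(masks["device"], record)] if "device" in masks else []
        for label, ovr in (("without_override", []), ("with_override", overrides)):
            sc_doses = stage(
                f"dose:case{i}:{label}", scenario_doses, phantom, masks, plan,
                config.calibration, ovr,
            )
            ctv_scen = [dvh_metrics(d, masks["ctv"]) for d in sc_doses.values()]
            worst = worst_case_metrics(ctv_scen)
            nominal = sc_doses["nominal"]
            for metric in METRIC_NAMES:
                dvh_rows.append(
                    {
                        "case": f"case{i}",
                        "structure": "ctv",
                        "evaluation": "worst_case",
                        "metric": metric,
                        "arm": label,
                        "value": getattr(worst, metric),
                    }
                )
            # nominal beam-specific CTV coverage (equal beam weights)
            nominal_pb = stage(
                f"dose:case{i}:{label}:beams", compute_dose, phantom, masks, plan,
                config.calibration, ovr, keep_per_beam=True,
            )
            per_beam = beam_specific_metrics(
                [nominal_pb.per_beam[b] for b in sorted(nominal_pb.per_beam)],
                masks["ctv"], plan.prescription_dose,
                spacing_mm=phantom.spacing_mm, origin_mm=phantom.origin_mm,
            )
            for b, bm in enumerate(per_beam):
                for metric in ("v95_pct", "d95_pct", "mean_dose_pct"):
                    dvh_rows.append(
                        {
                            "case": f"case{i}",
                            "structure": "ctv",
                            "evaluation": f"beam{b}",
                            "metric": metric,
                            "arm": label,
                            "value": getattr(bm, metric),
                        }
                    )
            for oar in case.oars:
                for metric, fn in (("max_dose_pct", max_dose_pct), ("mean_dose_pct", mean_dose_pct)):
                    dvh_rows.append(
                        {
                            "case": f"case{i}",
                            "structure": oar.name,
                            "evaluation": "nominal",
                            "metric": metric,
                            "arm": label,
                            "value": fn(nominal, masks[oar.name]),
                        }
                    )

    df = pd.DataFrame(dvh_rows)
    df.to_csv(out / "dvh_metrics.csv", index=False)

    # --- paired statistics ------------------------------------------------
    wide = df.pivot_table(
        index=["case", "structure", "evaluation", "metric"], columns="arm", values="value"
    ).reset_index()
    stats = {}
    for (structure, evaluation, metric), grp in wide.groupby(["structure", "evaluation", "metric"]):
        diffs = (grp["with_override"] - grp["without_override"]).to_numpy()
        entry = {
            "n": int(diffs.size),
            "mean_delta": float(np.mean(diffs)),
        }
        if np.any(diffs != 0):
            w, p = wilcoxon_signed_rank(diffs)
            entry.update({"wilcoxon_w": w, "p_value": p, "significant": bool(p < 0.05)})
        else:
            entry.update({"wilcoxon_w": None, "p_value": None, "significant": False})
        stats[f"{structure}:{evaluation}:{metric}"] = entry
        paired_records.extend(
            {
                "case": row["case"],
                "structure": structure,
                "metric": metric,
                "value_without_override": row["without_override"],
                "value_with_override": row["with_override"],
            }
            for _, row in grp.iterrows()
        )
    paired = paired_metric_table(paired_records)

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_cases": config.n_cases,
        "dosimetric_device": target_name,
        "override_factor": comparison.measured_spr / comparison.tps_spr,
        "table1_summary": {
            "mean_spr_percent_diff": table1.mean_percent_diff,
            "min_spr_percent_diff": table1.min_percent_diff,
            "max_spr_percent_diff": table1.max_percent_diff,
            "max_abs_wet_diff_mm": table1.max_abs_wet_diff_mm,
        },
        "dvh_statistics": stats,
    }
    with open(out / "comparison_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        log.info(line)
    return {"report": report, "table1": table1, "dvh": df, "paired": paired}
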