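"""Workflow orchestration: simulate, morphometry, flickering, hemolysis, report.

Ties the stages into the two measurement workflows (bright-field
morphometry of cell fields; high-speed single-cell flickering) plus the
synthetic-data and reporting commands. Every run writes its resolved
configuration next to its outputs, and every CSV carries header comments
stating the convention, temperature and thresholds it was computed under,
so no number is separable from its convention. All outputs are
deterministic given the configuration (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import dynamics as dyn
from . import hemolysis as hemo
from . import morphometry as morpho
from . import segmentation as seg
from . import spectra
from . import stats_report as stats
from . import synthetic as synth
from .errors import FlickerscopeError, SchemaError, TrackingError, UnusableCellError
from .thermal import ThermalContext

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_morpho", "run_flicker",
           "run_hemolysis", "run_report", "read_tiff", "write_tiff"]

_ID_COLUMNS = {"condition", "field_id", "cell_id", "n_angles_used"}


@dataclass
class RunConfig:
    """Resolved configuration shared by all pipeline commands."""

    pixel_size_field: float = 0.103e-6     # m/px, bright-field
    pixel_size_video: float = 50e-9        # m/px, high-speed
    fps: float = 2000.0
    n_angles_field: int = 720
    n_angles_video: int = 1024
    spline_degree_field: int = 12
    spline_degree_video: int = 18
    temperature: float = 310.15
    mode_used: int = 3
    msd_fit_lags: int = 10
    volatility_window_s: float = 0.5
    volatility_stride_s: float = 0.25
    seed: int = 0
    circularity_min: float = 0.9
    radius_window_um: tuple = (7.0, 8.0)
    border_margin: int = 1
    focus_metric_min: float = 0.06

    def __post_init__(self) -> None:
        for name in ("pixel_size_field", "pixel_size_video", "fps", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def thermal(self) -> ThermalContext:
        return ThermalContext(self.temperature)

    @property
    def acceptance(self) -> seg.AcceptanceCriteria:
        return seg.AcceptanceCriteria(
            circularity_min=self.circularity_min,
            radius_window=tuple(self.radius_window_um),
            border_margin=self.border_margin,
            focus_metric_min=self.focus_metric_min,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "radius_window_um" in data:
            data["radius_window_um"] = tuple(data["radius_window_um"])
        return cls(**data)

    def save(self, path) -> None:
        data = dataclasses.asdict(self)
        data["radius_window_um"] = list(data["radius_window_um"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_tiff(path, stack: np.ndarray) -> None:
    """Write float [0, 1] frames as 16-bit grayscale TIFF (multi-page if 3-D)."""
    arr = np.clip(np.asarray(stack, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, (arr * 65535.0 + 0.5).astype(np.uint16))


def read_tiff(path) -> np.ndarray:
    """Read a grayscale TIFF; integer data is rescaled to float [0, 1]."""
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FlickerscopeError(f"cannot read TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def _write_csv(df: pd.DataFrame, path, meta: dict) -> None:
    header = "".join(f"# {k}={v}\n" for k, v in sorted(meta.items()))
    Path(path).write_text(header + df.to_csv(index=False, float_format="%.10g"))


def _csv_meta(config: RunConfig) -> dict:
    return {
        "convention_id": spectra.CONVENTION_ID,
        "temperature_K": config.temperature,
        "circularity_min": config.circularity_min,
        "radius_window_um": list(config.radius_window_um),
        "mode_used": config.mode_used,
    }


def run_simulate(kind: str, out_dir, seed: int = 0, **params) -> dict:
    """Generate a fixture bundle (TIFF/CSV/JSON with ground-truth manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "field":
        spec = synth.make_default_scene(seed=seed, **params)
        img, manifest = synth.generate_field_scene(spec)
        write_tiff(out / "field.tif", img)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"image": str(out / "field.tif"),
                "manifest": str(out / "manifest.json")}
    if kind == "ensemble":
        spec = synth.EnsembleSpec(seed=seed, **params)
        contours, truth = synth.generate_static_ensemble(spec)
        rows = [{"cell_id": c.cell_id, "angle_index": j, "radius_m": rr}
                for c in contours for j, rr in enumerate(c.radii)]
        pd.DataFrame(rows).to_csv(out / "contours.csv", index=False,
                                  float_format="%.12g")
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        return {"contours": str(out / "contours.csv"),
                "truth": str(out / "truth.json")}
    if kind == "video":
        ou = synth.OuSpec(n_angles=params.pop("n_angles", 64),
                          n_frames=params.pop("n_frames", 200),
                          stiffness_true=params.pop("stiffness_true", 1.1e-7),
                          friction_true=params.pop("friction_true", 1e-7),
                          seed=seed)
        field, truth = synth.generate_angle_dynamics(ou)
        optics = synth.VideoOptics(seed=seed, **params)
        stack = synth.render_contour_video(field, optics)
        write_tiff(out / "video.tif", stack)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        return {"video": str(out / "video.tif"), "truth": str(out / "truth.json")}
    if kind == "absorbance":
        df = synth.generate_absorbance(
            blank_sd=params.pop("blank_sd", 0.01),
            hb_level=params.pop("hb_level", 0.0025), seed=seed, **params)
        df.to_csv(out / "absorbance.csv", index=False, float_format="%.10g")
        return {"absorbance": str(out / "absorbance.csv")}
    raise FlickerscopeError(f"unknown simulation kind {kind!r}")


def run_morpho(config: RunConfig, inputs, out_dir, condition: str = "") -> dict:
    """Bright-field morphometry: fields -> per-cell records + acceptance log.

    ``inputs`` is a list of TIFF paths (single- or multi-page; each page is
    one field). Writes morphometry.csv, acceptance_log.csv, summary.json
    (per-field normocyte fraction and an ensemble tension estimate when
    enough cells are accepted) and the resolved configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, log_rows, fractions = [], [], {}
    accepted_contours = []
    for path in inputs:
        pages = read_tiff(path)
        if pages.ndim == 2:
            pages = pages[None]
        for page_idx, raw in enumerate(pages):
            field_id = f"{Path(path).stem}:{page_idx}"
            frame = seg.preprocess(raw)
            level = seg.otsu_threshold(frame)
            accepted, log = seg.detect_and_filter(
                frame, config.acceptance, config.pixel_size_field)
            for rec in log:
                log_rows.append({
                    "condition": condition, "field_id": field_id,
                    "component": rec.label, "centroid_row": rec.centroid[0],
                    "centroid_col": rec.centroid[1], "status": rec.status,
                    "equivalent_radius_um": rec.equivalent_radius_um,
                    "circularity": rec.circularity, "solidity": rec.solidity,
                    "focus_metric": rec.focus_metric,
                })
            fractions[field_id] = (
                morpho.normocyte_fraction(len(accepted), len(log))
                if log else None)
            for rec in accepted:
                contour = seg.extract_contour(
                    frame, rec, n_angles=config.n_angles_field,
                    spline_degree=config.spline_degree_field,
                    pixel_size=config.pixel_size_field, level=level)
                accepted_contours.append(contour)
                m = morpho.measure(contour, condition=condition)
                rows.append({
                    "condition": condition, "field_id": field_id,
                    "cell_id": f"{field_id}/comp{rec.label}",
                    "A_um2": m.area * 1e12, "P_um": m.perimeter * 1e6,
                    "Req_um": m.equivalent_radius * 1e6,
                    "R0_um": m.mean_radius * 1e6,
                    "C": m.circularity, "C_lin": m.circularity_lin,
                    "F": m.form_factor, "E": m.elongation,
                    "a_um": m.semi_axis_major * 1e6,
                    "b_um": m.semi_axis_minor * 1e6,
                    "delta_nm": m.fluct_amplitude * 1e9,
                })
    meta = _csv_meta(config)
    _write_csv(pd.DataFrame(rows), out / "morphometry.csv", meta)
    _write_csv(pd.DataFrame(log_rows), out / "acceptance_log.csv", meta)

    summary = {"normocyte_fraction": fractions, "n_accepted": len(rows)}
    if len(accepted_contours) >= 2:
        ens = spectra.ensemble_spectrum(
            spectra.spectra_from_contours(accepted_contours))
        est = spectra.effective_tension(ens, config.thermal, config.mode_used)
        summary["sigma_eff_N_per_m"] = est.sigma_eff
        summary["tension_n_cells"] = est.n_cells
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    config.save(out / "resolved_config.yaml")
    return summary


def run_flicker(config: RunConfig, inputs, out_dir, condition: str = "") -> pd.DataFrame:
    """High-speed flickering: one video stack per cell -> DynamicsRecord CSV.

    Videos that cannot be tracked or summarized are skipped with a logged
    reason (mirroring the exclusion of unreliable recordings), never
    silently dropped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = seg.TrackParams(pixel_size=config.pixel_size_video, fps=config.fps,
                             n_angles=config.n_angles_video,
                             spline_degree=config.spline_degree_video)
    rows, skipped = [], []
    for path in inputs:
        stack = read_tiff(path)
        try:
            field = seg.track_video(stack, params, cell_id=Path(path).stem)
            rec = dyn.cell_summary(
                field, config.thermal, msd_fit_lags=config.msd_fit_lags,
                window_s=config.volatility_window_s,
                stride_s=config.volatility_stride_s, condition=condition)
        except (TrackingError, UnusableCellError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped.append({"video": str(path), "reason": str(exc)})
            continue
        rows.append({
            "condition": condition, "cell_id": rec.cell_id,
            "keff_N_per_m": rec.k_eff, "D_m2_per_s": rec.D,
            "gamma_kg_per_s": rec.gamma, "omega_c_per_s": rec.omega_c,
            "tau_c_s": rec.tau_c, "volatility_nm": rec.volatility * 1e9,
            "n_angles_used": rec.n_angles_used,
        })
    df = pd.DataFrame(rows)
    _write_csv(df, out / "dynamics.csv", _csv_meta(config))
    (out / "skipped.json").write_text(json.dumps(skipped, indent=2))
    config.save(out / "resolved_config.yaml")
    return df


def run_hemolysis(input_csv, out_dir, condition: str = "",
                  timepoint: str = "") -> hemo.HemolysisResult:
    """Hemolysis readout from an absorbance CSV in the standard schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(input_csv, comment="#")
    result = hemo.evaluate_records(records, condition=condition,
                                   timepoint=timepoint)
    pd.DataFrame([{
        "condition": result.condition, "timepoint": result.timepoint,
        "percent": result.percent, "lod_percent": result.lod_percent,
        "below_lod": result.below_lod,
    }]).to_csv(out / "hemolysis.csv", index=False, float_format="%.10g")
    return result


def run_report(config: RunConfig, percell_csvs, out_dir,
               pairs=None, holm: bool = False) -> pd.DataFrame:
    """Statistical report over per-cell tables from prior commands.

    Concatenates the tables (which must share a ``condition`` column), runs
    Kruskal-Wallis plus planned pairwise Mann-Whitney tests per numeric
    descriptor, and writes a long-format comparison CSV, a property-by-pair
    label matrix, per-group median/IQR summaries, and (when k_eff/omega_c
    columns are present) the mechanical-plane table and trend fit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = [pd.read_csv(p, comment="#") for p in percell_csvs]
    if not tables:
        raise SchemaError("no per-cell tables given")
    df = pd.concat(tables, ignore_index=True)
    if "condition" not in df.columns:
        raise SchemaError("per-cell tables are missing the 'condition' column")
    descriptors = [c for c in df.columns
                   if c not in _ID_COLUMNS and pd.api.types.is_numeric_dtype(df[c])]
    if not descriptors:
        raise SchemaError("no numeric descriptor columns found")

    long_rows, summary_rows = [], []
    for col in descriptors:
        groups = {str(cond): grp[col].dropna().to_numpy()
                  for cond, grp in df.groupby("condition") if grp[col].notna().sum() >= 3}
        for cond, vals in groups.items():
            med, iqr = stats.summarize(vals)
            summary_rows.append({"descriptor": col, "condition": cond,
                                 "n": len(vals), "median": med, "iqr": iqr})
        if len(groups) < 2:
            continue
        for comp in stats.compare_groups(groups, pairs=pairs, holm=holm):
            long_rows.append({"descriptor": col, "test": comp.test,
                              "group_a": comp.group_a, "group_b": comp.group_b,
                              "statistic": comp.statistic, "p": comp.p,
                              "label": comp.label})
    long_df = pd.DataFrame(long_rows)
    meta = _csv_meta(config)
    _write_csv(long_df, out / "comparisons_long.csv", meta)
    _write_csv(pd.DataFrame(summary_rows), out / "summaries.csv", meta)

    if not long_df.empty:
        pw = long_df[long_df["test"] == "mann_whitney"].copy()
        if not pw.empty:
            pw["pair"] = pw["group_a"] + " vs " + pw["group_b"]
            matrix = pw.pivot(index="descriptor", columns="pair", values="label")
            _write_csv(matrix.reset_index(), out / "comparisons_matrix.csv", meta)

    if {"keff_N_per_m", "omega_c_per_s"} <= set(df.columns):
        recs = [dyn.DynamicsRecord(
                    k_eff=r.keff_N_per_m, D=r.D_m2_per_s, gamma=r.gamma_kg_per_s,
                    omega_c=r.omega_c_per_s, tau_c=r.tau_c_s,
                    volatility=r.volatility_nm * 1e-9,
                    n_angles_used=int(r.n_angles_used), cell_id=str(r.cell_id),
                    condition=str(r.condition))
                for r in df.dropna(subset=["keff_N_per_m"]).itertuples()]
        table, fit = stats.mech_plane(recs)
        _write_csv(table, out / "mech_plane.csv", meta)
        (out / "mech_fit.json").write_text(
            json.dumps({"fit": fit, "skipped": fit is None}, indent=2))
    config.save(out / "resolved_config.yaml")
    return long_df
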