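"""End-to-end orchestration: simulate -> quality gate -> segment -> measure
-> detect cysts -> analyze, each stage writing a plain-text artifact.

Every CSV/JSON artifact carries the config hash and seed (sidecar
``run_info.json``); the whole run is deterministic given the config.  A
stage failure halts the run with the stage name and the offending
subject/eye; artifacts written so far are retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bscan import BScan, load_bscan_tiff, save_bscan_tiff
from .cohort import CohortSpec, SubjectRecord, simulate_cohort
from .config import PipelineConfig
from .microcysts import cohort_cyst_summary, detect_microcysts, merge_eye_cysts
from .sampling import eye_summary, sample_grid
from .segmentation import quality_check, segment_bscan
from . import stats as st

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    pass


def _write_csv(df: pd.DataFrame, path: Path, header_note: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write(f"# {header_note}\n")
        df.to_csv(f, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass
class EyeInput:
    subject: str
    role: str
    group: str
    laterality: str
    scans: list[BScan]
    has_cysts_truth: bool | None = None
    binocular: bool = False
    duration_on_to_oct_months: float | None = None
    duration_ms_months: float | None = None


def _eyes_from_records(records: list[SubjectRecord]) -> list[EyeInput]:
    out = []
    for rec in records:
        for role, eye in rec.eyes.items():
            out.append(
                EyeInput(
                    subject=rec.subject,
                    role=role,
                    group=rec.group,
                    laterality=eye.laterality,
                    scans=eye.scans,
                    has_cysts_truth=eye.has_cysts,
                    binocular=rec.binocular,
                    duration_on_to_oct_months=rec.duration_on_to_oct_months,
                    duration_ms_months=rec.duration_ms_months,
                )
            )
    return out


def _eyes_from_dir(input_dir: Path, config: PipelineConfig) -> list[EyeInput]:
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise StageError(f"stage load: metadata CSV missing at {meta_path}")
    meta = _read_csv(meta_path)
    required = {"subject", "role", "group", "laterality"}
    if not required <= set(meta.columns):
        raise StageError(
            f"stage load: metadata CSV missing columns {sorted(required - set(meta.columns))}"
        )
    eyes = []
    for _, row in meta.iterrows():
        scans = []
        for k in range(config.protocol.n_slices):
            p = input_dir / "scans" / f"{row.subject}_{row.role}_slice{k}.tif"
            if not p.exists():
                raise StageError(f"stage load: missing scan {p}")
            try:
                scans.append(
                    load_bscan_tiff(p, slice_index=k, laterality=row.laterality)
                )
            except Exception as e:  # corrupt image: halt naming the file
                raise StageError(f"stage load: corrupt image {p}: {e}") from e
        eyes.append(
            EyeInput(
                subject=str(row.subject),
                role=str(row.role),
                group=str(row.group),
                laterality=str(row.laterality),
                scans=scans,
                binocular=bool(row.get("binocular", False)),
                duration_on_to_oct_months=row.get("duration_on_to_oct_months"),
                duration_ms_months=row.get("duration_ms_months"),
            )
        )
    return eyes


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
) -> dict:
    """Run the full chain; returns the report dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    info = {"config_hash": config.config_hash(), "rng_seed": config.rng_seed}
    config.to_yaml(out / "config.yaml")
    (out / "run_info.json").write_text(json.dumps(info, indent=2))
    note = f"config_hash={info['config_hash']} seed={config.rng_seed}"
    counters = {"eyes_total": 0, "eyes_passed_quality": 0,
                "boundaries_failed": 0, "cysts_found": 0}

    # --- stage: simulate or load -------------------------------------------
    if input_dir is None:
        sim = config.simulate
        spec = CohortSpec(
            n_per_group=sim.n_per_group,
            cyst_prevalence=sim.cyst_prevalence,
            eye_model=sim.eye_model,
            eye_coupling=sim.eye_coupling,
            n_binocular=sim.n_binocular,
            cyst_spec=config.cyst_injection,
            rng_seed=config.rng_seed,
        )
        records, truth = simulate_cohort(
            spec, render=True, acq=config.acquisition, protocol=config.protocol
        )
        eyes = _eyes_from_records(records)
        _write_csv(truth, out / "truth" / "cohort.csv", f"ground truth; {note}")
        scan_dir = out / "scans"
        btr = []
        mask_dir = out / "truth" / "cyst_masks"
        for rec in records:
            for role, eyedata in rec.eyes.items():
                for k, s in enumerate(eyedata.scans):
                    save_bscan_tiff(s, scan_dir / f"{rec.subject}_{role}_slice{k}.tif")
                    t = eyedata.boundary_truth[k]
                    cols = np.arange(len(t["ILM"]))
                    for name, depth in t.items():
                        btr.append(pd.DataFrame({
                            "subject": rec.subject, "role": role, "slice": k,
                            "column_px": cols, "boundary": name, "row_px": depth,
                        }))
                    m = eyedata.cyst_masks[k]
                    if m is not None and m.any():
                        import imageio.v3 as iio
                        mask_dir.mkdir(parents=True, exist_ok=True)
                        iio.imwrite(
                            mask_dir / f"{rec.subject}_{role}_slice{k}.png",
                            (m.astype(np.uint8) * 255),
                        )
        _write_csv(pd.concat(btr, ignore_index=True),
                   out / "truth" / "boundaries.csv",
                   f"ground-truth boundaries, px; {note}")
        meta = truth.rename(columns={})
        _write_csv(meta, out / "metadata.csv", f"per-eye metadata; {note}")
    else:
        eyes = _eyes_from_dir(Path(input_dir), config)

    # --- stages: quality, segment, measure, cysts --------------------------
    quality_rows, seg_rows, grid_rows, cyst_rows, summary_rows = [], [], [], [], []
    eye_sets = {}
    for e in eyes:
        counters["eyes_total"] += 1
        eye_id = f"{e.subject}/{e.role}"
        try:
            reports = [quality_check(s, config.quality) for s in e.scans]
        except Exception as exc:
            raise StageError(f"stage quality failed for {eye_id}: {exc}") from exc
        passed = all(r.passed for r in reports)
        counters["eyes_passed_quality"] += int(passed)
        for k, r in enumerate(reports):
            quality_rows.append(
                {"subject": e.subject, "role": e.role, "slice": k,
                 "snr_db": r.snr_db, "centration_offset_um": r.centration_offset_um,
                 "brightness_uniformity": r.brightness_uniformity,
                 "passed": r.passed}
            )
        if config.fail_on_quality and not passed:
            raise StageError(f"stage quality: {eye_id} failed the quality gate")

        try:
            boundaries = [segment_bscan(s, config.segmentation) for s in e.scans]
        except Exception as exc:
            raise StageError(f"stage segment failed for {eye_id}: {exc}") from exc
        for k, lb in enumerate(boundaries):
            counters["boundaries_failed"] += sum(lb.failed.values())
            cols = np.arange(len(lb.depths["ILM"]))
            for name, depth in lb.depths.items():
                seg_rows.append(
                    pd.DataFrame(
                        {
                            "subject": e.subject,
                            "role": e.role,
                            "slice": k,
                            "column_px": cols,
                            "boundary": name,
                            "row_px": depth,
                            "provenance": np.where(
                                lb.provenance, "interpolated", "traced"
                            ),
                        }
                    )
                )

        try:
            grid = sample_grid(
                boundaries,
                config.protocol,
                e.scans[0].axial_um_per_px,
                e.scans[0].lateral_um_per_px,
                laterality=e.laterality,
                subject=e.subject,
                eye=e.role,
            )
        except Exception as exc:
            raise StageError(f"stage measure failed for {eye_id}: {exc}") from exc
        g = grid.table.copy()
        g.insert(0, "subject", e.subject)
        g.insert(1, "role", e.role)
        grid_rows.append(g)
        summ = eye_summary(grid)

        try:
            per_slice = [
                detect_microcysts(s, lb, config.cyst_detection, config.protocol)
                for s, lb in zip(e.scans, boundaries)
            ]
        except Exception as exc:
            raise StageError(f"stage detect-cysts failed for {eye_id}: {exc}") from exc
        eye_set = merge_eye_cysts(per_slice, subject=e.subject, eye=e.role)
        counters["cysts_found"] += eye_set.count
        eye_sets[eye_id] = eye_set
        c = eye_set.cysts.copy()
        if len(c):
            c.insert(0, "subject", e.subject)
            c.insert(1, "role", e.role)
            cyst_rows.append(c)

        summary_rows.append(
            {
                "subject": e.subject,
                "group": e.group,
                "role": e.role,
                "laterality": e.laterality,
                **{f"{l}_um": summ.mean_um[l] for l in st.LAYERS},
                "n_invalid": summ.n_invalid,
                "analyzable": summ.analyzable,
                "quality_passed": passed,
                "has_cysts": eye_set.has_microcysts,
                "binocular": e.binocular,
                "duration_on_to_oct_months": e.duration_on_to_oct_months,
                "duration_ms_months": e.duration_ms_months,
            }
        )

    _write_csv(pd.DataFrame(quality_rows), out / "quality.csv",
               f"scan quality reports; {note}")
    _write_csv(pd.concat(seg_rows, ignore_index=True),
               out / "segmentation" / "boundaries.csv",
               f"traced boundaries, row 0 = vitreous; {note}")
    _write_csv(pd.concat(grid_rows, ignore_index=True),
               out / "measurements" / "thickness.csv",
               f"36-point grid, um; {note}")
    eye_table = pd.DataFrame(summary_rows)
    _write_csv(eye_table, out / "measurements" / "eye_summaries.csv",
               f"per-eye layer means, um; {note}")
    cysts_df = (pd.concat(cyst_rows, ignore_index=True) if cyst_rows
                else pd.DataFrame())
    _write_csv(cysts_df, out / "cysts" / "cysts.csv", f"detected cysts; {note}")

    # --- stage: analyze -----------------------------------------------------
    report = {"run_info": info, "counters": counters}
    try:
        analyzable = eye_table[eye_table.analyzable]
        ctrl = analyzable[analyzable.role == "control"]
        on = analyzable[analyzable.role == "ON"]
        if len(ctrl) >= 2 and len(on) >= 2:
            report["group_comparison"] = {
                l: vars(st.group_compare(ctrl[f"{l}_um"], on[f"{l}_um"],
                                         equal_var=config.stats.equal_var))
                for l in st.LAYERS
            }
        if len(ctrl) >= 3 and len(on) >= 3:
            report["correlations"] = {
                "control": st.layer_correlations(analyzable, "control").to_dict("records"),
                "ON": st.layer_correlations(analyzable, "ON").to_dict("records"),
            }
        if (analyzable.role == "fellow").sum() >= 3:
            asym = st.asymmetry_analysis(analyzable)
            report["asymmetry"] = {
                "r": asym.r, "p": asym.p,
                "n_excluded_binocular": asym.n_excluded_binocular,
            }
            _write_csv(asym.records, out / "report" / "asymmetry_scatter.csv",
                       f"affected - fellow differences, um; {note}")
        on_sets = [eye_sets[f"{s}/ON"] for s in on.subject if f"{s}/ON" in eye_sets]
        if on_sets:
            cs = cohort_cyst_summary(on_sets, config.protocol)
            report["microcysts"] = vars(cs)
        grids = pd.concat(grid_rows, ignore_index=True)
        dev = st.pointwise_deviation(
            grids[grids.role == "control"], grids[grids.role == "ON"],
            protocol=config.protocol,
        )
        report["topography"] = {"r": dev.r, "p": dev.p, "n_points": dev.n_points,
                                "sign_convention": dev.sign_convention}
        _write_csv(dev.table, out / "report" / "deviation_map.csv",
                   f"{dev.sign_convention}; {note}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage analyze failed: {exc}") from exc

    (out / "report").mkdir(parents=True, exist_ok=True)
    (out / "report" / "report.json").write_text(
        json.dumps(report, indent=2, default=float)
    )
    return report
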