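"""End-to-end pipeline orchestration.

``run_pipeline`` executes simulate (or load) -> classify -> describe ->
internal validation -> external validation, writes all report files into
the output directory, and records a machine-readable manifest (inputs,
seed, package version, row counts at each stage).  A stage failure aborts
the run with the stage name and removes the files written by this run, so
an output directory never holds a partial, inconsistent report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as edio
from .describe import descriptive_table
from .external import external_ratios
from .internal import (
    GoldStandardSpec,
    all_metrics,
    case_series,
    confusion,
    gold_labels,
    moving_average,
    rolling_metrics,
)
from .records import link_cases
from .rules import INDICATORS, builtin_rules, classify_cohort
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.6f"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """What to run and where.

    Either ``simulate`` holds a generator configuration (the cohort is drawn
    and written under ``out_dir/data``), or the three input paths point at
    existing CSV files.  ``seed`` overrides the generator config's seed.
    """

    out_dir: Path
    simulate: GeneratorConfig | None = None
    ed_path: Path | None = None
    inpatient_path: Path | None = None
    hospital_stats_path: Path | None = None
    restrict_years: tuple[int, ...] = (2019, 2020)
    gold_scope: str = "any_diagnosis"
    skip_external: bool = False
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            out_dir=Path(d["out_dir"]),
            simulate=GeneratorConfig.from_dict(d["simulate"]) if d.get("simulate") else None,
            ed_path=Path(d["ed_path"]) if d.get("ed_path") else None,
            inpatient_path=Path(d["inpatient_path"]) if d.get("inpatient_path") else None,
            hospital_stats_path=Path(d["hospital_stats_path"]) if d.get("hospital_stats_path") else None,
            restrict_years=tuple(d.get("restrict_years", (2019, 2020))),
            gold_scope=d.get("gold_scope", "any_diagnosis"),
            skip_external=bool(d.get("skip_external", False)),
            seed=d.get("seed"),
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "package": "edsynd",
        "version": __version__,
        "seed": config.seed if config.seed is not None else (
            config.simulate.seed if config.simulate else None
        ),
        "inputs": {},
        "stages": {},
    }

    def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
        df.to_csv(path, float_format=_FLOAT_FMT, **kw)
        written.append(path)

    def _fail(stage: str, exc: BaseException) -> None:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    # -- stage: data -------------------------------------------------------
    stage = "data"
    try:
        if config.simulate is not None:
            bundle = generate_cohort(config.simulate, seed=config.seed)
            datadir = out / "data"
            paths = bundle.write(datadir)
            written.extend(paths.values())
            attendances, inpatient = bundle.attendances, bundle.inpatient
            hospital_stats = bundle.hospital_stats
            manifest["inputs"] = {k: str(v) for k, v in paths.items()}
        else:
            if config.ed_path is None or config.inpatient_path is None:
                raise ValueError("need ed_path and inpatient_path when not simulating")
            attendances = edio.read_ed_table(config.ed_path)
            inpatient = edio.read_inpatient_table(config.inpatient_path)
            hospital_stats = (
                edio.read_hospital_stats(config.hospital_stats_path)
                if config.hospital_stats_path
                else None
            )
            manifest["inputs"] = {
                "ed": str(config.ed_path),
                "inpatient": str(config.inpatient_path),
                "hospital_stats": str(config.hospital_stats_path or ""),
            }
        manifest["stages"]["data"] = {
            "attendances": len(attendances),
            "inpatient_records": len(inpatient),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail(stage, exc)

    # -- stage: classify ---------------------------------------------------
    stage = "classify"
    try:
        rules = builtin_rules()
        labels = classify_cohort(attendances, rules)
        _write_csv(labels, out / "labels.csv")
        manifest["stages"]["classify"] = {
            ind.lower(): int(labels[ind.lower()].sum()) for ind in INDICATORS
        }
    except Exception as exc:
        _fail(stage, exc)

    # -- stage: describe ---------------------------------------------------
    stage = "describe"
    try:
        desc = descriptive_table(attendances, labels)
        _write_csv(desc, out / "descriptive.csv", index=False)
        manifest["stages"]["describe"] = {"rows": len(desc)}
    except Exception as exc:
        _fail(stage, exc)

    # -- stage: internal validation ---------------------------------------
    stage = "internal"
    try:
        linked = link_cases(attendances, inpatient)
        gold = gold_labels(linked, GoldStandardSpec(scope=config.gold_scope))
        linked_ids = gold.index
        dates = {a.attendance_id: a.admission_date for a in attendances}
        period = (
            min(dates.values()),
            max(dates.values()),
        )
        metric_rows, confusion_rows = [], []
        for ind in INDICATORS:
            col = ind.lower()
            lab = labels.loc[linked_ids, col]
            cm = confusion(lab, gold[col])
            confusion_rows.append(
                {"indicator": ind, "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
            )
            for name, est in all_metrics(cm).items():
                metric_rows.append(
                    {
                        "indicator": ind,
                        "metric": name,
                        "value": est.value,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "numerator": est.numerator,
                        "denominator": est.denominator,
                    }
                )
            # positive-case tabulation and the two daily series
            pos_cases = [c for c in linked if bool(lab.loc[c.attendance.attendance_id])]
            from .internal import top_discharge_groups  # local to keep import graph flat

            _write_csv(top_discharge_groups(pos_cases, k=10), out / f"top_groups_{col}.csv", index=False)
            ed_dates = [dates[i] for i in labels.index[labels[col]]]
            gold_dates = [dates[i] for i in gold.index[gold[col]]]
            series = pd.DataFrame(
                {
                    "ed_cases": case_series(ed_dates, period),
                    "gold_cases": case_series(gold_dates, period),
                }
            )
            series["ed_ma7"] = moving_average(series["ed_cases"])
            series["gold_ma7"] = moving_average(series["gold_cases"])
            _write_csv(series, out / f"series_{col}.csv", index_label="date")
            rolled = rolling_metrics(lab, gold[col], dates)
            _write_csv(rolled, out / f"rolling_{col}.csv", index=False)
        _write_csv(pd.DataFrame(metric_rows), out / "metrics.csv", index=False)
        _write_csv(pd.DataFrame(confusion_rows), out / "confusion.csv", index=False)
        manifest["stages"]["internal"] = {"linked": len(linked)}
    except Exception as exc:
        _fail(stage, exc)

    # -- stage: external validation ---------------------------------------
    stage = "external"
    try:
        if config.skip_external or hospital_stats is None or len(hospital_stats) == 0:
            manifest["stages"]["external"] = {"skipped": True}
        else:
            by_id = {a.attendance_id: a for a in attendances}
            frames = []
            for ind in INDICATORS:
                pos = [by_id[i] for i in labels.index[labels[ind.lower()]]]
                frames.append(
                    external_ratios(pos, hospital_stats, ind, config.restrict_years)
                )
            _write_csv(pd.concat(frames, ignore_index=True), out / "ratios.csv", index=False)
            manifest["stages"]["external"] = {"strata": sum(len(f) for f in frames)}
    except Exception as exc:
        _fail(stage, exc)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
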