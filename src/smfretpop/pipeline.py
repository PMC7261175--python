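"""End-to-end orchestration: QC -> FRET -> histogram -> fit -> comparison.

Each condition is supplied as one or more replicate trace sets (separate
experiments are the replicates for statistics). Per replicate the pipeline
selects traces, computes apparent FRET series, builds the smoothed
normalized histogram, decomposes it into Gaussians and records the
closed-state fraction; conditions are then compared pairwise with Welch's
t-test on the replicate closed fractions. All outputs are plain CSV/JSON
plus a text summary, and a fixed configuration and input yield
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptySeriesError, PipelineError, SmFretError, UnclassifiableError
from .fret import classify_dynamic, compute_fret, fraction_dynamic
from .histogram import build_histogram, fit_components
from .popstats import welch_t_test
from .qc import QCConfig, qc_all, qc_table
from .trace_io import TraceSet, read_trace_binary, read_trace_csv

log = logging.getLogger("smfretpop")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the traces themselves."""

    seed: int = 0
    bin_width: float = 0.02
    hist_range: tuple[float, float] = (-0.1, 1.1)
    weighting: str = "frame"
    centers_init: tuple[float, float] = (0.4, 0.6)
    width_max: float = 0.14
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    qc: QCConfig = field(default_factory=QCConfig)
    outdir: str = "smfretpop_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        qc = QCConfig(**d.pop("qc", {}))
        if "hist_range" in d:
            d["hist_range"] = tuple(d["hist_range"])
        if "centers_init" in d:
            d["centers_init"] = tuple(d["centers_init"])
        return cls(qc=qc, **d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(data)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def analyze_traceset(trace_set: TraceSet, config: PipelineConfig) -> dict:
    """QC, FRET, histogram and Gaussian fit for one replicate trace set.

    Returns a dict with the QC table, FRET series, histogram, fit and
    per-replicate summary statistics.
    """
    results = qc_all(trace_set, config.qc)
    table = qc_table(results)
    by_id = {res.trace_id: res for res in results}
    accepted = trace_set.subset([res.trace_id for res in results if res.accepted])
    series = []
    for tr in accepted:
        qc_res = by_id[tr.trace_id]
        try:
            fs = compute_fret(
                tr, qc_res, config.background_donor, config.background_acceptor
            )
        except EmptySeriesError:
            continue
        try:
            classify_dynamic(fs)
        except UnclassifiableError:
            pass
        series.append(fs)
    if not series:
        raise PipelineError("no analyzable traces after QC")
    hist = build_histogram(series, config.bin_width, config.hist_range, config.weighting)
    fit = fit_components(hist, config.centers_init, config.width_max)
    classified = [s for s in series if s.is_dynamic is not None]
    if classified:
        frac_dyn, ci = fraction_dynamic(classified)
    else:
        frac_dyn, ci = float("nan"), (float("nan"), float("nan"))
    return {
        "qc_table": table,
        "series": series,
        "histogram": hist,
        "fit": fit,
        "closed_fraction": fit.closed_fraction,
        "fraction_dynamic": frac_dyn,
        "fraction_dynamic_ci": ci,
        "n_accepted": len(accepted),
        "n_total": len(trace_set),
    }


def run_pipeline(config: PipelineConfig, inputs: dict[str, list[TraceSet]]) -> dict:
    """Run the full analysis for every condition and write the report bundle.

    ``inputs`` maps condition label -> list of replicate trace sets. Emits,
    under ``config.outdir``: per-condition QC/FRET/histogram CSVs, a fit
    JSON, a cross-condition comparison JSON, and a plain-text summary.
    """
    if not inputs:
        raise PipelineError("no input conditions supplied")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"conditions": {}, "comparisons": []}

    for condition, replicates in inputs.items():
        if not replicates or all(len(ts) == 0 for ts in replicates):
            raise PipelineError(f"condition {condition!r}: empty input")
        cond_dir = outdir / condition
        cond_dir.mkdir(parents=True, exist_ok=True)
        closed_fractions = []
        qc_frames, fret_rows, fit_records = [], [], []
        for i, ts in enumerate(replicates):
            try:
                res = analyze_traceset(ts, config)
            except SmFretError as exc:
                raise PipelineError(
                    f"stage failure in condition {condition!r}, replicate {i}: {exc}"
                ) from exc
            closed_fractions.append(res["closed_fraction"])
            qc = res["qc_table"].copy()
            qc.insert(0, "replicate", i)
            qc_frames.append(qc)
            for s in res["series"]:
                fret_rows.append(
                    pd.DataFrame(
                        {"replicate": i, "trace_id": s.trace_id, "frame": s.frames,
                         "e_app": s.e_app}
                    )
                )
            hist = res["histogram"]
            pd.DataFrame(
                {"bin_center": hist.bin_centers, "raw": hist.raw_counts,
                 "smoothed": hist.smoothed, "normalized": hist.normalized}
            ).to_csv(cond_dir / f"hist_rep{i}.csv", index=False, float_format="%.6g")
            fit_records.append(
                {
                    "replicate": i,
                    "model_choice": res["fit"].model_choice,
                    "residual_rms": res["fit"].residual_rms,
                    "closed_fraction": res["fit"].closed_fraction,
                    "components": [asdict(c) for c in res["fit"].components],
                    "fraction_dynamic": res["fraction_dynamic"],
                    "fraction_dynamic_ci": list(res["fraction_dynamic_ci"]),
                    "n_accepted": res["n_accepted"],
                    "n_total": res["n_total"],
                }
            )
            log.info(
                "condition=%s replicate=%d traces=%d accepted=%d closed_fraction=%.3f",
                condition, i, res["n_total"], res["n_accepted"], res["closed_fraction"],
            )
        pd.concat(qc_frames, ignore_index=True).to_csv(
            cond_dir / "qc.csv", index=False, float_format="%.6g"
        )
        pd.concat(fret_rows, ignore_index=True).to_csv(
            cond_dir / "fret.csv", index=False, float_format="%.6g"
        )
        _json_dump({"replicates": fit_records}, cond_dir / "fit.json")
        report["conditions"][condition] = {
            "closed_fractions": closed_fractions,
            "mean_closed_fraction": float(np.mean(closed_fractions)),
        }

    labels = list(inputs)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            fa = report["conditions"][a]["closed_fractions"]
            fb = report["conditions"][b]["closed_fractions"]
            if len(fa) >= 2 and len(fb) >= 2:
                cmp_res = welch_t_test(fa, fb)
                report["comparisons"].append(
                    {"condition_a": a, "condition_b": b, "t": cmp_res.t,
                     "df": cmp_res.df, "p": cmp_res.p, "label": cmp_res.label}
                )
    _json_dump(report["comparisons"], outdir / "comparisons.json")
    _json_dump(report["conditions"], outdir / "closed_fractions.json")

    lines = ["smfretpop pipeline summary", ""]
    for condition in labels:
        info = report["conditions"][condition]
        fr = ", ".join(f"{v:.3f}" for v in info["closed_fractions"])
        lines.append(
            f"{condition}: closed fraction {info['mean_closed_fraction']:.3f} "
            f"(replicates: {fr})"
        )
    for c in report["comparisons"]:
        lines.append(
            f"{c['condition_a']} vs {c['condition_b']}: "
            f"t={c['t']:.3f}, df={c['df']:.2f}, p={c['p']:.3g} ({c['label']})"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


def load_traceset(path, fmt: str = "csv", condition: str = "") -> TraceSet:
    """Read a trace set in either supported format."""
    if fmt == "csv":
        return read_trace_csv(path, condition)
    if fmt == "traces":
        return read_trace_binary(path, condition)
    raise ValueError(f"unknown format {fmt!r}")
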