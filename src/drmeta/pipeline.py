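"""End-to-end pipeline: study table in, pooled dose-response report out.

Stages: dose assignment → within-study covariance reconstruction →
per-study linear and spline GLS fits → fixed-effect combination of
within-study strata → cross-study pooling (fixed and random effects) →
heterogeneity with the I² confidence interval → nonlinearity Wald test →
Egger/Begg funnel diagnostics → leave-one-out sensitivity → predicted RR
curve anchored at the reference dose.

Artifacts: ``summary.json`` (all statistics), ``curve.tsv``,
``per_study.tsv``, ``funnel.tsv``, and ``manifest.json``.  The summary is
a pure function of (input bytes, config): reruns are byte-identical;
manifests differ only in timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from collections import defaultdict

import numpy as np
import pandas as pd

from . import __version__
from .bias_sensitivity import bias_report, leave_one_out
from .dose_assignment import DoseRule, assign_all
from .gl_reconstruction import study_covariance
from .meta_pooling import PooledResult, nonlinearity_test, pool_fixed, pool_random
from .study_io import (
    RunConfig,
    StudyRecord,
    read_study_table,
    validate_all,
    write_results,
)
from .trend_models import (
    SplineSpec,
    TrendFit,
    combine_strata,
    gls_fit,
    per_increment,
    place_knots,
    predict_curve,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _pooled_block(p: PooledResult, increment: float, ci_level: float) -> dict:
    block = {
        "method": p.method,
        "model": p.model,
        "beta": p.beta.tolist(),
        "se": p.se.tolist(),
        "tau2": p.tau2,
        "Q": p.Q,
        "df": p.df,
        "p_Q": float(f"{p.p_Q:.4g}"),
        "i2_percent": p.i2,
        "i2_ci_percent": list(p.i2_ci) if p.i2_ci is not None else None,
        "k": p.k,
    }
    if p.model == "linear":
        rr, lo, hi = per_increment(
            float(p.beta[0]), float(p.cov_beta[0, 0]), increment, ci_level
        )
        block["rr_per_increment"] = rr
        block["rr_ci"] = [lo, hi]
        block["increment"] = increment
    return block


def analyze_studies(studies: list[StudyRecord], config: RunConfig) -> dict:
    """Run every analysis stage on validated records; returns the summary
    dict plus dataframes under keys ``curve_table``, ``per_study_table``,
    ``funnel_table`` (the caller strips those before serialization)."""
    findings = validate_all(studies)
    if findings:
        raise PipelineError(
            "validate", "; ".join(str(f) for f in findings[:5])
            + (f" (+{len(findings) - 5} more)" if len(findings) > 5 else "")
        )

    rule = DoseRule(strategy=config.dose_strategy, open_interval=config.open_interval)
    try:
        assigned = [assign_all(s, rule) for s in studies]
    except Exception as exc:
        raise PipelineError("dose_assignment", str(exc)) from exc

    try:
        spec = place_knots(assigned, config.knot_percentiles)
    except Exception as exc:
        raise PipelineError("knots", str(exc)) from exc

    linear_by_study: dict[str, list[TrendFit]] = defaultdict(list)
    spline_by_study: dict[str, list[TrendFit]] = defaultdict(list)
    per_study_rows = []
    for s in assigned:
        try:
            lrr = study_covariance(
                s, config.ci_level, tol=config.tol, max_iter=config.max_iter
            )
            lin = gls_fit(s, lrr, model="linear")
            spl = gls_fit(s, lrr, model="spline", spec=spec)
        except Exception as exc:
            raise PipelineError(
                "per_study_fit", f"study {s.study_id}/{s.stratum_id}: {exc}"
            ) from exc
        linear_by_study[s.study_id].append(lin)
        spline_by_study[s.study_id].append(spl)
        rr, lo, hi = per_increment(
            float(lin.beta[0]),
            float(lin.cov_beta[0, 0]),
            config.increment,
            config.ci_level,
        )
        per_study_rows.append(
            {
                "study_id": s.study_id,
                "stratum_id": s.stratum_id,
                "slope_per_unit": float(lin.beta[0]),
                "slope_se": float(lin.se[0]),
                "rr_per_increment": rr,
                "rr_ci_low": lo,
                "rr_ci_high": hi,
            }
        )

    linear_fits = [combine_strata(v) for v in linear_by_study.values()]
    spline_fits = [combine_strata(v) for v in spline_by_study.values()]

    try:
        lin_fixed = pool_fixed(linear_fits, config.ci_level)
        lin_random = pool_random(linear_fits, config.ci_level)
        spl_fixed = pool_fixed(spline_fits, config.ci_level)
        spl_random = pool_random(spline_fits, config.ci_level)
    except Exception as exc:
        raise PipelineError("pooling", str(exc)) from exc

    p_nonlin_fixed = nonlinearity_test(spl_fixed)
    p_nonlin_random = nonlinearity_test(spl_random)

    try:
        bias = bias_report(linear_fits)
        loo = leave_one_out(
            linear_fits, config.increment, config.ci_level, method="random"
        )
    except Exception as exc:
        raise PipelineError("bias_sensitivity", str(exc)) from exc

    doses = [c.dose_assigned for s in assigned for c in s.categories]
    lo_d, hi_d = min(doses), max(doses)
    ref_dose = config.reference_dose if config.reference_dose is not None else lo_d
    grid = np.linspace(lo_d, hi_d, config.curve_points)
    pooled_spline = spl_random if config.pooling_model == "random" else spl_fixed
    curve = predict_curve(
        pooled_spline.beta,
        pooled_spline.cov_beta,
        ref_dose,
        grid,
        spec=spec,
        ci_level=config.ci_level,
    )

    summary = {
        "config": config.to_dict(),
        "n_studies": len(linear_fits),
        "n_strata": len(assigned),
        "dose_range": [lo_d, hi_d],
        "reference_dose": ref_dose,
        "knots": list(spec.knots),
        "pooling": {
            "linear_fixed": _pooled_block(lin_fixed, config.increment, config.ci_level),
            "linear_random": _pooled_block(lin_random, config.increment, config.ci_level),
            "spline_fixed": _pooled_block(spl_fixed, config.increment, config.ci_level),
            "spline_random": _pooled_block(spl_random, config.increment, config.ci_level),
            "p_nonlinearity_fixed": float(f"{p_nonlin_fixed:.4g}"),
            "p_nonlinearity_random": float(f"{p_nonlin_random:.4g}"),
        },
        "bias": {
            "egger_intercept": bias.egger_intercept,
            "egger_se": bias.egger_se,
            "egger_p": float(f"{bias.egger_p:.4g}"),
            "begg_tau": bias.begg_tau,
            "begg_p": float(f"{bias.begg_p:.4g}"),
            "k": bias.k,
        },
        "sensitivity": {
            "leave_one_out": [
                {
                    "omitted": r.omitted,
                    "rr_per_increment": r.rr,
                    "rr_ci": [r.ci_low, r.ci_high],
                }
                for r in loo
            ],
            "rr_min": min(r.rr for r in loo),
            "rr_max": max(r.rr for r in loo),
        },
        "curve_table": pd.DataFrame(
            [(p.dose, p.rr, p.ci_low, p.ci_high) for p in curve],
            columns=["dose", "rr", "ci_low", "ci_high"],
        ),
        "per_study_table": pd.DataFrame(per_study_rows),
        "funnel_table": pd.DataFrame(
            bias.funnel, columns=["study_id", "effect", "se"]
        ),
    }
    return summary


def run_pipeline(input_path: str, config: RunConfig, out_dir: str) -> dict:
    """Execute the full pipeline on a study table; returns the run manifest.

    On any stage failure, partial outputs already written to ``out_dir``
    are removed and a stage-named :class:`PipelineError` is raised.
    """
    t0 = time.monotonic()
    timings: dict[str, float] = {}
    with open(input_path, "rb") as fh:
        digest = hashlib.sha256(fh.read()).hexdigest()

    # capture inner-module warnings so each appears exactly once in the manifest
    captured: list[str] = []

    class _Collector(logging.Handler):
        def emit(self, record: logging.LogRecord) -> None:
            if record.levelno >= logging.WARNING:
                msg = record.getMessage()
                if msg not in captured:
                    captured.append(msg)

    collector = _Collector()
    logging.getLogger("drmeta").addHandler(collector)

    try:
        studies = read_study_table(input_path)
    except Exception as exc:
        logging.getLogger("drmeta").removeHandler(collector)
        raise PipelineError("read", str(exc)) from exc
    timings["read"] = time.monotonic() - t0

    t1 = time.monotonic()
    try:
        summary = analyze_studies(studies, config)
    finally:
        logging.getLogger("drmeta").removeHandler(collector)
    curve = summary.pop("curve_table")
    per_study = summary.pop("per_study_table")
    funnel = summary.pop("funnel_table")
    timings["analyze"] = time.monotonic() - t1

    t2 = time.monotonic()
    written: list[str] = []
    try:
        paths = write_results(summary, curve, per_study, out_dir)
        written = list(paths.values())
        funnel_path = os.path.join(out_dir, "funnel.tsv")
        funnel.to_csv(funnel_path, sep="\t", index=False, float_format="%.12g")
        written.append(funnel_path)
        paths["funnel"] = funnel_path
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise PipelineError("write", str(exc)) from exc
    timings["write"] = time.monotonic() - t2

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "input_digest_sha256": digest,
        "outputs": paths,
        "timings_seconds": {k: round(v, 6) for k, v in timings.items()},
        "warnings": captured,
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["manifest"] = manifest_path
    return manifest
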