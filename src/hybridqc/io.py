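"""Text-file formats, configuration and the pipeline orchestrator.

Curves travel as two-column TSV (``#``-prefixed header lines, 12
significant digits) with a JSON metadata sidecar at ``<path>.json``; the
sidecar is validated with a pydantic model.  Rule sets and pipeline
configurations are YAML; reports are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ValidationError

from hybridqc.errors import (
    ConfigurationError,
    CurveFormatError,
    DynamicRangeError,
    InsufficientDecayError,
)
from hybridqc.fitting import (
    DCSFit,
    ExtinctionTable,
    TRSFit,
    compute_hemodynamics,
    fit_dtof,
    fit_g2,
    g1_from_g2,
)
from hybridqc.instrument import DTOFHistogram, G2Curve, IRF
from hybridqc.optics import ModelCurve, OpticalProperties
from hybridqc.qc import (
    QCRuleSet,
    QCVerdict,
    classify,
    dcs_qc_metrics,
    detect_secondary_decay,
    trs_qc_metrics,
)
from hybridqc import synthetic

logger = logging.getLogger("hybridqc")


class CurveSidecar(BaseModel):
    """Metadata sidecar of a curve file."""

    kind: Literal["dtof", "irf", "g2"]
    wavelength: Optional[float] = None
    rho: Optional[float] = None
    n_averaged: Optional[int] = None
    n_channels: Optional[int] = None
    count_rate: Optional[float] = None
    duration: Optional[float] = None
    beta: Optional[float] = None
    seed: Optional[int] = None
    fwhm: Optional[float] = None
    background_level: Optional[float] = None


def write_curve(path, curve) -> None:
    """Write a curve as two-column TSV plus a JSON sidecar.

    The abscissa/value pair is written with 12 significant digits; the
    sidecar lands at ``<path>.json``.
    """
    path = Path(path)
    if isinstance(curve, DTOFHistogram):
        x, y = curve.t_grid, curve.counts
        side = CurveSidecar(
            kind="dtof", wavelength=curve.wavelength, n_averaged=curve.n_averaged,
            background_level=curve.background_level,
        )
        header = "time_ns\tcounts"
    elif isinstance(curve, IRF):
        x, y = curve.t_grid, curve.values
        side = CurveSidecar(kind="irf", fwhm=curve.fwhm)
        header = "time_ns\tresponse"
    elif isinstance(curve, G2Curve):
        x, y = curve.tau_grid, curve.values
        side = CurveSidecar(
            kind="g2", count_rate=curve.count_rate, n_channels=curve.n_channels,
            duration=curve.duration,
        )
        header = "tau_s\tg2"
    else:
        raise CurveFormatError(f"cannot serialize curves of type {type(curve).__name__}")
    with open(path, "w") as fh:
        fh.write(f"# hybridqc curve kind={side.kind}\n# {header}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.15g}\t{yi:.15g}\n")
    with open(path.with_name(path.name + ".json"), "w") as fh:
        fh.write(side.model_dump_json(exclude_none=True, indent=2))


def read_curve(path):
    """Read a curve file and its sidecar; returns the typed curve object.

    Raises :class:`CurveFormatError` on a missing/invalid sidecar (with the
    offending field path) or a non-monotone abscissa.
    """
    path = Path(path)
    sidecar_path = path.with_name(path.name + ".json")
    if not sidecar_path.exists():
        raise CurveFormatError(f"missing sidecar {sidecar_path}")
    try:
        side = CurveSidecar.model_validate_json(sidecar_path.read_text())
    except ValidationError as exc:
        locs = "; ".join(".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in exc.errors())
        raise CurveFormatError(f"invalid sidecar {sidecar_path}: {locs}") from exc
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise CurveFormatError(f"{path}: expected two columns")
    x, y = data[:, 0], data[:, 1]
    if not np.all(np.diff(x) > 0):
        raise CurveFormatError(f"{path}: abscissa must be strictly increasing")
    if side.kind == "dtof":
        return DTOFHistogram(
            t_grid=x, counts=y, wavelength=side.wavelength or 0.0,
            n_averaged=side.n_averaged or 1,
            background_level=side.background_level or 0.0,
        )
    if side.kind == "irf":
        return IRF(t_grid=x, values=y, fwhm=side.fwhm or 0.1)
    return G2Curve(
        tau_grid=x, values=y, count_rate=side.count_rate or 0.0,
        n_channels=side.n_channels or 1, duration=side.duration or 1.0,
    )


def evaluate_case(bundle: dict, rules: QCRuleSet | None = None) -> dict:
    """Run the full evaluation on one TRS+DCS measurement bundle.

    ``bundle`` must hold ``dtof_687``, ``dtof_830``, ``irf`` and ``g2``; a
    ``ground_truth`` preset, when present, supplies the 785-nm optical
    properties used by the DCS fit (at the bedside these come from the TRS
    fit interpolated to the DCS wavelength).

    Returns a JSON-serializable report with fits, metrics, verdicts and the
    rule snapshot.  TRS verdicts are produced per wavelength and combined
    into the worst label.
    """
    if rules is None:
        rules = QCRuleSet()
    report: dict = {"rules": rules.to_dict(), "trs": {}, "dcs": {}}

    fits: dict[float, TRSFit | None] = {}
    irf = bundle["irf"]
    for lam, key in ((687.0, "dtof_687"), (830.0, "dtof_830")):
        dtof = bundle[key]
        entry: dict = {}
        refusals = []
        try:
            fit = fit_dtof(dtof, irf)
            if not fit.converged:
                fit = None
                refusals.append("fit did not converge")
        except DynamicRangeError as exc:
            fit = None
            refusals.append(str(exc))
        fits[lam] = fit
        metrics = trs_qc_metrics(dtof, irf)
        entry["metrics"] = metrics.to_dict()
        entry["fit"] = (
            None if fit is None else
            {"mua": fit.mua, "musp": fit.musp, "residual": fit.residual,
             "fit_range_ns": list(fit.fit_range), "converged": fit.converged}
        )
        entry["refusals"] = refusals
        report["trs"][str(int(lam))] = entry

    hemo = None
    if fits[687.0] is not None and fits[830.0] is not None:
        hemo = compute_hemodynamics(fits[687.0], fits[830.0])
        report["hemodynamics"] = {
            "c_hbo2_uM": hemo.c_hbo2, "c_hhb_uM": hemo.c_hhb,
            "thc_uM": hemo.thc, "sto2_pct": hemo.sto2, "physical": hemo.physical,
        }

    trs_verdicts = []
    for lam in (687.0, 830.0):
        entry = report["trs"][str(int(lam))]
        from hybridqc.qc import QCMetrics

        metrics = QCMetrics(**entry["metrics"])
        verdict = classify(metrics, hemo=hemo, rules=rules, refusals=entry["refusals"])
        entry["verdict"] = verdict.to_dict()
        trs_verdicts.append(verdict)
        for r in verdict.reasons:
            logger.warning("TRS %d nm rule violation: %s (observed %s)", int(lam), r.rule, r.observed)
    order = {"acceptable": 0, "suspect": 1, "reject": 2}
    worst = max(trs_verdicts, key=lambda v: order[v.label])
    report["trs"]["label"] = worst.label

    # --- DCS ---------------------------------------------------------------
    g2 = bundle["g2"]
    preset = bundle.get("ground_truth")
    if preset is not None:
        props785 = preset.props(785.0)
    else:
        # fall back to TRS-derived properties, averaged across wavelengths
        good = [f for f in fits.values() if f is not None]
        if good:
            props785 = OpticalProperties(
                mua=float(np.mean([f.mua for f in good])),
                musp=float(np.mean([f.musp for f in good])),
                wavelength=785.0,
            )
        else:
            props785 = OpticalProperties(mua=0.1, musp=10.0, wavelength=785.0)

    dcs_refusals = []
    dcs_fit: DCSFit | None = None
    try:
        dcs_fit = fit_g2(g2, props785)
    except InsufficientDecayError as exc:
        dcs_refusals.append(str(exc))
    metrics = dcs_qc_metrics(g2, dcs_fit)
    secondary = None
    if dcs_fit is not None and dcs_fit.beta > 0:
        g1d = np.clip(g1_from_g2(g2, dcs_fit.beta), 0.0, 1.0)
        g1_curve = ModelCurve(
            abscissa=g2.tau_grid, values=g1d, kind="g1",
            meta={"mua": props785.mua, "musp": props785.musp},
        )
        # data-driven g2 noise estimate from tail-to-tail differences, then
        # propagated through the sqrt normalization (floored where g1 ~ 0)
        tail = g2.values[-15:]
        sd_g2 = float(np.std(np.diff(tail)) / np.sqrt(2.0)) if tail.size >= 5 else 0.0
        sigma = None
        if sd_g2 > 0:
            sigma = sd_g2 / (2.0 * dcs_fit.beta * np.maximum(g1d, 0.1))
        try:
            secondary = detect_secondary_decay(g1_curve, props=props785, sigma=sigma)
        except Exception:
            secondary = None
    verdict = classify(metrics, hemo=None, rules=rules, secondary=secondary,
                       refusals=dcs_refusals)
    for r in verdict.reasons:
        logger.warning("DCS rule violation: %s (observed %s)", r.rule, r.observed)
    report["dcs"] = {
        "metrics": metrics.to_dict(),
        "fit": None if dcs_fit is None else {
            "bfi": dcs_fit.bfi, "beta": dcs_fit.beta, "residual": dcs_fit.residual,
            "cutoff": dcs_fit.cutoff_value, "converged": dcs_fit.converged,
            "reliability_flag": dcs_fit.reliability_flag, "n_points": dcs_fit.n_points,
        },
        "secondary_decay": None if secondary is None else {
            "present": secondary.present, "slow_weight": secondary.slow_weight,
            "slow_bfi": secondary.slow_bfi,
        },
        "refusals": dcs_refusals,
        "verdict": verdict.to_dict(),
        "label": verdict.label,
    }
    return report


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the evaluation pipeline from a YAML config (path) or dict.

    Config keys: either ``case`` (a preset id) with optional ``seed``, or
    ``inputs`` mapping ``dtof_687/dtof_830/irf/g2`` to curve files;
    optional ``rules`` (YAML rule file path) and ``out_dir`` for the JSON
    report.  Returns the report dict.  Hard I/O or configuration problems
    raise; reject verdicts do not.
    """
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise ConfigurationError(f"config file {path} not found")
        with open(path) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("pipeline config must be a mapping")

    if "rules" in config and config["rules"] is not None:
        rules_path = Path(config["rules"])
        if not rules_path.exists():
            raise ConfigurationError(f"rule file {rules_path} not found")
        rules = QCRuleSet.from_yaml(rules_path)
    else:
        rules = QCRuleSet()

    if "case" in config:
        bundle = synthetic.generate_case(config["case"], seed=int(config.get("seed", 0)))
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("dtof_687", "dtof_830", "irf", "g2"):
            if key not in inputs:
                raise ConfigurationError(f"pipeline inputs missing {key!r}")
        bundle = {k: read_curve(v) for k, v in inputs.items()}
    else:
        raise ConfigurationError("config must name a generator 'case' or curve 'inputs'")

    report = evaluate_case(bundle, rules)
    report["config"] = {k: v for k, v in config.items() if k != "out_dir"}
    out_dir = config.get("out_dir")
    if out_dir:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        name = config.get("case", "measurement")
        with open(out_dir / f"report_{name}.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
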