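"""Scenario configuration: load, validate, and dispatch analysis requests.

A scenario file is a small YAML (or JSON) mapping with a ``name``, a
``kind`` in {sev, bf, evidential-value, bfda}, and a ``parameters`` block
whose keys are validated against the owning module's spec type before
anything runs.  ``run_scenario`` dispatches to the library, returns a
JSON-serializable result dict, and optionally writes JSON plus CSV
by-products (severity curves, Bayes-factor lattices, BF samples).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design_analysis import DEFAULT_PRIOR_SCALE, DesignAnalysisSpec, simulate_bfda
from .error_statistics import NormalTestSpec, SeverityQuery, sev, severity_curve
from .evidential_value import MixtureWeights, expected_abs_log_bf
from .exceptions import ConfigurationError, SevBayesError
from .informative_binomial import (
    BinomialDesign,
    BinomialOutcome,
    IntervalHypothesis,
    bf_lattice,
    bf_vs_encompassing,
    classify_bf,
    prior_region_mass,
)

__all__ = ["Scenario", "load_scenario", "run_scenario", "bundled_scenario_path"]

logger = logging.getLogger("sevbayes")

_KINDS: dict[str, set[str]] = {
    "sev": {"mu0", "sigma", "n", "alpha", "xbar", "mu1", "grid"},
    "bf": {"label", "region_a", "region_b", "n_a", "n_b", "s_a", "s_b", "lattice"},
    "evidential-value": {
        "label", "region_a", "region_b", "n_a", "n_b",
        "w_constrained", "w_encompassing",
    },
    "bfda": {
        "n_per_group", "effect_size_d", "prior_scale_r",
        "upper_threshold", "lower_threshold", "n_sims", "seed", "alternative",
    },
}

_REQUIRED: dict[str, set[str]] = {
    "sev": {"mu0", "sigma", "n", "alpha", "xbar", "mu1"},
    "bf": {"label", "region_a", "region_b", "n_a", "n_b", "s_a", "s_b"},
    "evidential-value": {"label", "region_a", "region_b", "n_a", "n_b"},
    "bfda": {"n_per_group", "effect_size_d"},
}


@dataclass(frozen=True)
class Scenario:
    """A named, validated analysis request."""

    name: str
    kind: str
    parameters: dict[str, Any]


def load_scenario(path: str | Path) -> Scenario:
    """Parse and validate a scenario file; unknown keys are rejected by name."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"scenario file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raise ConfigurationError(f"scenario file {path} is empty")
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"scenario file {path} must contain a mapping")
    return _validate(dict(raw), source=str(path))


def _validate(raw: dict[str, Any], source: str) -> Scenario:
    for key in ("name", "kind", "parameters"):
        if key not in raw:
            raise ConfigurationError(f"{source}: missing required key {key!r}")
    extra = set(raw) - {"name", "kind", "parameters"}
    if extra:
        raise ConfigurationError(f"{source}: unknown top-level key {sorted(extra)[0]!r}")
    kind = raw["kind"]
    if kind not in _KINDS:
        raise ConfigurationError(
            f"{source}: unknown kind {kind!r}; expected one of {sorted(_KINDS)}"
        )
    params = raw["parameters"]
    if not isinstance(params, Mapping):
        raise ConfigurationError(f"{source}: 'parameters' must be a mapping")
    unknown = set(params) - _KINDS[kind]
    if unknown:
        raise ConfigurationError(
            f"{source}: unknown parameter {sorted(unknown)[0]!r} for kind {kind!r}"
        )
    missing = _REQUIRED[kind] - set(params)
    if missing:
        raise ConfigurationError(
            f"{source}: missing parameter {sorted(missing)[0]!r} for kind {kind!r}"
        )
    return Scenario(name=str(raw["name"]), kind=kind, parameters=dict(params))


def bundled_scenario_path(name: str) -> Path:
    """Filesystem path of a scenario fixture shipped with the package."""
    ref = resources.files("sevbayes") / "scenarios" / name
    with resources.as_file(ref) as p:
        if not p.exists():
            raise ConfigurationError(f"no bundled scenario named {name!r}")
        return Path(p)


def _hypothesis(params: Mapping[str, Any]) -> IntervalHypothesis:
    return IntervalHypothesis(
        label=str(params["label"]),
        region_a=tuple(float(x) for x in params["region_a"]),
        region_b=tuple(float(x) for x in params["region_b"]),
    )


def _run_sev(params: Mapping[str, Any], outdir: Path | None, name: str) -> dict[str, Any]:
    spec = NormalTestSpec(
        mu0=float(params["mu0"]), sigma=float(params["sigma"]),
        n=int(params["n"]), alpha=float(params["alpha"]),
    )
    query = SeverityQuery(mu1=float(params["mu1"]), xbar=float(params["xbar"]))
    res = sev(spec, query)
    out: dict[str, Any] = {
        "sev": res.sev,
        "rejected": res.rejected,
        "critical_mean": res.critical_mean,
        "critical_mean_rounded": round(res.critical_mean),
    }
    if "grid" in params:
        lo, hi, step = (float(x) for x in str(params["grid"]).split(":"))
        grid = np.arange(lo, hi + step / 2, step)
        curve = severity_curve(spec, query.xbar, grid)
        if outdir is not None:
            pd.DataFrame(curve, columns=["mu1", "sev"]).to_csv(
                outdir / f"{name}_curve.csv", index=False
            )
        out["curve_points"] = len(curve)
    return out


def _run_bf(params: Mapping[str, Any], outdir: Path | None, name: str) -> dict[str, Any]:
    h = _hypothesis(params)
    d = BinomialDesign(n_a=int(params["n_a"]), n_b=int(params["n_b"]))
    y = BinomialOutcome(s_a=int(params["s_a"]), s_b=int(params["s_b"]))
    res = bf_vs_encompassing(h, d, y)
    if params.get("lattice") and outdir is not None:
        lat = bf_lattice(h, d)
        pd.DataFrame(
            lat,
            index=pd.Index(range(d.n_a + 1), name="s_a"),
            columns=[str(s) for s in range(d.n_b + 1)],
        ).to_csv(outdir / f"{name}_lattice.csv")
    return {
        "label": h.label,
        "bf": res.bf,
        "log_bf": res.log_bf,
        "prior_mass": res.prior_mass,
        "posterior_mass": res.posterior_mass,
        "classification": classify_bf(res.bf) if res.bf > 0 else "Extreme evidence for H0",
        "max_possible_bf": 1.0 / prior_region_mass(h),
    }


def _run_ev(params: Mapping[str, Any], outdir: Path | None, name: str) -> dict[str, Any]:
    h = _hypothesis(params)
    d = BinomialDesign(n_a=int(params["n_a"]), n_b=int(params["n_b"]))
    weights = MixtureWeights(
        w_constrained=float(params.get("w_constrained", 0.5)),
        w_encompassing=float(params.get("w_encompassing", 0.5)),
    )
    res = expected_abs_log_bf(h, d, weights)
    if outdir is not None:
        res.per_outcome.to_csv(outdir / f"{name}_per_outcome.csv", index=False)
    return {
        "label": h.label,
        "expected_abs_log_bf": res.expectation,
        "n_outcomes": len(res.per_outcome),
        "weights": [weights.w_constrained, weights.w_encompassing],
    }


def _run_bfda(params: Mapping[str, Any], outdir: Path | None, name: str) -> dict[str, Any]:
    spec = DesignAnalysisSpec(
        n_per_group=int(params["n_per_group"]),
        effect_size_d=float(params["effect_size_d"]),
        prior_scale_r=float(params.get("prior_scale_r", DEFAULT_PRIOR_SCALE)),
        upper_threshold=float(params.get("upper_threshold", 3.0)),
        lower_threshold=float(params.get("lower_threshold", 1.0 / 3.0)),
        n_sims=int(params.get("n_sims", 10_000)),
        seed=int(params.get("seed", 0)),
        alternative=str(params.get("alternative", "greater")),
    )
    logger.info("BFDA seed=%d n_sims=%d", spec.seed, spec.n_sims)
    res = simulate_bfda(spec)
    if outdir is not None:
        pd.DataFrame({"bf10": res.bf_samples}).to_csv(
            outdir / f"{name}_bf_samples.csv", index=False
        )
    return {
        "rates": {
            "evidence_h1": res.rate_evidence_h1,
            "inconclusive": res.rate_inconclusive,
            "misleading_h0": res.rate_misleading_h0,
        },
        "se": res.mc_standard_errors,
        "n_sims": res.n_sims,
        "seed": res.seed,
    }


_RUNNERS = {"sev": _run_sev, "bf": _run_bf, "evidential-value": _run_ev, "bfda": _run_bfda}


def run_scenario(s: Scenario, output_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute a scenario, log provenance, and write JSON (+ CSV) outputs."""
    outdir: Path | None = None
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
    start = time.perf_counter()
    logger.info("running scenario %r (kind=%s)", s.name, s.kind)
    try:
        result = _RUNNERS[s.kind](s.parameters, outdir, s.name)
    except SevBayesError as exc:
        raise type(exc)(f"scenario {s.name!r}: {exc}") from exc
    elapsed = time.perf_counter() - start
    payload = {
        "scenario": s.name,
        "kind": s.kind,
        "parameters": s.parameters,
        "result": result,
        "sevbayes_version": __version__,
        "wall_time_s": round(elapsed, 4),
    }
    if outdir is not None:
        (outdir / f"{s.name}.json").write_text(json.dumps(payload, indent=2))
    logger.info("scenario %r finished in %.3fs", s.name, elapsed)
    return payload
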