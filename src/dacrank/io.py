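"""Configuration parsing and report serialization.

Configs are YAML (JSON is a YAML subset and works unchanged).  Schema:

.. code-block:: yaml

    data: observations.csv          # one numeric column, header optional
    experts:
      - {id: expert_1, mu0: 2.15, sigma0: 0.09, gamma0: 0.78}
    benchmark: {family: uniform, lower: 0, upper: 5}   # null => benchmark-free
    benchmarks:                     # optional, for sensitivity sweeps
      - {family: normal, mean: 0, sd: 100}
    model: {sigma_mode: plugin_sample_sd, theta_bounds: [0, 5]}
    seed: 1
    precision: 2
    out: results

Omitting ``benchmark`` selects a wide flat default spanning the data
mean +/- 50 sample SDs; an explicit ``null`` requests benchmark-free
mode (raw KL ranking, no agreement verdicts).  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .densities import DensitySpec, ExpertBelief, make_skew_normal, normal, uniform
from .errors import ValidationError
from .posterior import ModelSpec, ObservationSet
from .ranking import PairwiseTable, RankingConfig, RankingReport, pairwise_table
from .sensitivity import GridResult, SweepResult

__all__ = ["RunConfig", "load_config", "read_observations", "write_report", "parse_density"]

_TOP_KEYS = {"data", "experts", "benchmark", "benchmarks", "model", "seed", "precision", "out"}
_EXPERT_KEYS = {"id", "mu0", "sigma0", "gamma0"}
_MODEL_KEYS = {"sigma_mode", "sigma", "theta_bounds"}
_DENSITY_KEYS = {
    "normal": {"family", "mean", "sd"},
    "uniform": {"family", "lower", "upper"},
    "skew_normal": {"family", "mu0", "sigma0", "gamma0"},
}

#: sentinel: benchmark key absent => derive a wide flat benchmark from the data
AUTO_BENCHMARK = "auto"


@dataclass
class RunConfig:
    experts: List[ExpertBelief]
    benchmark: object = AUTO_BENCHMARK   # DensitySpec | None | AUTO_BENCHMARK
    benchmarks: List[DensitySpec] = field(default_factory=list)
    model: ModelSpec = field(default_factory=ModelSpec)
    data_path: Optional[str] = None
    seed: int = 1
    precision: int = 2
    out_dir: str = "results"
    config_hash: str = ""

    def resolve_benchmark(self, data: ObservationSet) -> Optional[DensitySpec]:
        if self.benchmark is AUTO_BENCHMARK:
            sd = data.sd if data.sd is not None else 1.0
            return uniform(data.mean - 50.0 * sd, data.mean + 50.0 * sd)
        return self.benchmark

    def to_ranking_config(self, data: ObservationSet) -> RankingConfig:
        return RankingConfig(
            experts=self.experts,
            benchmark=self.resolve_benchmark(data),
            model=self.model,
            data=data,
        )


def parse_density(node: dict, context: str = "benchmark") -> DensitySpec:
    if not isinstance(node, dict) or "family" not in node:
        raise ValidationError(f"{context}: expected a mapping with a 'family' key")
    family = node["family"]
    allowed = _DENSITY_KEYS.get(family)
    if allowed is None:
        raise ValidationError(f"{context}: unknown density family {family!r}")
    unknown = set(node) - allowed
    if unknown:
        raise ValidationError(f"{context}: unknown key(s) {sorted(unknown)} for family {family!r}")
    try:
        if family == "normal":
            return normal(node["mean"], node["sd"])
        if family == "uniform":
            return uniform(node["lower"], node["upper"])
        return make_skew_normal(node["mu0"], node["sigma0"], node.get("gamma0", 1.0))
    except KeyError as exc:
        raise ValidationError(f"{context}: missing key {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a run configuration file."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: malformed config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    if "experts" not in raw or not raw["experts"]:
        raise ValidationError(f"{path}: 'experts' must list at least one expert")

    experts = []
    for i, node in enumerate(raw["experts"]):
        if not isinstance(node, dict):
            raise ValidationError(f"experts[{i}]: expected a mapping")
        unknown = set(node) - _EXPERT_KEYS
        if unknown:
            raise ValidationError(f"experts[{i}]: unknown key(s) {sorted(unknown)}")
        eid = str(node.get("id", f"expert_{i + 1}"))
        for key in ("mu0", "sigma0"):
            if key not in node:
                raise ValidationError(f"expert {eid!r}: missing required key '{key}'")
        try:
            experts.append(
                ExpertBelief(eid, float(node["mu0"]), float(node["sigma0"]),
                             float(node.get("gamma0", 1.0)))
            )
        except ValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"expert {eid!r}: non-numeric parameter: {exc}") from exc

    benchmark: object = AUTO_BENCHMARK
    if "benchmark" in raw:
        benchmark = None if raw["benchmark"] is None else parse_density(raw["benchmark"])
    benchmarks = [
        parse_density(node, f"benchmarks[{i}]")
        for i, node in enumerate(raw.get("benchmarks", []))
    ]

    model = ModelSpec()
    if "model" in raw:
        node = raw["model"]
        unknown = set(node) - _MODEL_KEYS
        if unknown:
            raise ValidationError(f"model: unknown key(s) {sorted(unknown)}")
        bounds = node.get("theta_bounds")
        model = ModelSpec(
            sigma_mode=node.get("sigma_mode", "plugin_sample_sd"),
            sigma=node.get("sigma"),
            theta_bounds=(
                tuple(float(b) for b in bounds) if bounds is not None
                else (-math.inf, math.inf)
            ),
        )

    return RunConfig(
        experts=experts,
        benchmark=benchmark,
        benchmarks=benchmarks,
        model=model,
        data_path=raw.get("data"),
        seed=int(raw.get("seed", 1)),
        precision=int(raw.get("precision", 2)),
        out_dir=str(raw.get("out", "results")),
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
    )


def read_observations(path: str | Path) -> ObservationSet:
    """One numeric column, CSV or plain text; a single header line is tolerated."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None)
    except Exception as exc:
        raise ValidationError(f"{path}: cannot read observations: {exc}") from exc
    col = df.iloc[:, 0]
    values = pd.to_numeric(col, errors="coerce")
    if values.isna().iloc[0] and values.iloc[1:].notna().all():
        values = values.iloc[1:]  # header line
    if values.isna().any():
        raise ValidationError(f"{path}: non-numeric entries in the observation column")
    return ObservationSet.from_values(values.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# writers

REPORT_COLUMNS = [
    "expert_id", "kl", "dac", "dac_rank", "log_m", "bf_Jd", "bf_rank",
    "dac2", "agreement_dac", "agreement_bf",
]


def write_report(
    result: RankingReport | SweepResult | GridResult | PairwiseTable,
    outdir: str | Path,
    seed: int | None = None,
    config_hash: str = "",
    precision: int = 2,
) -> List[Path]:
    """Serialize a result object to CSV files plus a plain-text run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []

    if isinstance(result, RankingReport):
        df = result.to_frame()
        for col in REPORT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[REPORT_COLUMNS]
        for col in ("kl", "dac", "bf_Jd", "dac2"):
            df[col] = df[col].round(precision)
        df["log_m"] = df["log_m"].round(max(precision, 4))
        paths.append(_write_csv(df, outdir / "per_expert.csv", index=False))
        if (
            result.log_m is not None
            and np.all(np.isfinite(result.log_m))
            and np.all(np.isfinite(result.kl))
            and np.all(result.kl > 0)
        ):
            pt = pairwise_table(result.kl, result.log_m, result.expert_ids)
            paths.append(_write_csv(pt.kl_ratio.round(precision), outdir / "pairwise_kl_ratio.csv"))
            paths.append(_write_csv(pt.bf.round(precision), outdir / "pairwise_bf.csv"))
    elif isinstance(result, PairwiseTable):
        paths.append(_write_csv(result.kl_ratio.round(precision), outdir / "pairwise_kl_ratio.csv"))
        paths.append(_write_csv(result.bf.round(precision), outdir / "pairwise_bf.csv"))
    elif isinstance(result, SweepResult):
        paths.append(_write_csv(result.table.round(max(precision, 4)), outdir / "sweep.csv"))
        paths.append(_write_csv(result.dac.round(precision), outdir / "sweep_dac.csv"))
        paths.append(_write_csv(result.rankings, outdir / "sweep_rankings.csv"))
    elif isinstance(result, GridResult):
        long = result.to_long()
        long["mu0"] = long["mu0"].round(6)
        long["sigma0"] = long["sigma0"].round(6)
        long["dac"] = long["dac"].round(6)
        paths.append(_write_csv(long, outdir / "dac_grid.csv", index=False))
    else:
        raise ValidationError(f"don't know how to write a {type(result).__name__}")

    log = outdir / "run_log.txt"
    log.write_text(
        f"dacrank {__version__}\nseed: {seed}\nconfig_hash: {config_hash}\n"
    )
    paths.append(log)
    return paths


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, index=index)
    return path
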