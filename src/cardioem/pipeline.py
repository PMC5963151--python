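"""Experiment orchestration: the three-condition study behind one config.

Runs calcium generation -> myofilament activation -> the three circulation
scenarios (normal, heart failure, heart failure + LVAD) -> hemodynamic
summaries and the two canonical percent-change comparisons
(normal vs HF, HF vs HF+LVAD), writing deterministic CSV/JSON artifacts
plus a manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from .calcium import TransientParams
from .circulation import CirculationParams, load_default_params, run_scenario, CONDITIONS
from .exceptions import CardioemError, InvalidParameterError
from .hemodynamics import (
    HemodynamicSummary,
    compare_conditions,
    segment_last_beat,
    summarize_beat,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]


@dataclass
class ExperimentConfig:
    """Study conditions: pacing, cycle counts, heart-failure scaling, pump flow."""

    bcl_ms: float = 800.0
    n_cycles_cell: int = 10
    n_cycles_system: int = 25
    hf_amp_factor: float = 0.7
    hf_tau_factor: float = 0.7
    lvad_flow_lpm: float = 4.0
    dt_system_ms: float = 0.25
    out_dir: str = "cardioem_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bcl_ms <= 0:
            raise InvalidParameterError("bcl_ms must be > 0")
        for name in ("n_cycles_cell", "n_cycles_system"):
            if getattr(self, name) < 2:
                raise InvalidParameterError(f"{name} must be >= 2")
        for name in ("hf_amp_factor", "hf_tau_factor"):
            if not (0 < getattr(self, name) <= 1):
                raise InvalidParameterError(f"{name} must lie in (0, 1]")
        if self.lvad_flow_lpm < 0:
            raise InvalidParameterError("lvad_flow_lpm must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))


@dataclass
class ExperimentResult:
    summaries: dict[str, HemodynamicSummary]
    comparison: pd.DataFrame
    manifest: dict[str, str]
    out_dir: Path
    steady_state_metrics: dict[str, float]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(
    config: ExperimentConfig,
    params: CirculationParams | None = None,
    write_traces: bool = True,
) -> ExperimentResult:
    """Execute the full three-condition experiment and write the artifact bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = load_default_params() if params is None else params

    summaries: dict[str, HemodynamicSummary] = {}
    metrics: dict[str, float] = {}
    files: list[Path] = []
    for cond in CONDITIONS:
        try:
            res = run_scenario(
                cond,
                n_cycles=config.n_cycles_system,
                bcl_ms=config.bcl_ms,
                params=params,
                transient=TransientParams(bcl_ms=config.bcl_ms),
                hf_amp_factor=config.hf_amp_factor,
                hf_tau_factor=config.hf_tau_factor,
                lvad_flow_lpm=config.lvad_flow_lpm,
                dt_ms=config.dt_system_ms,
            )
        except CardioemError as err:
            raise type(err)(f"stage run_scenario({cond}) failed: {err}") from err
        metrics[cond] = res.steady_state_metric
        beat = segment_last_beat(res.traces, config.bcl_ms)
        summaries[cond] = summarize_beat(beat, config.bcl_ms)
        if write_traces:
            fp = out / f"traces_{cond}.csv"
            res.traces.to_csv(fp, index=False, float_format="%.6g")
            files.append(fp)
        fp = out / f"beat_{cond}.csv"
        beat.to_csv(fp, index=False, float_format="%.6g")
        files.append(fp)

    table = pd.DataFrame({c: summaries[c].as_series() for c in CONDITIONS})
    table.index.name = "quantity"
    fp = out / "summary_table.csv"
    table.to_csv(fp, float_format="%.6g")
    files.append(fp)

    comparison = compare_conditions(summaries)
    fp = out / "comparison.csv"
    comparison.to_csv(fp, index=False, float_format="%.6g")
    files.append(fp)

    fp = out / "summaries.json"
    fp.write_text(json.dumps(
        {c: {k: round(v, 10) for k, v in summaries[c].as_dict().items()} for c in CONDITIONS},
        indent=2, sort_keys=True))
    files.append(fp)

    fp = out / "config.json"
    config.to_file(fp)
    files.append(fp)

    manifest = {f.name: _sha256(f) for f in sorted(files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ExperimentResult(
        summaries=summaries, comparison=comparison, manifest=manifest,
        out_dir=out, steady_state_metrics=metrics,
    )
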