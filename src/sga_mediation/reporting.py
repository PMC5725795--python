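"""Rendering of study-style summary tables and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from .estimators import MODEL_ORDER
from .montecarlo import MCSummary
from .scenarios import SCENARIOS

__all__ = ["RunConfig", "render_table", "write_markdown", "write_manifest"]

_SCENARIO_RANK = {name: i for i, name in enumerate(SCENARIOS)}
_MODEL_RANK = {name: i for i, name in enumerate(MODEL_ORDER)}


@dataclass
class RunConfig:
    """Configuration of a replicated run; defaults reproduce the full study."""

    scenarios: list[str] = field(default_factory=lambda: list(SCENARIOS))
    mean_form: str = "linear"
    error_kind: str = "homoskedastic"
    n: int = 20_000
    reps: int = 1000
    seed: int = 0
    ga_dist_path: str | None = None
    out_dir: str = "results"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML or JSON config; keyword overrides win over file values."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def __post_init__(self) -> None:
        unknown = [s for s in self.scenarios if s not in SCENARIOS]
        if unknown:
            raise ValueError(
                f"unknown scenario(s) {unknown}; valid names: {', '.join(SCENARIOS)}"
            )


def _format_mean(x: float) -> str:
    """Mixed precision as in the published tables: wide values get fewer decimals."""
    if abs(x) >= 100:
        return f"{x:.2f}"
    if abs(x) >= 10:
        return f"{x:.3f}"
    return f"{x:.4f}"


def render_table(summaries: list[MCSummary], include_confounded: bool | None = None) -> pd.DataFrame:
    """Assemble MC summaries into a study-style table.

    Rows are ordered scenario-major with models in table order (M1, M1,V,
    M2, ..., M4,V). The ``confounded`` column is included when bias flags are
    present (confounding-scenario tables). Missing cells are the caller's
    responsibility; an empty input is rejected.
    """
    if not summaries:
        raise ValueError("no summaries to render")
    if include_confounded is None:
        include_confounded = any(s.confounded_flag is not None for s in summaries)
    rows = []
    for s in sorted(
        summaries, key=lambda s: (_SCENARIO_RANK[s.scenario], _MODEL_RANK[s.model])
    ):
        row = {
            "scenario": s.scenario,
            "model": s.model,
            "interpretation": s.interpretation,
            "mean": s.mean_estimate,
            "se": s.mc_se,
            "null_ics_effect": "yes" if s.null_flag else "no",
            "n_reps_used": s.n_reps_used,
        }
        if include_confounded:
            if s.confounded_flag is None:
                raise ValueError(
                    f"missing confounded flag for ({s.scenario}, {s.model})"
                )
            row["association_confounded"] = "yes" if s.confounded_flag else "no"
        rows.append(row)
    return pd.DataFrame(rows)


def write_markdown(table: pd.DataFrame, path: str | Path) -> None:
    """Write a GitHub-style pipe table (means at the published precision)."""
    display = table.copy()
    if "mean" in display:
        display["mean"] = display["mean"].map(_format_mean)
    if "se" in display:
        display["se"] = display["se"].map(lambda x: f"{x:.4f}")
    if "expected" in display:
        display["expected"] = display["expected"].map(
            lambda x: "-" if pd.isna(x) else _format_mean(x)
        )
    headers = list(display.columns)
    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    for _, row in display.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(config: RunConfig, path: str | Path) -> None:
    """Reproducibility manifest: seed, config hash, library versions."""
    config_dict = {k: getattr(config, k) for k in vars(config)}
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
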