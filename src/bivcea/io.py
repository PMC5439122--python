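"""Readers, writers and validation for the pipeline's text formats.

The patient table is comma-separated UTF-8 with a header row and the
exact columns of :data:`bivcea.simulate.PATIENT_COLUMNS`; configs load
from YAML or JSON; results serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ChainConfig, GeneratorConfig, ModelSpec, PipelineConfig
from .simulate import PATIENT_COLUMNS

__all__ = [
    "load_patient_table",
    "write_patient_table",
    "load_config",
    "load_pipeline_config",
    "write_json",
    "report_table",
]

_REQUIRED = PATIENT_COLUMNS
_VALID = {
    "group": {"intervention", "control"},
    "period": {"baseline", "post"},
    "risk": {"low", "high"},
}


def load_patient_table(path) -> pd.DataFrame:
    """Read and validate a patient table.

    Raises ``ValueError`` naming missing columns, and citing the
    1-based data row of the first out-of-range value (non-binary
    caesarean indicator, negative cost, unknown category label, broken
    component additivity, or an arm that varies within a hospital).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")

    cs = df["cs"].to_numpy()
    bad = ~np.isin(cs, (0, 1))
    if bad.any():
        row = int(np.nonzero(bad)[0][0]) + 1
        raise ValueError(f"non-binary cs value {cs[bad][0]!r} in row {row}")
    for col, valid in _VALID.items():
        bad = ~df[col].isin(valid).to_numpy()
        if bad.any():
            row = int(np.nonzero(bad)[0][0]) + 1
            raise ValueError(
                f"invalid {col} value {df[col].to_numpy()[bad][0]!r} in row {row}"
            )
    for col in ("delivery_cost", "maternal_cost", "neonatal_cost"):
        vals = df[col].to_numpy(float)
        bad = ~(np.isfinite(vals) & (vals >= 0))
        if bad.any():
            row = int(np.nonzero(bad)[0][0]) + 1
            raise ValueError(f"negative or non-finite {col} in row {row}")
    comp_sum = (
        df["delivery_cost"] + df["maternal_cost"] + df["neonatal_cost"]
    ).to_numpy(float)
    bad = np.abs(comp_sum - df["total_cost"].to_numpy(float)) > 1e-6
    if bad.any():
        row = int(np.nonzero(bad)[0][0]) + 1
        raise ValueError(f"total_cost does not equal component sum in row {row}")
    arms = df.groupby("hospital_id")["group"].nunique()
    mixed = arms[arms > 1]
    if len(mixed):
        raise ValueError(
            f"group must be constant within hospital (cluster randomization); "
            f"violated by {list(mixed.index)}"
        )
    return df


def write_patient_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def load_config(path) -> dict:
    """Load a YAML or JSON mapping."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_pipeline_config(path) -> PipelineConfig:
    d = dict(load_config(path))
    if d.get("generator") is not None:
        d["generator"] = GeneratorConfig.from_dict(d["generator"])
    if d.get("model") is not None:
        d["model"] = ModelSpec(**d["model"])
    if d.get("chain") is not None:
        d["chain"] = ChainConfig(**d["chain"])
    return PipelineConfig(**d)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, cls=_Encoder, sort_keys=True), encoding="utf-8"
    )


def report_table(results: dict) -> str:
    """Plain-text report of the DiD estimates (one row per analysis)."""
    lines = [
        f"{'analysis':<28}{'outcome':<10}{'coef':>12}{'SE':>10}"
        f"{'95% CI':>24}{'P':>9}",
        "-" * 93,
    ]
    for name, did in results.items():
        for outcome, est, se, ci, p in (
            ("CS", did.delta_e, did.se_e, did.ci_e, did.p_e),
            ("cost $", did.delta_c, did.se_c, did.ci_c, did.p_c),
        ):
            ci_txt = f"({ci[0]:.4g} to {ci[1]:.4g})"
            lines.append(
                f"{name:<28}{outcome:<10}{est:>12.4g}{se:>10.3g}{ci_txt:>24}{p:>9.3g}"
            )
    return "\n".join(lines)
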