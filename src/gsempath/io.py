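"""Readers, writers, and run manifests.

CSV is the sole data format: UTF-8, header row, missing values as empty cells
or ``NA``.  Fits serialize to JSON; every pipeline run writes a manifest
recording the configuration, the seed actually used, and library versions.
"""

from __future__ import annotations

import json
import sys
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .glm_engine import EquationFit, SystemFit
from .model_spec import CodingError, PathDiagram, MISSING_MARKERS

__all__ = [
    "read_records",
    "write_records",
    "system_to_json",
    "system_from_json",
    "write_manifest",
    "round_for_display",
]


def read_records(path, diagram: PathDiagram) -> pd.DataFrame:
    """Read a record CSV and type columns per the variable declarations.

    Unknown extra columns are kept but warned about; missing markers
    (empty / ``NA``) are normalized to NA; unknown category values raise a
    :class:`CodingError` naming the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    declared = [v.name for v in diagram.variables]
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise CodingError(f"input lacks required column(s): {missing}")
    extra = [c for c in df.columns if c not in declared and c != "weight"]
    if extra:
        warnings.warn(f"ignoring undeclared column(s): {extra}", stacklevel=2)

    out = {}
    for var in diagram.variables:
        col = df[var.name].str.strip()
        col = col.where(~col.isin(MISSING_MARKERS), other=pd.NA)
        if var.is_categorical:
            bad = col.dropna()[~col.dropna().isin(var.levels)]
            if len(bad):
                row = bad.index[0]
                raise CodingError(
                    f"{var.name}: unknown category {bad.iloc[0]!r} at row {row}"
                )
            out[var.name] = col.astype(object).where(col.notna(), None)
        else:
            out[var.name] = pd.to_numeric(col, errors="raise")
    frame = pd.DataFrame(out)
    if "weight" in df.columns:
        frame["weight"] = pd.to_numeric(df["weight"])
    return frame


def write_records(frame: pd.DataFrame, path) -> None:
    """Write records as UTF-8 CSV with empty cells for missing values."""
    frame.to_csv(path, index=False, na_rep="", encoding="utf-8")


def _fit_to_dict(fit: EquationFit) -> dict:
    return {
        "response": fit.response,
        "contrasts": fit.contrasts,
        "baseline": fit.baseline,
        "terms": fit.terms,
        "family": fit.family,
        "params": fit.params.tolist(),
        "covariance": fit.covariance.tolist(),
        "log_likelihood": None if np.isnan(fit.log_likelihood) else fit.log_likelihood,
        "n_used": fit.n_used,
        "rows_dropped": fit.rows_dropped,
        "converged": fit.converged,
        "iterations": fit.iterations,
    }


def system_to_json(system: SystemFit, path) -> None:
    payload = {
        "total_log_likelihood": (
            None
            if any(np.isnan(f.log_likelihood) for f in system.fits.values())
            else system.total_log_likelihood
        ),
        "equations": {name: _fit_to_dict(f) for name, f in system.fits.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def system_from_json(path) -> SystemFit:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    fits = {}
    for name, d in payload["equations"].items():
        fits[name] = EquationFit(
            response=d["response"],
            contrasts=list(d["contrasts"]),
            baseline=d["baseline"],
            terms=list(d["terms"]),
            params=np.asarray(d["params"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            log_likelihood=(
                np.nan if d["log_likelihood"] is None else float(d["log_likelihood"])
            ),
            n_used=d["n_used"],
            rows_dropped=d["rows_dropped"],
            converged=d["converged"],
            iterations=d["iterations"],
            family=d["family"],
        )
    return SystemFit(fits=fits)


def write_manifest(outdir, config: dict, seed: Optional[int]) -> Path:
    """Record the effective configuration, seed, and versions for a run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "versions": {
            "gsempath": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str), encoding="utf-8")
    return path


def round_for_display(frame: pd.DataFrame, decimals_effects: int = 3,
                      decimals_or: int = 2) -> pd.DataFrame:
    """Display variant of a numeric report: effects/PCs to 3 decimals, odds
    ratios to 2, matching the field's reporting conventions."""
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        if "odds" in col or col in ("ci_low", "ci_high") and "odds_ratio" in out.columns:
            out[col] = out[col].round(decimals_or)
        elif col == "p":
            out[col] = out[col].round(4)
        else:
            out[col] = out[col].round(decimals_effects)
    return out
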