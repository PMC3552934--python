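"""Reading and writing datasets and result tables as delimited text.

Dataset files are CSV with header ``group,y,w``: ``group`` is a 1-based
integer ordered by hypothesized increasing exposure, ``y`` the outcome, and
``w`` the error-prone exposure where an *empty field* means missing (never
zero).  Result files hold one row per fitted method plus a YAML metadata
sidecar (seed, options, package version).
"""

from __future__ import annotations

import datetime
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .group_estimators import EstimationResult
from .model import GroupedDataset

__all__ = ["read_dataset", "write_dataset", "write_results", "read_results"]


def read_dataset(path) -> GroupedDataset:
    """Parse a ``group,y,w`` CSV into a GroupedDataset, preserving row order."""
    df = pd.read_csv(path)
    required = {"group", "y", "w"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    for i, val in enumerate(df["y"]):
        if pd.isna(val):
            raise ValueError(f"{path}: missing outcome y on line {i + 2}")
    group = pd.to_numeric(df["group"], errors="coerce")
    vals = group.to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(vals) | (np.mod(vals, 1.0) != 0))[0]
    if bad.size:
        raise ValueError(f"{path}: non-integer group on line {bad[0] + 2}")
    try:
        y = df["y"].astype(float).to_numpy()
        w = df["w"].astype(float).to_numpy()  # empty fields -> NaN (missing)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable numeric value ({exc})") from exc
    return GroupedDataset(group=group.astype(int).to_numpy(), y=y, w=w)


def write_dataset(dataset: GroupedDataset, path) -> None:
    """Write a dataset back to ``group,y,w`` CSV (missing w -> empty field)."""
    pd.DataFrame({"group": dataset.group, "y": dataset.y, "w": dataset.w}).to_csv(
        path, index=False
    )


def _fmt(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{x:.6g}"


def _fmt_mu(mu: Optional[np.ndarray]) -> str:
    if mu is None:
        return ""
    return "[" + " ".join(f"{v:.6g}" for v in mu) + "]"


def write_results(results: Sequence[EstimationResult], path, metadata: Optional[dict] = None,
                  sigma_eta2: Optional[Sequence[Optional[float]]] = None) -> None:
    """Write one CSV row per fitted method plus a YAML metadata sidecar.

    Numbers are fixed at 6 significant digits for reproducible diffs.  The
    sidecar at ``<path>.meta.yaml`` records the run metadata (seed, options,
    package version, timestamp).
    """
    from . import __version__

    eta = list(sigma_eta2) if sigma_eta2 is not None else [None] * len(results)
    rows = []
    for res, se2 in zip(results, eta):
        rows.append({
            "method": res.method,
            "sigma_eta2": _fmt(se2),
            "beta0_hat": _fmt(res.beta0_hat),
            "beta1_hat": _fmt(res.beta1_hat),
            "se_beta1": _fmt(res.se_beta1),
            "se_inflated": res.se_inflated,
            "converged": res.converged,
            "n_iterations": "" if res.n_iterations is None else res.n_iterations,
            "mu_hat": _fmt_mu(res.mu_hat),
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    meta = dict(metadata or {})
    meta.setdefault("package", "semieco")
    meta.setdefault("version", __version__)
    meta.setdefault("written_at", datetime.datetime.now().isoformat(timespec="seconds"))
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_results(path) -> List[EstimationResult]:
    """Read a results CSV back into EstimationResult objects (lossless round trip)."""
    df = pd.read_csv(path, keep_default_na=False)
    out: List[EstimationResult] = []
    for _, row in df.iterrows():
        mu = None
        if row["mu_hat"]:
            mu = np.array([float(v) for v in str(row["mu_hat"]).strip("[]").split()])
        out.append(EstimationResult(
            method=row["method"],
            beta0_hat=float(row["beta0_hat"]),
            beta1_hat=float(row["beta1_hat"]),
            se_beta1=float(row["se_beta1"]) if row["se_beta1"] != "" else None,
            se_inflated=str(row["se_inflated"]) == "True",
            mu_hat=mu,
            converged=str(row["converged"]) == "True",
            n_iterations=int(row["n_iterations"]) if row["n_iterations"] != "" else None,
        ))
    return out
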