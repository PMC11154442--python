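"""Flux-rejection datasets and their delimited-text representation.

A :class:`RejectionDataset` holds the replicated (flux, observed-rejection)
measurements for one solution condition (a pH / ionic-strength pair).  On
disk a collection of conditions lives in a single CSV with columns

    condition_id, pH, ionic_strength_M, tmp_bar, flux_m_per_s, replicate,
    r_obs            (or the pair c_retentate, c_permeate)

Pressures are in bar and ionic strength in mol/L at the file boundary
(matching how operating conditions are reported); fluxes are SI (m/s).
When both ``r_obs`` and concentration columns are present the explicit
``r_obs`` wins; disagreement beyond 1e-6 is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .transport import observed_rejection

__all__ = ["RejectionDataset", "SchemaError", "read_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "condition_id",
    "pH",
    "ionic_strength_M",
    "tmp_bar",
    "flux_m_per_s",
    "replicate",
)

#: significant digits used for all floating-point serialization
SERIALIZATION_DIGITS = 6


class SchemaError(ValueError):
    """The file does not conform to the dataset schema."""


@dataclass
class RejectionDataset:
    """Replicated (flux, rejection) observations for one solution condition."""

    condition_id: str
    pH: float
    ionic_strength: float
    observations: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        obs = self.observations
        missing = {"v_w", "r_obs", "replicate"} - set(obs.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if len(obs) == 0:
            raise ValueError("a dataset needs at least one observation")
        if np.any(obs["v_w"].to_numpy() <= 0):
            raise ValueError("all fluxes v_w must be positive")
        if np.any(obs["r_obs"].to_numpy() > 1):
            raise ValueError("observed rejection cannot exceed 1")

    @property
    def v_w(self) -> np.ndarray:
        return self.observations["v_w"].to_numpy(dtype=float)

    @property
    def r_obs(self) -> np.ndarray:
        return self.observations["r_obs"].to_numpy(dtype=float)

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @classmethod
    def from_arrays(
        cls,
        condition_id: str,
        v_w: Sequence[float],
        r_obs: Sequence[float],
        *,
        pH: float = float("nan"),
        ionic_strength: float = float("nan"),
        replicate: Optional[Sequence[int]] = None,
        tmp_bar: Optional[Sequence[float]] = None,
    ) -> "RejectionDataset":
        n = len(v_w)
        obs = pd.DataFrame(
            {
                "v_w": np.asarray(v_w, dtype=float),
                "r_obs": np.asarray(r_obs, dtype=float),
                "replicate": np.ones(n, dtype=int) if replicate is None
                else np.asarray(replicate, dtype=int),
            }
        )
        if tmp_bar is not None:
            obs["tmp_bar"] = np.asarray(tmp_bar, dtype=float)
        return cls(condition_id, pH, ionic_strength, obs)


def _validate_rows(df: pd.DataFrame) -> None:
    bad: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["flux_m_per_s"] <= 0:
            bad.append(f"line {line}: non-positive flux {row['flux_m_per_s']}")
        if not np.isnan(row.get("r_obs", np.nan)) and row["r_obs"] > 1:
            bad.append(f"line {line}: r_obs {row['r_obs']} > 1")
    if bad:
        raise SchemaError("invalid rows:\n" + "\n".join(bad))


def read_dataset(path) -> list[RejectionDataset]:
    """Read a dataset collection from CSV, one :class:`RejectionDataset` per condition.

    ``r_obs`` is computed from (c_retentate, c_permeate) when absent; when
    both are present the explicit column takes precedence and any mismatch
    greater than 1e-6 is logged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise SchemaError(f"{path}: empty data section")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    has_r = "r_obs" in df.columns
    has_conc = {"c_retentate", "c_permeate"} <= set(df.columns)
    if not has_r and not has_conc:
        raise SchemaError(
            f"{path}: need either an r_obs column or both c_retentate and c_permeate"
        )
    if has_conc:
        from_conc = observed_rejection(
            df["c_retentate"].to_numpy(float), df["c_permeate"].to_numpy(float)
        )
        if has_r:
            mismatch = np.abs(df["r_obs"].to_numpy(float) - from_conc)
            n_bad = int(np.sum(mismatch > 1e-6))
            if n_bad:
                logger.warning(
                    "%s: r_obs disagrees with concentration pair beyond 1e-6 "
                    "on %d row(s); keeping r_obs", path, n_bad,
                )
        else:
            df = df.assign(r_obs=from_conc)
    _validate_rows(df)

    datasets = []
    for cid, group in df.groupby("condition_id", sort=False):
        obs = pd.DataFrame(
            {
                "v_w": group["flux_m_per_s"].to_numpy(float),
                "r_obs": group["r_obs"].to_numpy(float),
                "replicate": group["replicate"].to_numpy(int),
                "tmp_bar": group["tmp_bar"].to_numpy(float)
                if "tmp_bar" in group.columns else np.nan,
            }
        )
        datasets.append(
            RejectionDataset(
                condition_id=str(cid),
                pH=float(group["pH"].iloc[0]),
                ionic_strength=float(group["ionic_strength_M"].iloc[0]),
                observations=obs.reset_index(drop=True),
            )
        )
    return datasets


def _fmt(x: float) -> str:
    return f"{x:.{SERIALIZATION_DIGITS}g}"


def write_dataset(datasets: Iterable[RejectionDataset], path,
                  extra_columns: Sequence[str] = ()) -> None:
    """Write a dataset collection to CSV (6 significant digits on floats)."""
    rows = []
    for ds in datasets:
        for _, o in ds.observations.iterrows():
            row = {
                "condition_id": ds.condition_id,
                "pH": _fmt(ds.pH),
                "ionic_strength_M": _fmt(ds.ionic_strength),
                "tmp_bar": _fmt(o["tmp_bar"]) if "tmp_bar" in o and not pd.isna(o["tmp_bar"]) else "",
                "flux_m_per_s": _fmt(o["v_w"]),
                "replicate": int(o["replicate"]),
                "r_obs": _fmt(o["r_obs"]),
            }
            for col in extra_columns:
                if col in o:
                    row[col] = _fmt(o[col])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
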