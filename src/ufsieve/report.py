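"""Structured reporting of fit and model-comparison results.

Writes three artefacts: a delimited-text parameter table (one row per
condition with estimates and 95% CI half-widths), a model-comparison
table (adjusted r^2 of both nested models plus the F test), and a
machine-readable JSON summary.  Floats are serialized with 6 significant
digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .model import ModelComparison, RejectionResults

__all__ = ["write_report"]

logger = logging.getLogger(__name__)

_DIGITS = 6


def _r(x) -> Optional[float]:
    if x is None:
        return None
    return float(f"{float(x):.{_DIGITS}g}")


def _param_row(fit: RejectionResults) -> dict:
    p = fit.params
    return {
        "condition_id": fit.model.dataset.condition_id,
        "model": fit.model.kind,
        "sigma": _r(p.sigma),
        "sigma_ci95": _r(fit.ci95.get("sigma")),
        "k_dbl": _r(p.k_dbl),
        "k_dbl_ci95": _r(fit.ci95.get("k_dbl")),
        "k_m": _r(p.k_m) if p.k_m is not None else None,
        "k_m_ci95": _r(fit.ci95.get("k_m")),
        "ss_res": _r(fit.ss_res),
        "df": fit.df_resid,
        "adj_r2": _r(fit.adj_r2),
        "n_obs": fit.n_obs,
        "converged": fit.converged,
    }


def write_report(
    fits: Sequence[RejectionResults],
    comparisons: Sequence[tuple],
    path,
) -> dict:
    """Write parameter, comparison and JSON summary files under ``path``.

    ``comparisons`` is a sequence of (condition_id, fit_small, fit_large,
    ModelComparison) tuples; when empty the comparison table is omitted
    (logged).  Returns the summary dict.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    if len(fits) == 0:
        raise ValueError("no fits to report")

    param_rows = [_param_row(f) for f in fits]
    pd.DataFrame(param_rows).to_csv(outdir / "parameters.csv", index=False)
    logger.info("wrote %d parameter row(s) to %s", len(param_rows),
                outdir / "parameters.csv")

    comp_rows = []
    for cid, fit_small, fit_large, comp in comparisons:
        comp_rows.append(
            {
                "condition_id": cid,
                "adj_r2_small": _r(fit_small.adj_r2),
                "adj_r2_large": _r(fit_large.adj_r2),
                "F": _r(comp.F),
                "p": _r(comp.p),
                "df1": comp.df1,
                "df2": comp.df2,
            }
        )
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(outdir / "comparisons.csv", index=False)
        logger.info("wrote %d comparison row(s) to %s", len(comp_rows),
                    outdir / "comparisons.csv")
    else:
        logger.info("no model comparisons; comparison table omitted")

    summary = {"parameters": param_rows, "comparisons": comp_rows}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
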