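"""Synthetic flux-rejection datasets with the structure of a pilot-scale study.

The emulated experiment: a 0.5% (w/v) BSA solution is ultrafiltered in a
spiral-wound module at constant crossflow (0.167 m/s) under six solution
conditions (pH 7 at 0, 0.08, 0.15 and 0.2 M NaCl; pH 4.9 at 0 and 0.2 M)
and five transmembrane pressures (0.2, 0.5, 0.8, 1.5 and 3 bar), with the
retentate and permeate concentrations assayed in duplicate at each point.

The generator works forward from known ground-truth transport parameters:
flux is a linear function of pressure (no cake layer / limiting flux),
the true rejection comes from the closed-form rejection equations, and
measurement error enters where it does in the laboratory — as independent
multiplicative Gaussian noise on the two concentration readings — before
the observed rejection is recomputed from the noisy pair.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datasets import RejectionDataset
from .transport import TransportParameters, observed_rejection, rejection_advection, rejection_general

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "default_design",
    "default_ground_truth",
    "condition_label",
    "flux_from_pressure",
    "simulate_dataset",
]


@dataclass(frozen=True)
class StudyDesign:
    """The experimental grid: conditions x pressures x replicates."""

    conditions: Tuple[Tuple[float, float], ...]  # (pH, ionic strength mol/L)
    pressures: Tuple[float, ...]  # TMP, bar
    replicates: int = 2
    protein_conc: float = 0.5  # % w/v
    crossflow: float = 0.167  # m/s

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        p = np.asarray(self.pressures, dtype=float)
        if np.any(p <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly positive and increasing")

    @property
    def condition_ids(self) -> List[str]:
        return [condition_label(pH, istr) for pH, istr in self.conditions]


def condition_label(pH: float, ionic_strength: float) -> str:
    """Canonical condition id, e.g. ``pH7.0_0.08M``."""
    return f"pH{pH:g}_{ionic_strength:g}M"


#: per-condition sieving coefficients used as the default ground truth;
#: representative of near-complete BSA rejection that relaxes with ionic
#: strength at pH 7 and stays high near the isoelectric point (pH 4.9)
_DEFAULT_SIGMAS = {
    (7.0, 0.0): 0.9993,
    (7.0, 0.08): 0.9935,
    (7.0, 0.15): 0.9686,
    (7.0, 0.2): 0.9646,
    (4.9, 0.0): 0.9977,
    (4.9, 0.2): 0.9916,
}

#: polarization-layer mass-transfer coefficient shared by all conditions, m/s
DEFAULT_KDBL = 7.34e-6


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for the synthetic study.

    params maps condition_id -> TransportParameters; permeability is the
    linear flux/TMP coefficient (m/s per bar); noise_sd_conc the relative
    standard deviation of each concentration reading.
    """

    params: Dict[str, TransportParameters]
    permeability: float = 5e-6  # m/s per bar; places Pe_d roughly in 0.1-2
    noise_sd_conc: float = 0.01
    seed: int = 20240126

    def __post_init__(self) -> None:
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")
        if self.noise_sd_conc < 0:
            raise ValueError("noise_sd_conc must be >= 0")


def default_design() -> StudyDesign:
    """The six-condition, five-pressure, duplicate-measurement grid."""
    return StudyDesign(
        conditions=((7.0, 0.0), (7.0, 0.08), (7.0, 0.15), (7.0, 0.2),
                    (4.9, 0.0), (4.9, 0.2)),
        pressures=(0.2, 0.5, 0.8, 1.5, 3.0),
        replicates=2,
        protein_conc=0.5,
        crossflow=0.167,
    )


def default_ground_truth(*, noise_sd_conc: float = 0.01,
                         seed: int = 20240126) -> GroundTruth:
    """Ground truth matching the default design (advection model)."""
    params = {
        condition_label(pH, istr): TransportParameters(sigma=s, k_dbl=DEFAULT_KDBL)
        for (pH, istr), s in _DEFAULT_SIGMAS.items()
    }
    return GroundTruth(params=params, noise_sd_conc=noise_sd_conc, seed=seed)


def flux_from_pressure(tmp: float, permeability: float) -> float:
    """Volumetric flux v_w = permeability * TMP.

    A linear clean-membrane law: valid below the limiting-flux regime
    (no cake layer)."""
    if tmp < 0 or permeability <= 0:
        raise ValueError("tmp must be >= 0 and permeability > 0")
    return permeability * tmp


def simulate_dataset(
    design: StudyDesign,
    truth: GroundTruth,
    model: str = "advection",
    *,
    seed: Optional[int] = None,
) -> List[RejectionDataset]:
    """Generate one synthetic dataset collection from the forward model.

    For each condition x pressure x replicate the flux follows the linear
    pressure law, the true rejection comes from the advection-dominated or
    general rejection equation, nominal concentrations are formed as
    c_ret = feed and c_per = (1 - R) * c_ret, both readings receive
    independent multiplicative Gaussian noise of relative sd
    ``truth.noise_sd_conc``, and the recorded R_obs is recomputed from the
    noisy pair.  With sigma = 1 the permeate is empty and multiplicative
    noise cannot move it, so R_obs stays exactly 1.

    ``seed`` overrides ``truth.seed``; the output is bit-reproducible for
    a fixed seed.
    """
    if model not in ("advection", "general"):
        raise ValueError(f"unknown model {model!r}")
    missing = [cid for cid in design.condition_ids if cid not in truth.params]
    if missing:
        raise ValueError(f"ground truth missing conditions: {missing}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    feed = design.protein_conc * 10.0  # % w/v -> g/L

    datasets: List[RejectionDataset] = []
    for (pH, istr), cid in zip(design.conditions, design.condition_ids):
        p = truth.params[cid]
        rows = []
        for tmp in design.pressures:
            v_w = flux_from_pressure(tmp, truth.permeability)
            pe_d = v_w / p.k_dbl
            if model == "general":
                if p.k_m is None:
                    raise ValueError(f"{cid}: general model requires k_m")
                r_true = float(rejection_general(p.sigma, pe_d, v_w / p.k_m))
            else:
                r_true = float(rejection_advection(p.sigma, pe_d))
            for rep in range(1, design.replicates + 1):
                c_ret = feed * (1.0 + truth.noise_sd_conc * rng.standard_normal())
                c_per = feed * (1.0 - r_true) * (
                    1.0 + truth.noise_sd_conc * rng.standard_normal()
                )
                c_per = max(c_per, 0.0)
                rows.append(
                    {
                        "v_w": v_w,
                        "r_obs": float(observed_rejection(c_ret, c_per)),
                        "replicate": rep,
                        "tmp_bar": tmp,
                        "c_retentate": c_ret,
                        "c_permeate": c_per,
                        "r_true": r_true,
                    }
                )
        datasets.append(
            RejectionDataset(
                condition_id=cid,
                pH=pH,
                ionic_strength=istr,
                observations=pd.DataFrame(rows),
            )
        )
    return datasets
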