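"""Predicted vs measured exchange-rate validation and ensemble selection.

Measured exchange rates (umol/gDW/hr; uptake negative, secretion positive)
are compared with a model's predicted exchange fluxes on three levels:

- qualitative: fraction of sign agreements (a |flux| below 1e-9 counts as
  zero and agrees only with a zero measurement);
- semi-quantitative: Spearman rank correlation over the compared pairs;
- quantitative: weighted Euclidean distance with scale-free weights
  w_i = 1 / max(|measured_i|, eps)^2.

Measurements flagged ``excluded`` (e.g. essential amino acids whose medium
accumulation cannot constrain de-novo synthesis) are removed before all
three metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import MetabolicModel
from .optimize import FluxState

ZERO_FLUX = 1e-9
WEIGHT_EPS = 1e-6


@dataclass
class ExchangeMeasurement:
    metabolite_id: str
    rate: float  # umol/gDW/hr, uptake negative
    excluded: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError(f"measurement for {self.metabolite_id!r} is not finite")


@dataclass
class ValidationReport:
    qualitative_accuracy: float
    spearman_rho: float
    weighted_euclidean: float
    n_compared: int


def read_measurements(path) -> list[ExchangeMeasurement]:
    """Measurement TSV: metabolite_id, rate, excluded (0/1)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ExchangeMeasurement(
            metabolite_id=row["metabolite_id"],
            rate=float(row["rate"]),
            excluded=bool(row.get("excluded", 0)),
        )
        for _, row in df.iterrows()
    ]


def write_measurements(measurements: list[ExchangeMeasurement], path) -> None:
    pd.DataFrame(
        {
            "metabolite_id": [m.metabolite_id for m in measurements],
            "rate": [m.rate for m in measurements],
            "excluded": [int(m.excluded) for m in measurements],
        }
    ).to_csv(path, sep="\t", index=False)


def _sign(x: float) -> int:
    if abs(x) < ZERO_FLUX:
        return 0
    return 1 if x > 0 else -1


def compare_exchanges(
    predicted: FluxState,
    model: MetabolicModel,
    measurements: list[ExchangeMeasurement],
) -> ValidationReport:
    """Multi-level consistency check of predicted vs measured exchanges."""
    flux = predicted.as_dict()
    pred, meas = [], []
    for m in measurements:
        if m.excluded:
            continue
        ex = model.exchange_for_metabolite(m.metabolite_id)
        if ex is None or ex not in flux:
            continue
        pred.append(flux[ex])
        meas.append(m.rate)
    if not pred:
        raise ValueError("no non-excluded measurement maps to a model exchange")
    pred_arr = np.array(pred)
    meas_arr = np.array(meas)
    agree = sum(_sign(p) == _sign(m) for p, m in zip(pred_arr, meas_arr))
    accuracy = agree / len(pred_arr)
    if len(pred_arr) > 1 and (np.ptp(pred_arr) > 0 or np.ptp(meas_arr) > 0):
        rho = spearmanr(pred_arr, meas_arr).statistic
        if np.isnan(rho):  # one vector constant
            rho = 0.0
    else:
        rho = 1.0 if len(pred_arr) == 1 else 0.0
    w = 1.0 / np.maximum(np.abs(meas_arr), WEIGHT_EPS) ** 2
    dist = float(np.sqrt(np.sum(w * (pred_arr - meas_arr) ** 2)))
    return ValidationReport(
        qualitative_accuracy=float(accuracy),
        spearman_rho=float(rho),
        weighted_euclidean=dist,
        n_compared=len(pred_arr),
    )


@dataclass
class SelectionCriteria:
    """Pass/fail thresholds; ``None`` disables a criterion."""

    min_accuracy: float | None = 0.65
    min_rho: float | None = 0.56
    max_distance: float | None = None


def select_models(
    reports: list[tuple[str, ValidationReport]],
    criteria: SelectionCriteria | None = None,
) -> list[str]:
    """Model ids passing all configured thresholds."""
    if not reports:
        raise ValueError("no validation reports supplied")
    criteria = criteria or SelectionCriteria()
    retained = []
    for model_id, rep in reports:
        ok = True
        if criteria.min_accuracy is not None and rep.qualitative_accuracy < criteria.min_accuracy:
            ok = False
        if criteria.min_rho is not None and rep.spearman_rho < criteria.min_rho:
            ok = False
        if criteria.max_distance is not None and rep.weighted_euclidean > criteria.max_distance:
            ok = False
        if ok:
            retained.append(model_id)
    if not retained:
        warnings.warn("no model passed the selection criteria", stacklevel=2)
    return retained
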