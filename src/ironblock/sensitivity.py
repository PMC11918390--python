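"""Scaled local sensitivity of the block characteristics to model parameters.

For a characteristic V and parameter p the scaled coefficient is

    R = (dV/V) / (dp/p)  =  d log V / d log p,

estimated by a one-sided forward perturbation (+10 % by default).  R is
dimensionless, so values can be compared across characteristics and
parameters; a negative sign means the characteristic moves opposite to the
parameter.

The time characteristics live on the interval grid of the block curve, so a
raw argmin is quantised.  Before differencing, each characteristic is made
continuous: the minimum is located by a parabolic fit through the three grid
points around the argmin, and the 95 %-recovery time by linear interpolation
of the threshold crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ModelConfig
from .block import (BlockAssayConfig, BlockCurve, basal_state, block_curve,
                    control_readout, _apply_scan_value)
from .model import Model

__all__ = ["SensitivityResult", "relative_sensitivity", "sensitivity_table",
            "smooth_characteristics", "TABLE_PARAMETERS",
            "NEGLIGIBLE_THRESHOLD"]

#: |dV/V| below this is reported as negligible ("-")
NEGLIGIBLE_THRESHOLD = 0.005

CHARACTERISTICS = ("min_uptake_time", "min_uptake_value",
                   "recovery_of_uptake_time", "min_transfer_time",
                   "min_transfer_value")

#: the ten scanned parameters, in published-table order.  "IRPs degradation"
#: maps to the IRPs inactivation rate constant and "FT turnover" to the
#: ferritin degradation constant (the network has no reactions with those
#: literal names).
TABLE_PARAMETERS = (
    "loading_dose",
    "fpn_inactivation.k_cat",
    "fpn_inactivation.K_m",
    "fpn_activation.k_cat",
    "ft_expression.k_cat",
    "ft_expression.K_m",
    "irps_inactivation.k_cat",   # "IRPs degradation"
    "ft_degradation.k_deg",      # "FT turnover"
    "fixed_FT",
    "dmt1_endocytosis_lip.k_cat",
)


@dataclass
class SensitivityResult:
    parameter: str
    characteristic: str
    R: float                # scaled coefficient, nan if negligible/undefined
    raw_s: float            # dV/dp estimate
    delta: float            # relative perturbation used
    baseline: float         # V at baseline
    perturbed: float        # V at p(1+delta)
    negligible: bool

    def __str__(self) -> str:
        return "-" if self.negligible else f"{self.R:.2f}"


def _parabolic_min(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Continuous minimum location/value via a 3-point parabolic fit."""
    i = int(np.argmin(y))
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:
        return float(x1), float(y1)
    xv = -b / (2 * a)
    if not (x0 <= xv <= x2):
        return float(x1), float(y1)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def smooth_characteristics(curve: BlockCurve, control_uptake: float
                           ) -> dict[str, float]:
    """Continuous (sub-grid) estimates of the five block characteristics."""
    x = curve.intervals_h
    mut, muv = _parabolic_min(x, curve.uptake_fmol)
    mtt, mtv = _parabolic_min(x, curve.transfer_fmol)
    thr = 0.95 * control_uptake
    rec = float("inf")
    i0 = int(np.argmin(curve.uptake_fmol))
    u = curve.uptake_fmol
    for j in range(i0, len(x)):
        if u[j] > thr:
            if j == i0:
                rec = float(x[j])
            else:
                f = (thr - u[j - 1]) / (u[j] - u[j - 1])
                rec = float(x[j - 1] + f * (x[j] - x[j - 1]))
            break
    return {"min_uptake_time": mut, "min_uptake_value": muv,
            "recovery_of_uptake_time": rec,
            "min_transfer_time": mtt, "min_transfer_value": mtv}


def _refine_intervals(base: np.ndarray, anchors_h: list[float],
                      factor: int = 3, span: int = 2) -> np.ndarray:
    """Insert ``factor``x-denser points within ``span`` grid steps of each
    anchor (anchors in hours, grid in seconds)."""
    pts = set(np.round(base, 6))
    step = base[1] - base[0] if len(base) > 1 else 3600.0
    for a in anchors_h:
        a_s = a * 3600.0
        lo = max(base[0], a_s - span * step)
        hi = min(base[-1], a_s + span * step)
        extra = np.arange(lo, hi + step / (2 * factor), step / factor)
        pts.update(np.round(extra, 6))
    return np.array(sorted(pts))


def _characteristics_for(config: ModelConfig, assay: BlockAssayConfig,
                         anchors_h: list[float] | None = None
                         ) -> tuple[dict[str, float], BlockCurve, float]:
    model = Model(config)
    basal = basal_state(model, assay.clamps)
    if anchors_h:
        assay = replace(assay,
                        intervals=_refine_intervals(assay.intervals, anchors_h))
    curve = block_curve(model, assay, basal=basal)
    ctrl, _ = control_readout(model, assay, basal=basal)
    return smooth_characteristics(curve, ctrl), curve, ctrl


def relative_sensitivity(config: ModelConfig, assay: BlockAssayConfig,
                         parameter: str, characteristic: str | None = None,
                         delta: float = 0.10,
                         baseline: dict[str, float] | None = None,
                         refine: bool = True):
    """Scaled sensitivity of block characteristics to one parameter.

    Returns a dict of :class:`SensitivityResult` per characteristic (or a
    single result if ``characteristic`` is given).  ``baseline`` can carry
    precomputed baseline characteristics to avoid recomputation across
    parameters.
    """
    if parameter == "fixed_FT" and "FT" not in assay.clamps:
        # the fixed-[FT] row perturbs the clamped ferritin level
        assay = replace(assay, clamps={**assay.clamps,
                                       "FT": Model(config).config.initial["FT"]})

    if baseline is None:
        base_chars, curve, _ = _characteristics_for(config, assay)
        if refine:
            anchors = [base_chars["min_uptake_time"],
                       base_chars["min_transfer_time"]]
            if np.isfinite(base_chars["recovery_of_uptake_time"]):
                anchors.append(base_chars["recovery_of_uptake_time"])
            base_chars, _, _ = _characteristics_for(config, assay, anchors)
    else:
        base_chars = baseline

    if parameter == "loading_dose":
        p0 = assay.loading_dose
    elif parameter == "fixed_FT":
        p0 = assay.clamps["FT"]
    else:
        p0 = config.get_rate(parameter)
    cfg_p, assay_p = _apply_scan_value(config, assay, parameter,
                                       p0 * (1.0 + delta))
    pert_chars, _, _ = _characteristics_for(cfg_p, assay_p)
    if refine:
        anchors = [pert_chars["min_uptake_time"],
                   pert_chars["min_transfer_time"]]
        if np.isfinite(pert_chars["recovery_of_uptake_time"]):
            anchors.append(pert_chars["recovery_of_uptake_time"])
        pert_chars, _, _ = _characteristics_for(cfg_p, assay_p, anchors)

    out = {}
    for name in CHARACTERISTICS:
        v0, v1 = base_chars[name], pert_chars[name]
        if not (np.isfinite(v0) and np.isfinite(v1)) or v0 == 0:
            raise RuntimeError(
                f"characteristic {name} undefined for {parameter} "
                f"(baseline {v0}, perturbed {v1})")
        rel = (v1 - v0) / v0
        negligible = abs(rel) < NEGLIGIBLE_THRESHOLD
        out[name] = SensitivityResult(
            parameter=parameter, characteristic=name,
            R=rel / delta, raw_s=(v1 - v0) / (delta * p0),
            delta=delta, baseline=v0, perturbed=v1, negligible=negligible)
    if characteristic is not None:
        return out[characteristic]
    return out


def sensitivity_table(config: ModelConfig, assay: BlockAssayConfig,
                      parameters=TABLE_PARAMETERS, delta: float = 0.10,
                      ft_km_at_kcat: float = 1.5e-12):
    """Full sensitivity table (parameters x five characteristics).

    The FT-expression K_m row is evaluated at the elevated expression rate
    ``ft_km_at_kcat`` where its effect is largest; all other rows use the
    baseline model.  Failed rows are recorded as None (table marked partial).
    """
    rows: dict[str, dict | None] = {}
    for p in parameters:
        cfg = config.copy()
        if p == "ft_expression.K_m" and ft_km_at_kcat is not None:
            cfg.set_rate("ft_expression.k_cat", ft_km_at_kcat)
        try:
            rows[p] = relative_sensitivity(cfg, assay, p, delta=delta)
        except Exception:
            rows[p] = None
    return rows


def table_to_frame(rows):
    """Render a sensitivity table as a DataFrame ('-' for negligible)."""
    import pandas as pd
    data = {}
    for p, row in rows.items():
        if row is None:
            data[p] = {c: "!" for c in CHARACTERISTICS}
        else:
            data[p] = {c: str(row[c]) for c in CHARACTERISTICS}
    return pd.DataFrame(data).T[list(CHARACTERISTICS)]
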