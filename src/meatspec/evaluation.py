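"""Simplified multispectral model rebuilding and limit of detection.

After wavelength selection, PLSR is refitted on the reduced band set (the
"multispectral" model) and scored with the same LOOCV / prediction-set
protocol as the full-spectrum model, so the two are directly comparable.

The limit of detection follows the blank-based two-sigma convention:

    LOD = 2 * delta_b / S

where ``delta_b`` is the standard deviation (n-1) of the model response on
blank (0 % adulteration, pure pork) samples and ``S`` is the sensitivity --
the slope of the predicted-vs-reference least-squares line on the
calibration set (a prediction-set slope is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SpectraTable, make_pretreatment
from .regression import (
    ModelReport,
    PLSRegressionNIPALS,
    evaluate,
    loocv_predictions,
    loocv_select,
)
from .selection import WavelengthSet

__all__ = [
    "LodResult",
    "fit_report",
    "refit_multispectral",
    "calibration_slope",
    "limit_of_detection",
]


def fit_report(
    table: SpectraTable,
    pretreatment: str,
    max_lv: int = 20,
    n_lv: int | None = None,
) -> tuple[PLSRegressionNIPALS, ModelReport]:
    """Pretreat, select the LV count by LOOCV, fit, and score a PLSR model.

    The pretreatment chain is fitted on the calibration rows and applied to
    all rows; LOOCV runs over the calibration set only.  Returns the fitted
    model (trained at the selected LV count on the full calibration set) and
    a report row with R^2/RMSE for calibration, cross-validation and
    prediction plus the prediction-set RPD.
    """
    pt = table.pretreated(make_pretreatment(pretreatment), pretreatment)
    X_cal, y_cal = pt.X_cal, pt.y_cal
    max_lv = min(max_lv, len(y_cal) - 2, X_cal.shape[1])
    if n_lv is None:
        n_lv, rmsecv_curve = loocv_select(X_cal, y_cal, max_lv)
        rmsecv = float(rmsecv_curve[n_lv - 1])
        cv_pred = loocv_predictions(X_cal, y_cal, n_lv)[:, n_lv - 1]
    else:
        cv_pred = loocv_predictions(X_cal, y_cal, n_lv)[:, n_lv - 1]
        rmsecv = float(np.sqrt(np.mean((cv_pred - y_cal) ** 2)))
    model = PLSRegressionNIPALS(n_components=n_lv).fit(X_cal, y_cal)
    model.pretreatment_tag_ = pretreatment

    cal = evaluate(y_cal, model.predict(X_cal))
    cv = evaluate(y_cal, cv_pred)
    pred = evaluate(pt.y_pred, model.predict(pt.X_pred))
    report = ModelReport(
        pretreatment=pretreatment,
        n_lv=n_lv,
        r2_c=cal["r2"],
        rmsec=cal["rmse"],
        r2_cv=cv["r2"],
        rmsecv=rmsecv,
        r2_p=pred["r2"],
        rmsep=pred["rmse"],
        rpd=pred["rpd"],
    )
    return model, report


def refit_multispectral(
    table: SpectraTable,
    bands: WavelengthSet,
    pretreatment: str = "snv",
    max_lv: int = 20,
    pretreat_on: str = "subset",
) -> tuple[PLSRegressionNIPALS, ModelReport]:
    """Rebuild a PLSR model on a selected band subset.

    ``pretreat_on="subset"`` (default) applies the pretreatment to the
    reduced spectra, as a real multispectral instrument would observe them;
    ``"full"`` pretreats the full spectra first and then drops columns.
    The full fit/LOOCV/evaluate cycle is rerun, so the returned report is
    directly comparable to the full-spectrum one.
    """
    if len(bands) == 0:
        raise ValueError(f"wavelength set {bands.method!r} is empty; cannot refit")
    if pretreat_on not in ("subset", "full"):
        raise ValueError("pretreat_on must be 'subset' or 'full'")
    if pretreat_on == "full":
        pt = table.pretreated(make_pretreatment(pretreatment), pretreatment)
        sub = pt.restrict(bands.band_indices)
        model, report = fit_report(sub, "none", max_lv=max_lv)
        # the data already carry the chain; label the model with the real tag
        report.pretreatment = pretreatment
        model.pretreatment_tag_ = pretreatment
    else:
        sub = table.restrict(bands.band_indices)
        model, report = fit_report(sub, pretreatment, max_lv=max_lv)
    model.band_indices_ = bands.band_indices
    model.selection_method_ = bands.method
    report.pretreatment = f"{pretreatment}[{bands.method}:{len(bands)}]"
    return model, report


@dataclass
class LodResult:
    """Limit-of-detection summary: LOD = 2 * delta_b / S."""

    delta_b: float  # SD of blank-sample predictions, % w/w
    S: float        # calibration-line slope (predicted vs reference)
    lod: float      # % w/w

    def __post_init__(self) -> None:
        if self.lod < 0:
            raise ValueError("LOD cannot be negative")


def calibration_slope(y_ref, y_pred) -> float:
    """Slope of the least-squares line of predicted vs reference values."""
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    yc = y_ref - y_ref.mean()
    denom = float(yc @ yc)
    if denom == 0:
        raise ValueError("reference values are constant; slope undefined")
    return float(yc @ (y_pred - y_pred.mean()) / denom)


def limit_of_detection(
    model,
    blank_spectra: np.ndarray,
    calibration_line_slope: float,
) -> LodResult:
    """Blank-based LOD of a fitted model.

    ``blank_spectra`` are spectra of 0 %-level (pure pork) samples, already
    in the model's input space (same pretreatment and band subset).  delta_b
    is the n-1 SD of their predictions; the slope comes from
    :func:`calibration_slope` on the calibration set.
    """
    blank_spectra = np.atleast_2d(np.asarray(blank_spectra, dtype=float))
    if blank_spectra.shape[0] < 2:
        raise ValueError("LOD needs at least 2 blank samples")
    S = float(calibration_line_slope)
    if S <= 0:
        raise ValueError(f"degenerate calibration: slope must be positive, got {S}")
    delta_b = float(np.std(model.predict(blank_spectra), ddof=1))
    return LodResult(delta_b=delta_b, S=S, lod=2.0 * delta_b / S)
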