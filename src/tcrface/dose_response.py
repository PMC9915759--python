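"""Four-parameter logistic (4PL) dose-response fitting and selectivity.

The model is the standard Hill equation

    R(d) = bottom + (top - bottom) / (1 + (ec50 / d)^hill)

fit by least squares on log10(dose) via lmfit. EC50 is the dose of
half-maximal response by construction: R(ec50) = (top + bottom) / 2.
Confidence intervals for EC50 come from a seeded residual bootstrap
(the method is flagged in the output).

Selectivity between two ligands (e.g. mutant vs wild-type peptide) is
the plain EC50 ratio after unit normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Minimizer, Parameters

from .errors import FitError, ValidationError

__all__ = [
    "TitrationSeries",
    "CurveFit",
    "four_pl",
    "fit_4pl",
    "selectivity_ratio",
    "MOLAR_UNITS",
]

#: Multipliers to molar for the usual concentration units.
MOLAR_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6, "µM": 1e-6, "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}


def to_molar(value: float, unit: str = "M") -> float:
    try:
        return float(value) * MOLAR_UNITS[unit]
    except KeyError:
        raise ValidationError(f"unknown concentration unit {unit!r}")


@dataclass(frozen=True)
class TitrationSeries:
    """Dose-response observations; doses in molar, strictly positive."""

    doses: np.ndarray
    responses: np.ndarray
    replicate_ids: tuple | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "responses", r)
        if d.shape != r.shape or d.ndim != 1:
            raise ValidationError("doses and responses must be equal-length 1-D")
        if not np.all(d > 0):
            raise ValidationError("doses must be strictly positive (molar)")
        if not np.all(np.isfinite(r)):
            raise ValidationError("responses must be finite")
        if len(np.unique(d)) < 5:
            raise ValidationError(
                f"need >= 5 distinct doses for a 4PL fit, got {len(np.unique(d))}"
            )


def four_pl(dose, bottom: float, top: float, ec50: float, hill: float):
    """4PL response at ``dose`` (same units as ``ec50``)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


@dataclass(frozen=True)
class CurveFit:
    """Fitted 4PL parameters with a bootstrap EC50 interval."""

    bottom: float
    top: float
    ec50: float
    hill: float
    ci95_ec50: tuple[float, float]
    ci_method: str
    residual_sd: float
    n_points: int
    flat_data_warning: bool = False

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.top <= self.bottom:
            raise ValueError("top must exceed bottom")

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)


def _residual(params: Parameters, logd: np.ndarray, resp: np.ndarray):
    model = params["bottom"] + (params["top"] - params["bottom"]) / (
        1.0 + 10.0 ** (params["hill"] * (params["log_ec50"] - logd))
    )
    return model - resp


def _fit_once(logd: np.ndarray, resp: np.ndarray) -> Parameters:
    lo, hi = float(resp.min()), float(resp.max())
    span = max(hi - lo, 1e-12)
    params = Parameters()
    params.add("bottom", value=lo, min=lo - span, max=hi + span)
    params.add("top", value=hi, min=lo - span, max=hi + 2 * span)
    params.add("log_ec50", value=float(np.median(logd)),
               min=float(logd.min()) - 3.0, max=float(logd.max()) + 3.0)
    params.add("hill", value=1.0, min=0.1, max=10.0)
    result = Minimizer(_residual, params, fcn_args=(logd, resp)).minimize(
        method="leastsq"
    )
    if not result.success:
        raise FitError(f"4PL fit did not converge: {result.message}")
    return result.params


def fit_4pl(
    series: TitrationSeries,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> CurveFit:
    """Least-squares 4PL fit on log10(dose).

    The Hill slope is bounded to (0.1, 10]; initial values come from the
    data range and the median log-dose. The 95% CI for EC50 is a seeded
    residual bootstrap (``n_bootstrap`` refits); set ``n_bootstrap=0``
    to skip it (the interval then degenerates to the point estimate).
    """
    logd = np.log10(series.doses)
    resp = series.responses
    span = resp.max() - resp.min()
    flat = bool(span < 1e-3 * max(abs(resp).max(), 1.0) or span == 0.0)
    if flat:
        raise FitError(
            "responses are flat across all doses; a 4PL dose-response "
            "cannot be identified"
        )
    params = _fit_once(logd, resp)
    fitted = resp + _residual(params, logd, resp)
    residuals = resp - fitted
    resid_sd = float(np.std(residuals, ddof=min(4, len(resp) - 1)))

    ec50 = 10.0 ** params["log_ec50"].value
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_bootstrap):
            perturbed = fitted + rng.choice(residuals, size=len(residuals), replace=True)
            try:
                p = _fit_once(logd, perturbed)
                boots.append(10.0 ** p["log_ec50"].value)
            except FitError:
                continue
        if len(boots) >= max(20, n_bootstrap // 4):
            lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo_ci), float(hi_ci))
            method = f"residual bootstrap (n={len(boots)}, seed={seed})"
        else:
            ci = (ec50, ec50)
            method = "bootstrap failed; point estimate only"
    else:
        ci = (ec50, ec50)
        method = "none"

    # Detect monotonicity trouble: correlation of response with log-dose.
    order = np.argsort(logd)
    rho = float(np.corrcoef(logd[order], resp[order])[0, 1])
    warn = bool(abs(rho) < 0.2)

    return CurveFit(
        bottom=float(params["bottom"].value),
        top=float(params["top"].value),
        ec50=float(ec50),
        hill=float(params["hill"].value),
        ci95_ec50=ci,
        ci_method=method,
        residual_sd=resid_sd,
        n_points=len(resp),
        flat_data_warning=warn,
    )


def selectivity_ratio(
    ec50_reference: float,
    ec50_test: float,
    unit_reference: str = "M",
    unit_test: str = "M",
) -> float:
    """Fold-selectivity: EC50(reference) / EC50(test).

    With the wild-type ligand as reference and the mutant as test, a
    value > 1 means the receptor is that many fold more sensitive to
    the mutant. Units are normalised to molar before dividing.
    """
    ref = to_molar(ec50_reference, unit_reference)
    test = to_molar(ec50_test, unit_test)
    if ref <= 0 or test <= 0:
        raise ValidationError("EC50 values must be positive")
    return ref / test
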