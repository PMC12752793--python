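"""One-site dose-response fitting and cytotoxicity / screening statistics.

The one-site binding model

    Y(X) = top * X / (half_dose + X)

is fit by least squares with the half-dose in log space, so that rescaling
all doses by a constant rescales the fitted half-dose by exactly the same
constant.  ``top`` is the plateau (Bmax for binding signals, maximal
percent lysis for cytotoxicity); ``half_dose`` is the EC50 or ED50.

Also here: the chromium-release specific-lysis statistic, the ELISA
positivity rule (specific/aspecific signal ratio strictly above 10), RMFI
normalization, and fold-change helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponse",
    "OneSiteFit",
    "LysisPlate",
    "PlateauWarning",
    "fit_one_site",
    "one_site_model",
    "specific_lysis",
    "elisa_positive",
    "rmfi",
    "fold_change",
]


class PlateauWarning(UserWarning):
    """The dose range did not reach the fitted plateau."""


@dataclass
class DoseResponse:
    dose: np.ndarray  # molar
    signal: np.ndarray  # RMFI or percent lysis
    replicate_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.dose.shape != self.signal.shape:
            raise ValueError("dose/signal length mismatch")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be positive")

    @classmethod
    def from_tsv(cls, path) -> "DoseResponse":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        se = df["se"].to_numpy() if "se" in df.columns else None
        return cls(df["dose_M"].to_numpy(), df["signal"].to_numpy(), se)


@dataclass
class OneSiteFit:
    top: float  # plateau (Bmax / max lysis %)
    half_dose: float  # EC50 or ED50, molar
    rss: float = np.nan
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.top <= 0 or self.half_dose <= 0:
            raise ValueError("top and half_dose must be positive")

    def predict(self, dose) -> np.ndarray:
        return one_site_model(np.asarray(dose, dtype=float), self.top, self.half_dose)


def one_site_model(dose: np.ndarray, top: float, half_dose: float) -> np.ndarray:
    """Y = top * X / (half_dose + X); Y(half_dose) = top/2 by construction."""
    return top * dose / (half_dose + dose)


def fit_one_site(dr: DoseResponse) -> OneSiteFit:
    """Least-squares one-site fit of (top, half_dose) with log-dose scaling.

    Requires at least four doses.  Warns (:class:`PlateauWarning`) when the
    largest dose is below three times the fitted half-dose, i.e. the
    plateau was not approached within the measured range.
    """
    if dr.dose.size < 4:
        raise ValueError("need >= 4 doses")
    x, y = dr.dose, dr.signal
    top0 = max(float(y.max()), 1e-12)
    # initial half-dose: dose nearest half the maximal signal
    half0 = float(x[np.argmin(np.abs(y - top0 / 2))])

    def resid(p):
        top, log_half = p
        return one_site_model(x, top, 10.0**log_half) - y

    sol = least_squares(
        resid, [top0, np.log10(half0)], method="lm", xtol=1e-15, ftol=1e-15
    )
    top, half = float(sol.x[0]), float(10.0 ** sol.x[1])
    if x.max() < 3 * half:
        warnings.warn(
            f"max dose {x.max():.3g} M < 3 x fitted half_dose {half:.3g} M; "
            "plateau not reached",
            PlateauWarning,
            stacklevel=2,
        )
    return OneSiteFit(
        top=top, half_dose=half, rss=float(np.sum(sol.fun**2)), n_points=x.size
    )


@dataclass
class LysisPlate:
    """Counts-per-minute triplicates from a chromium-release assay."""

    experimental: np.ndarray
    spontaneous: np.ndarray
    maximal: np.ndarray

    def __post_init__(self) -> None:
        self.experimental = np.atleast_1d(np.asarray(self.experimental, dtype=float))
        self.spontaneous = np.atleast_1d(np.asarray(self.spontaneous, dtype=float))
        self.maximal = np.atleast_1d(np.asarray(self.maximal, dtype=float))
        if self.maximal.mean() <= self.spontaneous.mean():
            raise ValueError("maximal release must exceed spontaneous release")


def specific_lysis(plate: LysisPlate) -> tuple[np.ndarray, float]:
    """Percent specific lysis per experimental replicate, plus the mean.

    (experimental - spontaneous) / (maximal - spontaneous) * 100, with the
    plate-mean spontaneous and maximal releases.  Values outside [0, 100]
    are reported as-is (never clipped).
    """
    spont = plate.spontaneous.mean()
    denom = plate.maximal.mean() - spont
    if denom == 0:
        raise ZeroDivisionError("maximal equals spontaneous release")
    per_rep = (plate.experimental - spont) / denom * 100.0
    return per_rep, float(per_rep.mean())


def elisa_positive(specific_signal: float, aspecific_signal: float) -> bool:
    """Screening rule: positive iff specific/aspecific ratio strictly > 10."""
    if aspecific_signal <= 0:
        raise ValueError("aspecific signal must be positive")
    return specific_signal / aspecific_signal > 10.0


def rmfi(sample_median: float, control_median: float) -> float:
    """Ratio of median fluorescence intensities, sample over control."""
    if control_median <= 0:
        raise ValueError("control median must be positive")
    return sample_median / control_median


def fold_change(a: float, b: float) -> float:
    """a / b: fold ratio of two affinities or effective doses."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b
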