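"""Single-cycle-kinetics SPR forward models and fits.

Two standard interaction schemes for a single-cycle titration (increasing
analyte concentrations injected back-to-back, one final dissociation, no
regeneration between steps):

1:1 Langmuir
    dR/dt = ka * C(t) * (Rmax - R) - kd * R,        KD = kd / ka

Bivalent analyte (two-armed analyte crosslinking two surface ligands)
    A + L  <-> AL    (ka1 [1/(M s)], kd1 [1/s])
    AL + L <-> AL2   (ka2 [1/(RU s)], kd2 [1/s])
    dAL/dt  = ka1*C*Lfree - kd1*AL - ka2*AL*Lfree + kd2*AL2
    dAL2/dt = ka2*AL*Lfree - kd2*AL2
    Lfree   = Rmax - AL - 2*AL2,    response = AL + AL2
    apparent KD = kd1 / ka1

The second step's association constant follows the response-unit convention
of SPR evaluation software (ka2 in 1/(RU*s)), so the model reduces exactly
to the Langmuir model at ka2 = 0.

Forward traces are integrated with a fixed-step classical Runge-Kutta
scheme (dt = 0.1 s default) for bit-reproducibility; fits are nonlinear
least squares in log-parameter space with seeded multi-start
initialization.  For the 1:1 model the fit uses the exact piecewise
exponential solution, which coincides with the integrated trace to well
below instrument noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "InjectionSchedule",
    "Sensorgram",
    "KineticFit",
    "FitNonConvergenceError",
    "simulate_langmuir_sck",
    "simulate_bivalent_sck",
    "fit_langmuir",
    "fit_bivalent",
    "langmuir_closed_form",
    "DEFAULT_SCHEDULE",
]


class FitNonConvergenceError(RuntimeError):
    """Fit failed; carries diagnostics instead of returning silently."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class InjectionSchedule:
    """Single-cycle titration: each concentration associates for ``t_assoc``
    seconds, followed by one final buffer dissociation of ``t_dissoc``."""

    concentrations: tuple[float, ...]
    t_assoc: float = 120.0
    t_dissoc: float = 600.0

    def __post_init__(self) -> None:
        c = self.concentrations
        if not c or any(x <= 0 for x in c) or any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("concentrations must be strictly increasing and positive")
        if self.t_assoc <= 0 or self.t_dissoc <= 0:
            raise ValueError("phase durations must be positive")

    @property
    def total_time(self) -> float:
        return len(self.concentrations) * self.t_assoc + self.t_dissoc

    def concentration_at(self, t: float) -> float:
        """Stepwise analyte concentration C(t); 0 during dissociation."""
        k = int(t // self.t_assoc)
        if t < 0 or k >= len(self.concentrations):
            return 0.0
        return self.concentrations[k]

    def phases(self) -> list[tuple[float, float, float]]:
        """(t_start, t_end, concentration) per phase, dissociation last."""
        out = []
        t = 0.0
        for c in self.concentrations:
            out.append((t, t + self.t_assoc, c))
            t += self.t_assoc
        out.append((t, t + self.t_dissoc, 0.0))
        return out


#: The titration used throughout: 12.5-200 nM two-fold steps, 2 min
#: association each, 10 min dissociation.
DEFAULT_SCHEDULE = InjectionSchedule(
    concentrations=(12.5e-9, 25e-9, 50e-9, 100e-9, 200e-9),
    t_assoc=120.0,
    t_dissoc=600.0,
)


@dataclass
class Sensorgram:
    time: np.ndarray  # seconds
    response: np.ndarray  # RU
    schedule: InjectionSchedule

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time/response length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "response_RU": self.response})


@dataclass
class KineticFit:
    model: str  # "langmuir" | "bivalent"
    ka: float
    kd: float
    rmax: float
    ka2: float | None = None
    kd2: float | None = None
    rss: float = np.nan
    n_points: int = 0

    @property
    def KD(self) -> float:
        """Equilibrium (apparent, for bivalent) dissociation constant kd/ka."""
        return self.kd / self.ka


def _rk4(f, y0: np.ndarray, t0: float, t1: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step RK4 over [t0, t1]; returns (times, states)."""
    n = max(1, int(round((t1 - t0) / dt)))
    h = (t1 - t0) / n
    ts = t0 + h * np.arange(n + 1)
    ys = np.empty((n + 1, len(y0)))
    y = np.array(y0, dtype=float)
    ys[0] = y
    for i in range(n):
        t = ts[i]
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ys[i + 1] = y
    return ts, ys


def _integrate_phases(rhs_factory, y0, schedule: InjectionSchedule, dt: float):
    """Integrate piecewise-constant-C phases, keeping the state continuous."""
    times, states = [np.array([0.0])], [np.array([y0])]
    y = np.array(y0, dtype=float)
    for t0, t1, c in schedule.phases():
        ts, ys = _rk4(rhs_factory(c), y, t0, t1, dt)
        y = ys[-1]
        times.append(ts[1:])
        states.append(ys[1:])
    return np.concatenate(times), np.concatenate(states)


def simulate_langmuir_sck(
    ka: float,
    kd: float,
    rmax: float,
    schedule: InjectionSchedule = DEFAULT_SCHEDULE,
    dt: float = 0.1,
) -> Sensorgram:
    """Integrate the 1:1 model over a single-cycle schedule."""
    if min(ka, kd, rmax) <= 0:
        raise ValueError("parameters must be positive")
    if dt > 1.0:
        raise ValueError("dt must be <= 1 s")

    def factory(c):
        return lambda t, y: np.array([ka * c * (rmax - y[0]) - kd * y[0]])

    ts, ys = _integrate_phases(factory, [0.0], schedule, dt)
    return Sensorgram(time=ts, response=ys[:, 0], schedule=schedule)


def langmuir_closed_form(
    ka: float,
    kd: float,
    rmax: float,
    schedule: InjectionSchedule,
    t: np.ndarray,
) -> np.ndarray:
    """Exact piecewise-exponential 1:1 response at arbitrary times ``t``.

    Within a phase at constant C:  R(t) = Req + (R0 - Req) exp(-(ka C + kd) t)
    with Req = ka C Rmax / (ka C + kd).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    r0 = 0.0
    for t0, t1, c in schedule.phases():
        k_obs = ka * c + kd
        req = ka * c * rmax / k_obs if k_obs > 0 else 0.0
        mask = (t >= t0) & (t <= t1)
        out[mask] = req + (r0 - req) * np.exp(-k_obs * (t[mask] - t0))
        r0 = req + (r0 - req) * np.exp(-k_obs * (t1 - t0))
    return out


def simulate_bivalent_sck(
    ka1: float,
    kd1: float,
    ka2: float,
    kd2: float,
    rmax: float,
    schedule: InjectionSchedule = DEFAULT_SCHEDULE,
    dt: float = 0.1,
) -> Sensorgram:
    """Integrate the bivalent-analyte model over a single-cycle schedule.

    ``ka2 = 0`` (with the second species starting empty) reduces exactly to
    the 1:1 model.  Free-ligand conservation AL + 2*AL2 <= Rmax holds at
    every step.
    """
    if min(ka1, kd1, rmax) <= 0 or ka2 < 0 or kd2 < 0:
        raise ValueError("rate parameters must be positive (ka2, kd2 >= 0)")

    def factory(c):
        def rhs(t, y):
            al, al2 = y
            lfree = rmax - al - 2.0 * al2
            return np.array(
                [
                    ka1 * c * lfree - kd1 * al - ka2 * al * lfree + kd2 * al2,
                    ka2 * al * lfree - kd2 * al2,
                ]
            )

        return rhs

    ts, ys = _integrate_phases(factory, [0.0, 0.0], schedule, dt)
    return Sensorgram(time=ts, response=ys.sum(axis=1), schedule=schedule)


def _bivalent_on_grid(
    params: np.ndarray, schedule: InjectionSchedule, t: np.ndarray, dt: float = 1.0
) -> np.ndarray:
    """Bivalent response evaluated on the data grid (RK4, coarse step).

    No input validation: this is the fit's inner loop, and wild multi-start
    parameters may legitimately overflow (the caller maps non-finite
    residuals to a large penalty).
    """
    ka1, kd1, ka2, kd2, rmax = params

    def factory(c):
        def rhs(_t, y):
            al, al2 = y
            lfree = rmax - al - 2.0 * al2
            return np.array(
                [
                    ka1 * c * lfree - kd1 * al - ka2 * al * lfree + kd2 * al2,
                    ka2 * al * lfree - kd2 * al2,
                ]
            )

        return rhs

    ts, ys = _integrate_phases(factory, [0.0, 0.0], schedule, dt)
    return np.interp(t, ts, ys.sum(axis=1))


_START_GRID = {"ka": (1e3, 1e7), "kd": (1e-5, 1e-1)}


def _multistart(rng: np.random.Generator, n: int, bounds: list[tuple[float, float]]):
    for _ in range(n):
        yield [10 ** rng.uniform(np.log10(lo), np.log10(hi)) for lo, hi in bounds]


def _run_starts(resid, rng, n_starts, start_ranges, log_bounds, xtol=1e-14):
    """Seeded multi-start bounded least squares in log10-parameter space."""
    lo, hi = log_bounds
    best = None
    for start in _multistart(rng, n_starts, start_ranges):
        x0 = np.clip(np.log10(start), lo, hi)
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf", xtol=xtol, ftol=xtol
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise FitNonConvergenceError("all starts failed", {"n_starts": n_starts})
    return best


def _check_signal(sg: Sensorgram) -> None:
    span = float(np.ptp(sg.response))
    if span <= 0 or not np.isfinite(span):
        raise FitNonConvergenceError(
            "sensorgram carries no signal to fit",
            {"response_span": span, "n_points": sg.time.size},
        )


def fit_langmuir(
    sensorgram: Sensorgram, n_starts: int = 5, seed: int = 0
) -> KineticFit:
    """Least-squares 1:1 fit of (ka, kd, Rmax) to a single-cycle trace.

    Multi-start log-space initialization (ka in [1e3, 1e7] 1/(M s), kd in
    [1e-5, 1e-1] 1/s, seeded); best residual sum of squares wins.  Raises
    :class:`FitNonConvergenceError` with diagnostics on degenerate input.
    """
    if len(sensorgram.schedule.concentrations) < 2:
        raise ValueError("need >= 2 association phases")
    _check_signal(sensorgram)
    t, y = sensorgram.time, sensorgram.response
    rmax_guess = max(float(y.max()), 1e-6)

    def resid(logp):
        ka, kd, rmax = 10.0 ** np.asarray(logp)
        model = langmuir_closed_form(ka, kd, rmax, sensorgram.schedule, t)
        return np.nan_to_num(model - y, nan=1e6, posinf=1e6, neginf=-1e6)

    rng = np.random.default_rng(seed)
    starts = [_START_GRID["ka"], _START_GRID["kd"], (rmax_guess, rmax_guess * 10)]
    lo = [1.0, -8.0, np.log10(rmax_guess) - 2]
    hi = [9.0, 2.0, np.log10(rmax_guess) + 3]
    best = _run_starts(resid, rng, n_starts, starts, (lo, hi))
    rss, sol = best
    ka, kd, rmax = 10.0**sol.x
    fit = KineticFit(model="langmuir", ka=ka, kd=kd, rmax=rmax, rss=rss, n_points=t.size)
    _sanity_check(fit, y)
    return fit


def fit_bivalent(
    sensorgram: Sensorgram, n_starts: int = 5, seed: int = 0, dt: float = 1.0
) -> KineticFit:
    """Least-squares bivalent fit of (ka1, kd1, ka2, kd2, Rmax).

    Same multi-start strategy as the 1:1 fit; the second-step constants
    start log-uniform in ka2 [1e-6, 1e-1] 1/(RU s), kd2 [1e-5, 1e-1] 1/s.
    Reported KD is the apparent kd1/ka1.
    """
    if len(sensorgram.schedule.concentrations) < 2:
        raise ValueError("need >= 2 association phases")
    _check_signal(sensorgram)
    t, y = sensorgram.time, sensorgram.response
    rmax_guess = max(float(y.max()), 1e-6)

    def resid(logp):
        params = 10.0 ** np.asarray(logp)
        with np.errstate(all="ignore"):
            model = _bivalent_on_grid(params, sensorgram.schedule, t, dt=dt)
        return np.nan_to_num(model - y, nan=1e6, posinf=1e6, neginf=-1e6)

    rng = np.random.default_rng(seed)
    starts = [
        _START_GRID["ka"],
        _START_GRID["kd"],
        (1e-6, 1e-1),
        (1e-5, 1e-1),
        (rmax_guess, rmax_guess * 10),
    ]
    lo = [1.0, -8.0, -9.0, -8.0, np.log10(rmax_guess) - 2]
    hi = [8.0, 1.0, 0.0, 1.0, np.log10(rmax_guess) + 3]
    best = _run_starts(resid, rng, n_starts, starts, (lo, hi), xtol=1e-12)
    rss, sol = best
    ka1, kd1, ka2, kd2, rmax = 10.0**sol.x
    fit = KineticFit(
        model="bivalent", ka=ka1, kd=kd1, ka2=ka2, kd2=kd2, rmax=rmax,
        rss=rss, n_points=t.size,
    )
    _sanity_check(fit, y)
    return fit


def _sanity_check(fit: KineticFit, y: np.ndarray) -> None:
    span = float(np.ptp(y))
    if fit.rss > (0.5 * span) ** 2 * y.size:
        raise FitNonConvergenceError(
            "residuals comparable to signal span: no kinetic model explains the trace",
            {"rss": fit.rss, "span": span, "model": fit.model,
             "ka": fit.ka, "kd": fit.kd, "rmax": fit.rmax},
        )


def read_sensorgram_tsv(path, schedule: InjectionSchedule) -> Sensorgram:
    """Delimited text with columns time_s, response_RU (tab- or comma-sep)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    return Sensorgram(
        time=df["time_s"].to_numpy(), response=df["response_RU"].to_numpy(),
        schedule=schedule,
    )


def write_sensorgram_tsv(sg: Sensorgram, path) -> None:
    sg.to_frame().to_csv(path, sep="\t", index=False)
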