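"""Linear compartmental ODE for long-horizon quit-progression.

The second modelling step replaces the stochastic chain by its
deterministic flow on stage prevalences (percent of the cohort). With
nine nonnegative rates d_ij (from stage i to stage j) the transient
subsystem (U, I, M) = (unmotivated, indecisive, motivated) evolves as

    U' = d21 I + d31 M - (d12 + d13 + d14) U
    I' = d12 U + d32 M - (d21 + d23 + d24) I
    M' = d13 U + d23 I - (d31 + d32 + d34) M

and the former-smoker prevalence closes the system by conservation,
F(t) = 100 - (U + I + M). Writing x = (U, I, M), x' = A x with A the
compartmental Jacobian; its eigenvalues have nonpositive real parts,
so the cohort either drains into the absorbing stage (all eigenvalues
negative: the trivial equilibrium (0, 0, 0, 100), globally stable) or,
when A is singular, settles on a ray of equilibria determined by the
null space (the system is then under-determined and full absorption
never happens).

Rates are estimated by bounded least squares (lower bounds zero)
against target prevalence curves — in the two-step workflow, the
weekly curves produced by the fitted Markov chain on [0, 26].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.optimize import least_squares

__all__ = [
    "RATE_NAMES",
    "OdeRates",
    "OdeFit",
    "StabilityReport",
    "jacobian",
    "ode_rhs",
    "propagate",
    "simulate",
    "fit_rates",
    "eigen_stability",
    "asymptotic_state",
    "average_prevalence",
    "time_to_absorption",
]

RATE_NAMES = ("d12", "d13", "d14", "d21", "d23", "d24", "d31", "d32", "d34")

TOTAL = 100.0  # prevalences are percentages of a closed cohort


class OdeError(ValueError):
    pass


@dataclass(frozen=True)
class OdeRates:
    """Nine nonnegative stage-transition rates (per model time unit)."""

    d12: float = 0.0
    d13: float = 0.0
    d14: float = 0.0
    d21: float = 0.0
    d23: float = 0.0
    d24: float = 0.0
    d31: float = 0.0
    d32: float = 0.0
    d34: float = 0.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise OdeError(f"{name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "OdeRates":
        values = np.asarray(values, float)
        if values.shape != (9,):
            raise OdeError("expected nine rates in RATE_NAMES order")
        return cls(**dict(zip(RATE_NAMES, map(float, values))))

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "OdeRates":
        unknown = set(values) - set(RATE_NAMES)
        if unknown:
            raise OdeError(f"unknown rate names: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in values.items()})

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def jacobian(rates: OdeRates) -> np.ndarray:
    """3x3 coefficient matrix A of the (U, I, M) subsystem.

    Diagonal entries are minus the total exit rate of the stage
    (including the flow to the former-smoker stage); entry (i, j) off
    the diagonal is the rate from stage j into stage i. Consequently
    trace(A) = -(sum of all nine rates).
    """
    r = rates
    return np.array(
        [
            [-(r.d12 + r.d13 + r.d14), r.d21, r.d31],
            [r.d12, -(r.d21 + r.d23 + r.d24), r.d32],
            [r.d13, r.d23, -(r.d31 + r.d32 + r.d34)],
        ]
    )


def ode_rhs(state_uim: Sequence[float], rates: OdeRates) -> np.ndarray:
    """Time derivatives (U', I', M'); F' follows by conservation."""
    return jacobian(rates) @ np.asarray(state_uim, float)


def _init_uim(init: Sequence[float]) -> np.ndarray:
    init = np.asarray(init, float)
    if init.shape != (4,):
        raise OdeError("initial state must be (U, I, M, F)")
    if abs(init.sum() - TOTAL) > 1e-6:
        raise OdeError(f"initial state must sum to {TOTAL}, got {init.sum()}")
    return init[:3].copy()


def propagate(
    rates: OdeRates, init: Sequence[float], times: Sequence[float]
) -> np.ndarray:
    """Closed-form trajectory exp(tA) x0 at the given times.

    Returns an array of shape (len(times), 4) with columns U, I, M, F.
    Exact for this linear system up to the matrix-exponential
    evaluation; used both as the fitting forward model and as the
    reference the numerical integrator is validated against.
    """
    A = jacobian(rates)
    x0 = _init_uim(init)
    out = np.empty((len(times), 4))
    for k, t in enumerate(times):
        x = expm(A * float(t)) @ x0
        out[k, :3] = x
        out[k, 3] = TOTAL - x.sum()
    return out


def simulate(
    rates: OdeRates,
    init: Sequence[float],
    horizon: float = 104.0,
    grid: Sequence[float] | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Numerically integrate the system on [0, horizon].

    Uses the implicit BDF method with the analytic Jacobian, so stiff
    rate sets (order 10^3, as large fitted exchange rates produce) are
    handled. Returns a frame with columns time, U, I, M, F; F is the
    conservation remainder.
    """
    x0 = _init_uim(init)
    A = jacobian(rates)
    if grid is None:
        grid = np.linspace(0.0, float(horizon), 209)
    grid = np.asarray(grid, float)
    sol = solve_ivp(
        lambda t, x: A @ x,
        (float(grid[0]), float(grid[-1])),
        x0,
        method="BDF",
        t_eval=grid,
        jac=lambda t, x: A,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise OdeError(
            f"ODE solver failed: {sol.message} "
            f"(stiffness ratio ~{_stiffness_ratio(A):.3g})"
        )
    U, I, M = sol.y
    F = TOTAL - (U + I + M)
    return pd.DataFrame({"time": sol.t, "U": U, "I": I, "M": M, "F": F})


def _stiffness_ratio(A: np.ndarray) -> float:
    ev = np.abs(np.linalg.eigvals(A).real)
    nz = ev[ev > 1e-12]
    return float(nz.max() / nz.min()) if len(nz) > 1 else 1.0


@dataclass
class OdeFit:
    rates: OdeRates
    sse: float
    n_starts: int
    success: bool
    warnings: list[str] = field(default_factory=list)


def _target_arrays(target) -> tuple[np.ndarray, np.ndarray]:
    """Accept a (week, stage1..stage4) frame or (times, values) pair."""
    if isinstance(target, pd.DataFrame):
        tcol = "week" if "week" in target.columns else "time"
        times = np.asarray(target[tcol], float)
        cols = (
            ["stage1", "stage2", "stage3", "stage4"]
            if "stage1" in target.columns
            else ["U", "I", "M", "F"]
        )
        values = np.asarray(target[cols], float)
    else:
        times, values = target
        times = np.asarray(times, float)
        values = np.asarray(values, float)
    if values.shape != (len(times), 4):
        raise OdeError("target must provide four compartments per time point")
    return times, values


def fit_rates(
    target,
    init_state: Sequence[float] | None = None,
    multistarts: int = 20,
    seed: int = 0,
    sse_warn: float = 50.0,
) -> OdeFit:
    """Estimate the nine rates by bounded least squares.

    Minimises the sum over grid points and the four compartments of the
    squared deviation between the closed-form ODE solution and the
    target curves, with all rates bounded below by zero. The
    9-parameter problem is multi-modal, so ``multistarts`` log-uniform
    random initials (seeded, deterministic) are tried and the best kept.

    Parameters
    ----------
    target : DataFrame (week, stage1..4) — typically the weekly curves
        of the fitted Markov chain — or a (times, values) pair.
    init_state : (U, I, M, F) at the first target time; defaults to the
        first target row.
    sse_warn : record a warning when the best SSE exceeds this (a poor
        fit is possible — an under-determined flow can be unable to
        chase the chain's curves).
    """
    times, values = _target_arrays(target)
    if len(times) < 3:
        raise OdeError("need at least 3 target time points")
    if init_state is None:
        init_state = values[0]
    init_state = np.asarray(init_state, float)
    if np.ptp(values, axis=0).max() < 1e-10:
        # constant target: the zero-rate flow reproduces it exactly
        zero = OdeRates()
        sse = float(((propagate(zero, init_state, times) - values) ** 2).sum())
        return OdeFit(rates=zero, sse=sse, n_starts=0, success=True)

    def residual(theta: np.ndarray) -> np.ndarray:
        r = OdeRates.from_array(theta)
        model = propagate(r, init_state, times)
        return (model - values).ravel()

    rng = np.random.default_rng(seed)
    starts = [np.full(9, 0.05)]
    for _ in range(max(multistarts - 1, 0)):
        starts.append(10.0 ** rng.uniform(-3, 1, size=9))

    best = None
    warns: list[str] = []
    for x0 in starts:
        try:
            res = least_squares(
                residual, x0, bounds=(0.0, np.inf), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            warns.append(f"start failed: {exc}")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise OdeError("least-squares fit failed from every start")
    sse = float(2 * best.cost)
    if sse > sse_warn:
        warns.append(f"SSE {sse:.4g} exceeds sanity threshold {sse_warn}")
    return OdeFit(
        rates=OdeRates.from_array(np.clip(best.x, 0.0, None)),
        sse=sse,
        n_starts=len(starts),
        success=bool(best.status > 0),
        warnings=warns,
    )


@dataclass
class StabilityReport:
    """Spectral analysis of the (U, I, M) subsystem."""

    jacobian: np.ndarray
    eigenvalues: np.ndarray  # real parts sorted ascending
    under_determined: bool
    trivial_equilibrium_stable: bool
    equilibrium_family: dict
    asymptotic: np.ndarray | None = None
    convergence_time: float | None = None


def eigen_stability(
    rates: OdeRates,
    init: Sequence[float] | None = None,
    zero_tol: float = 1e-10,
) -> StabilityReport:
    """Eigenvalues, equilibria and stability of the compartment flow.

    The trivial equilibrium (0, 0, 0, 100) is stable iff all
    eigenvalues of A are negative. A zero eigenvalue (|lambda| <=
    zero_tol relative to the spectral scale) makes the system
    under-determined: every point of null(A), intersected with the
    nonnegative simplex and scaled so the components plus F total 100,
    is an equilibrium, and full absorption is lost.
    """
    A = jacobian(rates)
    ev = np.linalg.eigvals(A)
    order = np.argsort(ev.real)
    ev_sorted = ev[order].real
    scale = max(np.abs(ev_sorted).max(), 1.0)
    zero = np.abs(ev_sorted) <= zero_tol * scale
    under = bool(zero.any())

    family: dict = {"type": "trivial", "point": (0.0, 0.0, 0.0, TOTAL)}
    if under:
        # basis of the null space via SVD
        _, s, vt = np.linalg.svd(A)
        null = vt[s <= zero_tol * max(s.max(), 1.0)].T
        family = {
            "type": "family",
            "description": (
                "all nonnegative multiples c*v with components + F = 100"
            ),
            "null_basis": null,
        }

    report = StabilityReport(
        jacobian=A,
        eigenvalues=ev_sorted,
        under_determined=under,
        trivial_equilibrium_stable=not under and bool((ev_sorted < 0).all()),
        equilibrium_family=family,
    )
    if init is not None:
        report.asymptotic = asymptotic_state(rates, init)
        report.convergence_time = time_to_absorption(
            rates, init, mode="equilibrium"
        )
    return report


def asymptotic_state(
    rates: OdeRates, init: Sequence[float], zero_tol: float = 1e-10
) -> np.ndarray:
    """Limiting state (U*, I*, M*, F*) from a given initial condition.

    Spectral projection of the initial (U, I, M) onto the
    zero-eigenvalue subspace of A; modes with negative eigenvalues
    decay, and F* takes the conservation remainder. All eigenvalues
    negative gives (0, 0, 0, 100).
    """
    A = jacobian(rates)
    x0 = _init_uim(init)
    ev, V = np.linalg.eig(A)
    scale = max(np.abs(ev).max(), 1.0)
    c = np.linalg.solve(V, x0.astype(complex))
    keep = np.abs(ev) <= zero_tol * scale
    x_inf = (V[:, keep] @ c[keep]).real if keep.any() else np.zeros(3)
    x_inf = np.clip(x_inf, 0.0, None)
    return np.array([*x_inf, TOTAL - x_inf.sum()])


def average_prevalence(trajectory: pd.DataFrame, T: float) -> pd.Series:
    """Per-compartment time average (1/T) int_0^T x(t) dt.

    Composite trapezoid on the trajectory grid restricted to [0, T]
    (with linear interpolation at T if it falls between grid points).
    The four averages sum to 100 by conservation.
    """
    t = np.asarray(trajectory["time"], float)
    if T <= 0:
        raise OdeError("T must be positive")
    if T > t[-1] + 1e-9:
        raise OdeError(f"T={T} beyond trajectory span [{t[0]}, {t[-1]}]")
    out = {}
    inside = t <= T + 1e-12
    tt = t[inside]
    for col in ("U", "I", "M", "F"):
        y = np.asarray(trajectory[col], float)
        yy = y[inside]
        if tt[-1] < T:  # interpolate the right endpoint
            y_T = np.interp(T, t, y)
            tt_full = np.append(tt, T)
            yy_full = np.append(yy, y_T)
        else:
            tt_full, yy_full = tt, yy
        out[col] = float(np.trapezoid(yy_full, tt_full) / T)
    return pd.Series(out)


def time_to_absorption(
    rates: OdeRates,
    init: Sequence[float],
    epsilon: float = 0.5,
    mode: str = "absorption",
    max_horizon: float = 2.0**22,
) -> float:
    """Time until the transient stages stay within epsilon of their limit.

    mode="absorption" (default): first time max(U, I, M) stays below
    ``epsilon`` percentage points — i.e. (near-)everyone has become a
    former smoker. Returns inf when the limiting state keeps more than
    epsilon outside stage 4 (an under-determined flow).

    mode="equilibrium": first time the max componentwise distance of
    (U, I, M) from its asymptotic value stays below epsilon.
    """
    if epsilon <= 0:
        raise OdeError("epsilon must be positive")
    if mode not in ("absorption", "equilibrium"):
        raise OdeError(f"unknown mode {mode!r}")
    x_star = asymptotic_state(rates, init)[:3]
    target = np.zeros(3) if mode == "absorption" else x_star
    if mode == "absorption" and x_star.max() > epsilon:
        return np.inf

    A = jacobian(rates)
    x0 = _init_uim(init)

    def dist(t: float) -> float:
        x = expm(A * t) @ x0
        return float(np.abs(x - target).max())

    if dist(0.0) <= epsilon:
        return 0.0
    horizon = 52.0
    while dist(horizon) > epsilon:
        horizon *= 2
        if horizon > max_horizon:
            return np.inf
    # locate the last exceedance on a fine grid, then bisect
    grid = np.linspace(0.0, horizon, 4097)
    values = np.array([dist(t) for t in grid])
    above = np.flatnonzero(values > epsilon)
    if len(above) == 0:
        return 0.0
    lo, hi = grid[above[-1]], grid[min(above[-1] + 1, len(grid) - 1)]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if dist(mid) > epsilon:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9 * max(hi, 1.0):
            break
    return float(hi)
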