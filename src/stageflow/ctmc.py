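"""Four-state continuous-time Markov chain for panel-observed stage data.

The chain has transient stages 1-3 (unmotivated, indecisive, motivated)
and an absorbing stage 4 (former smoker). Its generator Q has
nonnegative off-diagonal intensities q_lk (per week), rows summing to
zero, and a zero fourth row. Panel observations at discrete waves are
linked to Q through the interval transition probabilities
P(t) = expm(t Q); for equal-interval complete-case panels the
likelihood depends on the data only through the 4x4 interval
transition-count matrix,

    log L(Q) = sum_{l,k} n_lk log P(Delta)_lk .

Maximum likelihood estimation is carried out over log-intensities
(positivity for free), with analytic gradients via the Frechet
derivative of the matrix exponential, multi-start quasi-Newton
optimisation and an observed-information covariance on the log scale.
Confidence intervals for rates and sojourn times are obtained by
simulating from the asymptotic multivariate normal distribution of the
log-intensity estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, expm_frechet, logm
from scipy.optimize import minimize

from .staging import N_STAGES, PanelDataset, TransitionCountMatrix, snap_interval

__all__ = [
    "IntensityMatrix",
    "CTMCFit",
    "DEFAULT_MASK",
    "transition_probability",
    "panel_log_likelihood",
    "fit_ctmc",
    "sojourn_times",
    "ci_simulated",
    "model_prevalence",
    "absorption_probability",
]

# all nine arrows between transient stages plus exits to the absorbing
# stage; row 4 has no exits
DEFAULT_MASK = np.array(
    [
        [False, True, True, True],
        [True, False, True, True],
        [True, True, False, True],
        [False, False, False, False],
    ]
)

RATE_CAP = 1e4  # per week; keeps the likelihood surface bounded
RATE_FLOOR = 1e-8  # boundary for arrows with no observed evidence

_ROW_TOL = 1e-10


class CTMCError(ValueError):
    pass


@dataclass(frozen=True)
class IntensityMatrix:
    """Validated 4x4 CTMC generator with an allowed-transition mask."""

    matrix: np.ndarray
    mask: np.ndarray = field(default_factory=lambda: DEFAULT_MASK.copy())

    def __post_init__(self) -> None:
        m = np.array(self.matrix, dtype=float)
        mask = np.array(self.mask, dtype=bool)
        if m.shape != (N_STAGES, N_STAGES) or mask.shape != (N_STAGES, N_STAGES):
            raise CTMCError("intensity matrix and mask must be 4x4")
        off = ~np.eye(N_STAGES, dtype=bool)
        if (m[off] < 0).any():
            raise CTMCError("off-diagonal intensities must be nonnegative")
        if (m[~mask & off] != 0).any():
            raise CTMCError("masked-out transitions must have zero intensity")
        if np.abs(m.sum(axis=1)).max() > 1e-8:
            raise CTMCError("each generator row must sum to zero")
        if np.abs(m[N_STAGES - 1]).max() > 0:
            raise CTMCError("stage 4 is absorbing: its row must be zero")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_rates(
        cls,
        rates: Mapping[str, float] | np.ndarray,
        mask: np.ndarray | None = None,
    ) -> "IntensityMatrix":
        """Build Q from off-diagonal rates; diagonal set to -row sum.

        ``rates`` is either a mapping like {"q12": 0.04, ...} or a full
        4x4 array whose diagonal is ignored.
        """
        m = np.zeros((N_STAGES, N_STAGES))
        if isinstance(rates, Mapping):
            for key, value in rates.items():
                if not (len(key) == 3 and key[0] == "q"):
                    raise CTMCError(f"unrecognised rate key {key!r}")
                i, j = int(key[1]) - 1, int(key[2]) - 1
                m[i, j] = float(value)
        else:
            m = np.array(rates, dtype=float)
        np.fill_diagonal(m, 0.0)
        m[N_STAGES - 1, :] = 0.0
        np.fill_diagonal(m, -m.sum(axis=1))
        if mask is None:
            mask = DEFAULT_MASK.copy()
        return cls(matrix=m, mask=mask)

    def rate(self, l: int, k: int) -> float:
        """Intensity q_lk with 1-based stage labels."""
        return float(self.matrix[l - 1, k - 1])


def transition_probability(Q: IntensityMatrix, t: float) -> np.ndarray:
    """Interval transition probabilities P(t) = expm(t Q).

    Rows sum to one; the absorbing row is the stage-4 unit row; P(0) is
    the identity.
    """
    if t < 0:
        raise CTMCError("t must be nonnegative")
    P = expm(t * Q.matrix)
    # clip tiny negative round-off without disturbing row sums materially
    P = np.clip(P, 0.0, None)
    return P


def _as_interval_counts(
    data: PanelDataset | TransitionCountMatrix | Sequence[TransitionCountMatrix],
    group: str | None = None,
) -> list[tuple[float, np.ndarray]]:
    """Reduce input to a list of (interval, 4x4 count) pairs.

    A panel with unequal spacing contributes one count matrix per
    distinct interval length, which is exactly what the product-form
    likelihood needs.
    """
    if isinstance(data, TransitionCountMatrix):
        return [(data.interval, data.counts)]
    if isinstance(data, PanelDataset):
        panel = data if group is None else data.subset(group)
        buckets: dict[float, np.ndarray] = {}
        for seq in panel.subjects.values():
            for (w1, a), (w2, b) in zip(seq, seq[1:]):
                delta = snap_interval(float(w2 - w1), panel.grid)
                c = buckets.setdefault(delta, np.zeros((N_STAGES, N_STAGES), int))
                c[a - 1, b - 1] += 1
        if not buckets:
            raise CTMCError("panel contains no observed transitions")
        return sorted(buckets.items())
    return [(c.interval, c.counts) for c in data]


def panel_log_likelihood(
    Q: IntensityMatrix,
    counts: PanelDataset | TransitionCountMatrix | Sequence[TransitionCountMatrix],
    group: str | None = None,
) -> float:
    """Panel log-likelihood sum_{l,k} n_lk log P(Delta)_lk.

    Accepts a count matrix, a list of count matrices (one per interval
    length), or a PanelDataset (reduced internally). Observed
    transitions with structurally zero probability yield -inf.
    """
    total = 0.0
    for delta, n in _as_interval_counts(counts, group):
        P = transition_probability(Q, delta)
        observed = n > 0
        if (P[observed] <= 0).any():
            return -np.inf
        total += float((n[observed] * np.log(P[observed])).sum())
    return total


def _loglik_and_grad(
    theta: np.ndarray,
    idx: np.ndarray,
    interval_counts: list[tuple[float, np.ndarray]],
) -> tuple[float, np.ndarray]:
    """Log-likelihood and gradient w.r.t. log-intensities.

    theta are log intensities for the free (masked-in) entries indexed
    by idx (array of (row, col)). The gradient uses
    d expm(tQ)/d theta_m = t * L(tQ, q_m E_m) where E_m moves mass from
    the diagonal to the off-diagonal entry and L is the Frechet
    derivative of expm.
    """
    q = np.exp(theta)
    Qm = np.zeros((N_STAGES, N_STAGES))
    for (i, j), v in zip(idx, q):
        Qm[i, j] = v
    np.fill_diagonal(Qm, -Qm.sum(axis=1))

    ll = 0.0
    grad = np.zeros_like(theta)
    for delta, n in interval_counts:
        A = delta * Qm
        P = expm(A)
        observed = n > 0
        Pobs = P[observed]
        if (Pobs <= 0).any():
            return -np.inf, grad * np.nan
        ll += float((n[observed] * np.log(Pobs)).sum())
        # clip denormal probabilities: an optimizer excursion can push
        # an observed cell to ~1e-300, where n/P overflows
        weights = n[observed] / np.maximum(P[observed], 1e-250)
        for m, (i, j) in enumerate(idx):
            E = np.zeros((N_STAGES, N_STAGES))
            E[i, j] = q[m]
            E[i, i] = -q[m]
            _, L = expm_frechet(A, delta * E)
            grad[m] += float((weights * L[observed]).sum())
    return ll, grad


@dataclass
class CTMCFit:
    """Maximum likelihood fit of the panel CTMC.

    log_params are the fitted log-intensities for the free transitions
    listed (1-based) in param_index; cov is the estimated covariance of
    log_params from the inverse observed information.
    """

    Q: IntensityMatrix
    log_params: np.ndarray
    param_index: list[tuple[int, int]]
    cov: np.ndarray
    log_likelihood: float
    converged: bool
    n_starts: int
    at_upper_bound: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.log_likelihood > 1e-9:
            raise CTMCError("panel log-likelihood cannot be positive")


def _moment_init(
    interval_counts: list[tuple[float, np.ndarray]],
    idx: np.ndarray,
) -> np.ndarray:
    """Method-of-moments start: matrix log of the empirical P(Delta).

    The aggregated counts are row-normalised into an empirical interval
    transition matrix and Q0 = logm(P_hat)/Delta is projected onto the
    allowed-transition cone. Falls back to the naive occurrence-rate
    start n_lk / (n_l. * Delta) when the matrix log is unusable.
    """
    delta0 = interval_counts[0][0]
    agg = np.zeros((N_STAGES, N_STAGES))
    for _, n in interval_counts:
        agg += n
    rates = None
    row_tot = agg.sum(axis=1)
    if (row_tot[:-1] > 0).all():
        P_hat = agg / np.where(row_tot[:, None] > 0, row_tot[:, None], 1.0)
        P_hat[N_STAGES - 1] = 0.0
        P_hat[N_STAGES - 1, N_STAGES - 1] = 1.0
        try:
            L = logm(P_hat) / delta0
            if np.abs(L.imag).max() < 1e-8:
                cand = np.array([L.real[i, j] for i, j in idx])
                if (cand > 0).sum() >= len(idx) / 2:
                    rates = np.clip(cand, 1e-4 / delta0, None)
        except Exception:
            rates = None
    if rates is None:
        rates = np.empty(len(idx))
        for m, (i, j) in enumerate(idx):
            row = max(agg[i].sum(), 1.0)
            rates[m] = max(agg[i, j], 0.5) / (row * delta0)
    return np.log(np.clip(rates, RATE_FLOOR * 10, RATE_CAP / 10))


def fit_ctmc(
    data: PanelDataset | TransitionCountMatrix | Sequence[TransitionCountMatrix],
    group: str | None = None,
    mask: np.ndarray | None = None,
    init: IntensityMatrix | None = None,
    seed: int = 0,
    multistarts: int = 5,
    gtol: float = 1e-8,
) -> CTMCFit:
    """Fit the CTMC by maximum likelihood over log-intensities.

    Multi-start L-BFGS-B from a method-of-moments initial (plus seeded
    perturbations) keeps the fit deterministic given ``seed``. Rates
    driven to the upper cap (1e4/week) are flagged; arrows with no
    observed evidence are driven to the 1e-8 floor.

    Parameters
    ----------
    data : panel, count matrix, or list of count matrices.
    mask : boolean 4x4 allowed-transition mask (default: all nine
        arrows of the stage diagram).
    init : optional starting generator overriding the moment initial.
    """
    interval_counts = _as_interval_counts(data, group)
    if sum(int(n.sum() - np.trace(n)) for _, n in interval_counts) == 0:
        raise CTMCError("no off-diagonal transitions observed; nothing to fit")
    mask = DEFAULT_MASK if mask is None else np.asarray(mask, bool)
    idx = np.argwhere(mask)
    n_par = len(idx)

    theta0 = _moment_init(interval_counts, idx)
    if init is not None:
        theta0 = np.array(
            [np.log(max(init.matrix[i, j], RATE_FLOOR)) for i, j in idx]
        )

    rng = np.random.default_rng(seed)
    starts = [theta0] + [
        theta0 + rng.normal(0.0, 0.5, size=n_par) for _ in range(multistarts - 1)
    ]
    bounds = [(np.log(RATE_FLOOR), np.log(RATE_CAP))] * n_par

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = _loglik_and_grad(theta, idx, interval_counts)
        return -ll, -g

    best = None
    for theta_start in starts:
        res = minimize(
            negloglik,
            theta_start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if not np.isfinite(best.fun):
        raise CTMCError("CTMC fit did not converge: non-finite likelihood")

    theta_hat = best.x
    _, grad = _loglik_and_grad(theta_hat, idx, interval_counts)
    # interior gradient check only; bound-active coordinates are exempt
    interior = (theta_hat > np.log(RATE_FLOOR) + 1e-6) & (
        theta_hat < np.log(RATE_CAP) - 1e-6
    )
    converged = bool(best.success) and (
        not interior.any() or np.abs(grad[interior]).max() < 1e-4
    )
    if not converged and not best.success:
        raise CTMCError(f"CTMC fit did not converge: {best.message}")

    hess = _numeric_hessian(theta_hat, idx, interval_counts)
    cov = np.linalg.pinv(hess)

    Qhat = np.zeros((N_STAGES, N_STAGES))
    for (i, j), th in zip(idx, theta_hat):
        Qhat[i, j] = np.exp(th)
    np.fill_diagonal(Qhat, -Qhat.sum(axis=1))
    at_cap = [
        (int(i) + 1, int(j) + 1)
        for (i, j), th in zip(idx, theta_hat)
        if th > np.log(RATE_CAP) - 1e-6
    ]
    if at_cap:
        warnings.warn(f"rates at the {RATE_CAP}/week cap: {at_cap}")

    return CTMCFit(
        Q=IntensityMatrix(matrix=Qhat, mask=mask),
        log_params=theta_hat,
        param_index=[(int(i) + 1, int(j) + 1) for i, j in idx],
        cov=cov,
        log_likelihood=-float(best.fun),
        converged=converged,
        n_starts=len(starts),
        at_upper_bound=at_cap,
    )


def _numeric_hessian(
    theta: np.ndarray,
    idx: np.ndarray,
    interval_counts: list[tuple[float, np.ndarray]],
    h: float = 1e-5,
) -> np.ndarray:
    """Observed information: central differences of the analytic gradient."""
    n = len(theta)
    H = np.zeros((n, n))
    for m in range(n):
        tp, tm = theta.copy(), theta.copy()
        tp[m] += h
        tm[m] -= h
        _, gp = _loglik_and_grad(tp, idx, interval_counts)
        _, gm = _loglik_and_grad(tm, idx, interval_counts)
        H[m] = -(gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def sojourn_times(Q: IntensityMatrix) -> dict[int, float]:
    """Mean one-visit duration -1/q_ll (weeks) per transient stage.

    A stage with no exit (q_ll = 0) is reported as infinity; the
    absorbing stage 4 is always infinity.
    """
    out: dict[int, float] = {}
    for stage in range(1, N_STAGES):
        qll = Q.matrix[stage - 1, stage - 1]
        out[stage] = np.inf if qll == 0 else -1.0 / qll
    out[N_STAGES] = np.inf
    return out


def ci_simulated(
    fit: CTMCFit,
    draws: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Percentile confidence bounds for rates and sojourn times.

    Draws ``draws`` vectors from the asymptotic multivariate normal of
    the log-intensity estimates, transforms each to rates and sojourn
    times, and takes the (1-level)/2 and (1+level)/2 percentiles. A
    covariance that is not positive semi-definite is repaired to the
    nearest PSD matrix (eigenvalue clipping) with a warning.
    """
    cov = np.asarray(fit.cov, float)
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-10:
        warnings.warn("covariance not PSD; clipping negative eigenvalues")
    w = np.clip(w, 0.0, None)
    cov = V @ np.diag(w) @ V.T

    rng = np.random.default_rng(seed)
    thetas = rng.multivariate_normal(fit.log_params, cov, size=draws,
                                     method="eigh")
    rates = np.exp(np.clip(thetas, -700.0, 700.0))  # (draws, n_par)

    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    rate_bounds = {
        lk: (float(np.percentile(rates[:, m], lo_q)),
             float(np.percentile(rates[:, m], hi_q)))
        for m, lk in enumerate(fit.param_index)
    }

    sojourn_bounds: dict[int, tuple[float, float]] = {}
    for stage in range(1, N_STAGES):
        cols = [m for m, (l, _) in enumerate(fit.param_index) if l == stage]
        if not cols:
            continue
        exits = rates[:, cols].sum(axis=1)
        s = np.where(exits > 0, 1.0 / np.where(exits > 0, exits, 1.0), np.inf)
        sojourn_bounds[stage] = (
            float(np.percentile(s, lo_q)),
            float(np.percentile(s, hi_q)),
        )
    return {
        "level": level,
        "draws": draws,
        "rates": rate_bounds,
        "sojourn": sojourn_bounds,
    }


def model_prevalence(
    fit: CTMCFit | IntensityMatrix,
    init: Sequence[float],
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Model-implied stage prevalence curves init . P(t), in percent.

    ``init`` may be fractions summing to 1 or percentages summing to
    100. Default grid: weekly on [0, 26].
    """
    Q = fit.Q if isinstance(fit, CTMCFit) else fit
    init = np.asarray(init, float)
    total = init.sum()
    if not (np.isclose(total, 1.0, atol=1e-6) or np.isclose(total, 100.0, atol=1e-4)):
        raise CTMCError("initial distribution must sum to 1 or 100")
    pi0 = init / total
    if grid is None:
        grid = np.arange(0, 27)
    rows = []
    for t in grid:
        prev = 100.0 * (pi0 @ transition_probability(Q, float(t)))
        rows.append((float(t), *prev))
    return pd.DataFrame(
        rows, columns=["week"] + [f"stage{i}" for i in range(1, N_STAGES + 1)]
    )


def absorption_probability(
    fit: CTMCFit | IntensityMatrix,
    from_stage: int,
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Probability p_l4(t) of having reached the former-smoker stage.

    Nondecreasing in t with p_l4(0) = 0 for transient stages; constant
    1 for from_stage = 4.
    """
    if from_stage not in (1, 2, 3, 4):
        raise CTMCError("from_stage must be in 1..4")
    Q = fit.Q if isinstance(fit, CTMCFit) else fit
    if grid is None:
        grid = np.arange(0, 27)
    values = []
    for t in grid:
        if from_stage == N_STAGES:
            values.append(1.0)
        else:
            P = transition_probability(Q, float(t))
            values.append(float(P[from_stage - 1, N_STAGES - 1]))
    return pd.DataFrame({"week": [float(t) for t in grid], "p_absorb": values})
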