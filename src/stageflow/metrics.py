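"""Temporal efficacy and effectiveness of competing interventions.

Both metrics are computed from per-group stage-prevalence curves on a
common time grid (model-based weekly curves by default; observed
three-wave prevalence works too).

Relative efficacy ignores side effects on motivation:

    sigma_g(t) = F_g(t) / F_max ,

where F_g(t) is the former-smoker prevalence of group g and F_max is
the maximum former-smoker prevalence over all groups (and, in global
mode, over the whole grid) — so the best group touches 1.

Relative effectiveness penalises growth of the unmotivated pool and
loss of the motivated pool, at penalty alpha in (0, 1):

    rho_g(t) = ( dF_g(t) - alpha * (dU_g(t) - dM_g(t)) ) / N_max ,

where d denotes the change since the baseline week and N_max is the
maximum numerator across groups (global mode: also across the grid).
rho can be negative; its ranking need not agree with sigma's — an
intervention can quit the most smokers while demotivating the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["MetricConfig", "MetricSeries", "efficacy", "effectiveness", "compute_metrics"]


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricConfig:
    """Settings for the efficacy/effectiveness computation.

    alpha : penalty in (0, 1) on unfavourable motivation shifts
        (default 0.20).
    baseline_week : reference wave for the changes in the
        effectiveness numerator (default 0).
    normalization : "global" (one scalar N_max across groups and
        times, default) or "per-time" (N_max recomputed at each t).
    """

    alpha: float = 0.20
    baseline_week: float = 0.0
    normalization: str = "global"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise MetricError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.normalization not in ("global", "per-time"):
            raise MetricError(f"unknown normalization {self.normalization!r}")


@dataclass
class MetricSeries:
    """Efficacy and effectiveness curves plus their normalizers."""

    sigma: pd.DataFrame  # columns: week, one column per group
    rho: pd.DataFrame
    f_max: float
    n_max: float | pd.Series  # scalar (global) or per-time series
    components: dict[str, pd.DataFrame] = field(default_factory=dict)
    config: MetricConfig = field(default_factory=MetricConfig)


def _check_aligned(curves: Mapping[str, pd.DataFrame]) -> np.ndarray:
    if not curves:
        raise MetricError("at least one group of prevalence curves required")
    grids = [np.asarray(df["week"], float) for df in curves.values()]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise MetricError("prevalence grids are not aligned across groups")
    return grids[0]


def efficacy(
    curves: Mapping[str, pd.DataFrame],
    config: MetricConfig | None = None,
) -> pd.DataFrame:
    """Relative efficacy sigma_g(t) = F_g(t)/F_max per group.

    F_max is the single scalar max of the former-smoker prevalence over
    all groups and grid times, so max sigma = 1 is attained.
    """
    config = config or MetricConfig()
    weeks = _check_aligned(curves)
    f = {g: np.asarray(df["stage4"], float) for g, df in curves.items()}
    f_max = max(v.max() for v in f.values())
    if f_max <= 0:
        raise MetricError("F_max = 0: no former smokers in any group")
    out = pd.DataFrame({"week": weeks})
    for g, v in f.items():
        out[g] = v / f_max
    return out


def _numerators(
    curves: Mapping[str, pd.DataFrame],
    config: MetricConfig,
) -> tuple[np.ndarray, dict[str, pd.DataFrame]]:
    weeks = _check_aligned(curves)
    base = np.flatnonzero(np.isclose(weeks, config.baseline_week))
    if len(base) == 0:
        raise MetricError(
            f"baseline week {config.baseline_week} not on the grid"
        )
    b = int(base[0])
    comps: dict[str, pd.DataFrame] = {}
    for g, df in curves.items():
        U = np.asarray(df["stage1"], float)
        M = np.asarray(df["stage3"], float)
        F = np.asarray(df["stage4"], float)
        dU, dM, dF = U - U[b], M - M[b], F - F[b]
        num = dF - config.alpha * (dU - dM)
        comps[g] = pd.DataFrame(
            {"week": weeks, "dU": dU, "dM": dM, "dF": dF, "numerator": num}
        )
    return weeks, comps


def effectiveness(
    curves: Mapping[str, pd.DataFrame],
    config: MetricConfig | None = None,
) -> pd.DataFrame:
    """Penalized relative effectiveness rho_g(t) per group."""
    return compute_metrics(curves, config).rho


def compute_metrics(
    curves: Mapping[str, pd.DataFrame],
    config: MetricConfig | None = None,
) -> MetricSeries:
    """Efficacy and effectiveness together, with normalizer report."""
    config = config or MetricConfig()
    sigma = efficacy(curves, config)
    weeks, comps = _numerators(curves, config)

    num_matrix = np.column_stack([comps[g]["numerator"] for g in curves])
    rho = pd.DataFrame({"week": weeks})
    if config.normalization == "global":
        n_max = float(num_matrix.max())
        if n_max <= 0:
            raise MetricError(
                "global N_max <= 0: no group improves on baseline "
                f"(alpha={config.alpha}, baseline={config.baseline_week})"
            )
        for g in curves:
            rho[g] = comps[g]["numerator"] / n_max
        n_max_out: float | pd.Series = n_max
    else:
        per_t = num_matrix.max(axis=1)
        # the baseline week has all-zero numerators by construction:
        # rho is defined as 0 there; a strictly negative max (every
        # group worse than baseline) is a genuinely degenerate config
        if (per_t < 0).any():
            bad = weeks[per_t < 0]
            raise MetricError(
                f"per-time N_max < 0 at weeks {bad[:5].tolist()} "
                f"(alpha={config.alpha}); per-time normalization undefined"
            )
        safe = np.where(per_t > 0, per_t, 1.0)
        for g in curves:
            rho[g] = np.where(per_t > 0, comps[g]["numerator"] / safe, 0.0)
        n_max_out = pd.Series(per_t, index=weeks, name="n_max")

    f_max = max(float(np.asarray(df["stage4"], float).max()) for df in curves.values())
    return MetricSeries(
        sigma=sigma, rho=rho, f_max=f_max, n_max=n_max_out,
        components=comps, config=config,
    )
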