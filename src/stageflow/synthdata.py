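"""Synthetic panels and fixtures with the structure the methods assume.

The generator draws latent continuous-time paths per subject
(exponential holding times + embedded jump chain from a known generator
Q), observes them at the trial's wave grid (weeks 0/13/26 by default,
i.e. two equal 13-week follow-up intervals), and optionally injects
missingness and relapse so the staging exclusions can be exercised.
Because the truth Q is stored alongside, the whole pipeline is testable
end to end: fitting the chain to a sampled panel must recover Q.

``make_reference_fixtures`` packages the small printed inputs of the study
the methods were developed on: the observed stage-count margins per arm
and wave, the three resolved ODE rate sets, and a synthetic three-wave
panel whose marginal counts match the health-education arm exactly
(individual transitions are synthetic: only margins are printed).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctmc import IntensityMatrix
from .odeproj import OdeRates
from .staging import (
    MOTIVATION_BINS,
    PanelDataset,
    StageRecord,
    build_panel,
    censor_relapse,
)

__all__ = [
    "SimulationSpec",
    "sample_path",
    "sample_ctmc_records",
    "sample_ctmc_panel",
    "make_reference_fixtures",
    "study_like_intensities",
    "TABLE1_COUNTS",
    "RESOLVED_ODE_RATES",
]

# observed stage-count margins per arm and wave (columns: stages 1-4).
# The MI week-12/26 rows sum to 88 although the arm size is stated as
# 87 in the source table -- an internal inconsistency of that table,
# preserved verbatim here.
TABLE1_COUNTS: dict[str, dict[int, tuple[int, int, int, int]]] = {
    "BA": {0: (31, 12, 0, 0), 12: (20, 16, 7, 0), 26: (18, 12, 10, 3)},
    "MI": {0: (69, 14, 4, 0), 12: (36, 23, 27, 2), 26: (32, 27, 22, 7)},
    "HE": {0: (67, 24, 0, 0), 12: (30, 22, 33, 6), 26: (23, 31, 21, 16)},
}

# nine-rate ODE sets with transition directions resolved so the
# resulting Jacobians reproduce the published eigenvalue analysis
RESOLVED_ODE_RATES: dict[str, OdeRates] = {
    "HE": OdeRates(d21=1.1698, d32=0.6286, d34=1.1147),
    "MI": OdeRates(
        d12=37.555, d13=21.725, d14=0.0329,
        d21=55.752, d23=13.532, d24=0.0722,
        d31=25.941, d32=19.135, d34=0.4692,
    ),
    "BA": OdeRates(
        d12=2695.0, d13=0.5216, d14=0.00004,
        d21=3657.0, d23=0.9938, d24=0.000006,
        d31=0.0003, d32=0.0003, d34=0.8581,
    ),
}


def _week0_distribution(group: str) -> np.ndarray:
    counts = TABLE1_COUNTS.get(group, {}).get(0)
    if counts is None:
        return np.array([0.75, 0.25, 0.0, 0.0])
    c = np.asarray(counts, float)
    return c / c.sum()


@dataclass(frozen=True)
class SimulationSpec:
    """Fully-seeded description of a synthetic multi-arm panel study."""

    group_sizes: Mapping[str, int]
    intensities: Mapping[str, IntensityMatrix]
    initial_distributions: Mapping[str, Sequence[float]] | None = None
    # equal 13-week follow-up intervals, the design the methods assume
    weeks: tuple[int, ...] = (0, 13, 26)
    missing_fraction: float = 0.0
    relapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.group_sizes) != set(self.intensities):
            raise ValueError("group_sizes and intensities must share keys")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not 0 <= self.relapse_rate <= 1:
            raise ValueError("relapse_rate must be in [0, 1]")

    def initial(self, group: str) -> np.ndarray:
        if self.initial_distributions and group in self.initial_distributions:
            d = np.asarray(self.initial_distributions[group], float)
            return d / d.sum()
        return _week0_distribution(group)


def sample_path(
    Q: IntensityMatrix, start_stage: int, t_end: float, rng: np.random.Generator
) -> list[tuple[float, int]]:
    """One latent trajectory [(jump time, new stage), ...] on [0, t_end].

    Event-driven simulation: in stage l, the holding time is
    Exponential(-q_ll) and the next stage is drawn with probabilities
    q_lk / (-q_ll). The initial state is recorded at time 0.
    """
    t, stage = 0.0, int(start_stage)
    path = [(0.0, stage)]
    while True:
        exit_rate = -Q.matrix[stage - 1, stage - 1]
        if exit_rate <= 0:
            break  # absorbing (or frozen) stage
        t += rng.exponential(1.0 / exit_rate)
        if t >= t_end:
            break
        probs = Q.matrix[stage - 1].copy()
        probs[stage - 1] = 0.0
        probs = np.clip(probs, 0.0, None) / exit_rate
        stage = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
        path.append((t, stage))
    return path


def _stage_at(path: list[tuple[float, int]], t: float) -> int:
    stage = path[0][1]
    for jump_t, s in path:
        if jump_t <= t:
            stage = s
        else:
            break
    return stage


def _items_for_stage(stage: int, rng: np.random.Generator) -> tuple[int | None, bool]:
    """Questionnaire items (motivation, smoked_past7) consistent with a stage."""
    if stage == 4:
        return (None, False)
    lo, hi = MOTIVATION_BINS[stage - 1]
    return (int(rng.integers(lo, hi + 1)), True)


def sample_ctmc_records(spec: SimulationSpec) -> tuple[list[StageRecord], dict]:
    """Draw questionnaire-level records for every arm of the spec.

    Returns the raw StageRecord list (with missingness injected as
    absent waves) and a truth dictionary carrying the generating Q per
    arm and the latent stage at every wave before corruption.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[StageRecord] = []
    latent: dict[str, list[tuple[int, ...]]] = {}
    horizon = float(max(spec.weeks)) + 1.0
    for group in spec.group_sizes:
        Q = spec.intensities[group]
        init = spec.initial(group)
        n = int(spec.group_sizes[group])
        latent[group] = []
        for i in range(n):
            sid = f"{group}-{i:04d}"
            start = int(rng.choice([1, 2, 3, 4], p=init))
            path = sample_path(Q, start, horizon, rng)
            stages = tuple(_stage_at(path, float(w)) for w in spec.weeks)
            latent[group].append(stages)
            # relapse injection: flip a post-absorption wave back to a
            # smoking stage to exercise the censoring step
            stages_obs = list(stages)
            if spec.relapse_rate > 0:
                for k in range(1, len(stages_obs) - 1):
                    if stages_obs[k] == 4 and rng.random() < spec.relapse_rate:
                        stages_obs[k + 1] = int(rng.integers(1, 4))
                        break
            for k, w in enumerate(spec.weeks):
                if (
                    spec.missing_fraction > 0
                    and k > 0
                    and rng.random() < spec.missing_fraction
                ):
                    continue  # wave not observed
                motivation, smoked = _items_for_stage(stages_obs[k], rng)
                records.append(
                    StageRecord(
                        subject_id=sid,
                        group=group,
                        week=int(w),
                        motivation=motivation,
                        smoked_past7=smoked,
                    )
                )
    truth = {
        "intensities": dict(spec.intensities),
        "latent_stages": latent,
        "weeks": spec.weeks,
        "seed": spec.seed,
    }
    return records, truth


def sample_ctmc_panel(
    spec: SimulationSpec, complete_case: bool = True
) -> tuple[PanelDataset, dict]:
    """Sampled panel after staging, exclusion and relapse censoring."""
    records, truth = sample_ctmc_records(spec)
    panel = build_panel(records, grid=spec.weeks, complete_case=complete_case)
    panel = censor_relapse(panel)
    return panel, truth


def _he_margin_panel() -> PanelDataset:
    """Synthetic 91-subject panel matching the HE stage margins exactly.

    Subjects are assigned stages wave by wave in index blocks sized by
    the printed counts, with the absorbing block anchored at the top
    indices so no synthetic relapse appears. Only the margins are
    faithful; the joint transitions are an artefact of the block
    layout.
    """
    margins = TABLE1_COUNTS["HE"]
    weeks = sorted(margins)
    n = sum(margins[weeks[0]])
    # per wave: assign stage 4 to the top indices, stages 3,2,1 below,
    # so the absorbing block only grows
    assignment: dict[int, list[int]] = {}
    for w in weeks:
        c1, c2, c3, c4 = margins[w]
        stages = [1] * c1 + [2] * c2 + [3] * c3 + [4] * c4
        assignment[w] = stages
    subjects: "OrderedDict[str, list[tuple[int, int]]]" = OrderedDict()
    groups: dict[str, str] = {}
    for i in range(n):
        sid = f"HE-{i:03d}"
        subjects[sid] = [(w, assignment[w][i]) for w in weeks]
        groups[sid] = "HE"
    return PanelDataset(
        subjects=subjects, groups=groups, grid=tuple(weeks),
        exclusion_log={"mode": "synthetic-margins"},
    )


def study_like_intensities() -> dict[str, IntensityMatrix]:
    """Synthetic per-arm generators emulating the described arm dynamics.

    Stand-ins for the study's fitted intensity matrices (which were
    published only as supplementary material): weekly rates chosen once
    so the arms show the qualitative patterns reported in words --
    health education (HE) with the strongest quit flow but a
    demotivation cascade motivated -> indecisive -> unmotivated; brief
    advice (BA) with a slow unmotivated <-> indecisive exchange and a
    small quit flow; motivational interviewing (MI) with fast mixing
    between the smoking stages (short sojourn times).
    """
    return {
        "HE": IntensityMatrix.from_rates(
            {"q12": 0.010, "q13": 0.120, "q14": 0.001,
             "q21": 0.120, "q23": 0.010, "q24": 0.004,
             "q31": 0.020, "q32": 0.150, "q34": 0.030}
        ),
        "BA": IntensityMatrix.from_rates(
            {"q12": 0.050, "q13": 0.010, "q14": 0.001,
             "q21": 0.050, "q23": 0.030, "q24": 0.002,
             "q31": 0.005, "q32": 0.010, "q34": 0.008}
        ),
        "MI": IntensityMatrix.from_rates(
            {"q12": 0.250, "q13": 0.100, "q14": 0.001,
             "q21": 0.800, "q23": 0.600, "q24": 0.005,
             "q31": 0.300, "q32": 0.800, "q34": 0.012}
        ),
    }


def make_reference_fixtures() -> dict:
    """Named small fixtures: resolved ODE rates, stage-count margins,
    and the synthetic HE-margin panel."""
    tables = {
        group: pd.DataFrame.from_dict(
            counts, orient="index",
            columns=[f"stage{i}" for i in range(1, 5)],
        ).rename_axis("week")
        for group, counts in TABLE1_COUNTS.items()
    }
    return {
        "ode_rates": dict(RESOLVED_ODE_RATES),
        "table1_counts": tables,
        "he_margin_panel": _he_margin_panel(),
    }
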