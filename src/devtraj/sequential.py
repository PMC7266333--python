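"""Beta-Bernoulli sequential updating of milestone achievement.

Each child's milestone record within a functional domain is treated as an
ordered sequence of Bernoulli trials.  Starting from a Beta(1, 1) prior, the
posterior after each observation is again a Beta distribution: a success adds
one to the first shape parameter, a failure adds one to the second.  The
resulting sequence of posterior means is the child's developmental profile
for that domain, and the 95% highest-posterior-density (HPD) interval of each
Beta posterior quantifies its uncertainty.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BetaState",
    "MilestoneSequence",
    "PosteriorTrace",
    "update_beta",
    "posterior_trace",
    "hpd_interval",
    "read_cohort",
    "traces_to_frame",
    "cohort_traces",
]


@dataclass(frozen=True)
class BetaState:
    """Conjugate Beta pseudo-count pair (successes ``a``, failures ``b``)."""

    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Beta pseudo-counts must be positive, got ({self.a}, {self.b})")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)


@dataclass(frozen=True)
class MilestoneSequence:
    """Ordered binary milestone record for one child within one domain.

    ``observations`` is a sequence of ``(milestone_index, scheduled_month,
    achieved)`` triples with strictly increasing milestone indices and
    non-decreasing months.
    """

    child_id: str
    domain: str
    observations: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        obs = tuple((int(i), int(m), int(y)) for i, m, y in self.observations)
        object.__setattr__(self, "observations", obs)
        idx = [o[0] for o in obs]
        months = [o[1] for o in obs]
        if any(j <= i for i, j in zip(idx, idx[1:])):
            raise ValueError("milestone_index must be strictly increasing")
        if any(m2 < m1 for m1, m2 in zip(months, months[1:])):
            raise ValueError("scheduled_month must be non-decreasing")
        for _, _, y in obs:
            if y not in (0, 1):
                raise ValueError(f"achieved must be 0 or 1, got {y}")

    @property
    def achieved(self) -> np.ndarray:
        return np.array([y for _, _, y in self.observations], dtype=int)

    def has_gaps(self) -> bool:
        idx = [o[0] for o in self.observations]
        return any(j != i + 1 for i, j in zip(idx, idx[1:]))


@dataclass(frozen=True)
class PosteriorTrace:
    """Per-milestone posterior means and 95% HPD bounds for one child/domain.

    ``entries`` holds ``(milestone_index, posterior_mean, hpd_low, hpd_high)``
    where entry *i* summarises the Beta posterior *after* incorporating
    observation *i*.
    """

    child_id: str
    domain: str
    entries: tuple[tuple[int, float, float, float], ...]

    @property
    def means(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries])

    @property
    def milestone_indices(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=int)

    def __len__(self) -> int:
        return len(self.entries)


def update_beta(state: BetaState, y: int) -> BetaState:
    """One conjugate update: a success increments ``a``, a failure ``b``.

    The input state is not modified.
    """
    if y not in (0, 1):
        raise ValueError(f"observation must be 0 or 1, got {y!r}")
    if y == 1:
        return BetaState(state.a + 1, state.b)
    return BetaState(state.a, state.b + 1)


@functools.lru_cache(maxsize=65536)
def _hpd_cached(a: float, b: float, mass: float) -> tuple[float, float]:
    dist = stats.beta(a, b)
    tail = 1.0 - mass
    if a <= 1.0 and b <= 1.0:
        # Flat or bathtub-shaped density: the HPD interval is not unique, so
        # fall back to the central (equal-tailed) interval.
        return float(dist.ppf(tail / 2)), float(dist.ppf(1 - tail / 2))
    if a <= 1.0 < b:
        return 0.0, float(dist.ppf(mass))  # monotone decreasing density
    if b <= 1.0 < a:
        return float(dist.ppf(tail)), 1.0  # monotone increasing density
    # Unimodal interior mode: minimise interval width over the lower tail mass.
    res = optimize.minimize_scalar(
        lambda p: dist.ppf(p + mass) - dist.ppf(p),
        bounds=(0.0, tail),
        method="bounded",
        options={"xatol": 1e-10},
    )
    p = float(res.x)
    return float(dist.ppf(p)), float(dist.ppf(p + mass))


def hpd_interval(a: float, b: float, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` posterior probability of Beta(a, b).

    For monotone densities one endpoint is 0 or 1; for the flat/bathtub case
    (``a <= 1`` and ``b <= 1``) the equal-tailed interval is returned, since
    the HPD region is non-unique there.
    """
    if not (a > 0 and b > 0):
        raise ValueError("shape parameters must be positive")
    if not (0.0 < mass < 1.0):
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    return _hpd_cached(float(a), float(b), float(mass))


def posterior_trace(
    seq: MilestoneSequence,
    prior: BetaState | None = None,
    mass: float = 0.95,
    allow_gaps: bool = False,
) -> PosteriorTrace:
    """Run the sequential updating over one milestone sequence.

    Entry *i* of the result summarises the Beta posterior after observation
    *i* (its mean ``a/(a+b)`` and HPD interval).  Sequences with missing
    milestones mid-stream are rejected unless ``allow_gaps`` is set, in which
    case updating simply continues across the gap.
    """
    if prior is None:
        prior = BetaState(1.0, 1.0)
    if len(seq.observations) == 0:
        raise ValueError("milestone sequence is empty")
    if seq.has_gaps() and not allow_gaps:
        raise ValueError(
            f"child {seq.child_id!r} domain {seq.domain!r} has missing milestones "
            "mid-sequence; pass allow_gaps=True to skip and continue"
        )
    state = prior
    entries = []
    for idx, _, y in seq.observations:
        state = update_beta(state, y)
        low, high = hpd_interval(state.a, state.b, mass)
        entries.append((idx, state.mean, low, high))
    return PosteriorTrace(seq.child_id, seq.domain, tuple(entries))


# ---------------------------------------------------------------------------
# Cohort-level I/O helpers

_COHORT_COLUMNS = ["child_id", "domain", "milestone_index", "month", "achieved"]


def read_cohort(path_or_frame) -> pd.DataFrame:
    """Read a cohort table (CSV path or DataFrame) and validate its columns."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    bad = set(df["achieved"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"achieved must be binary, found values {sorted(bad)}")
    return df


def cohort_sequences(cohort: pd.DataFrame) -> list[MilestoneSequence]:
    """Split a cohort table into per-child, per-domain milestone sequences."""
    cohort = read_cohort(cohort)
    seqs = []
    for (child, domain), grp in cohort.groupby(["child_id", "domain"], sort=True):
        grp = grp.sort_values("milestone_index")
        obs = tuple(
            (int(r.milestone_index), int(r.month), int(r.achieved))
            for r in grp.itertuples()
        )
        seqs.append(MilestoneSequence(str(child), str(domain), obs))
    return seqs


def cohort_traces(
    cohort: pd.DataFrame,
    prior: BetaState | None = None,
    allow_gaps: bool = False,
) -> list[PosteriorTrace]:
    """Sequential updating for every child x domain sequence in a cohort."""
    return [
        posterior_trace(s, prior=prior, allow_gaps=allow_gaps)
        for s in cohort_sequences(cohort)
    ]


def traces_to_frame(traces: Iterable[PosteriorTrace]) -> pd.DataFrame:
    """Flatten traces to a tidy table for CSV output."""
    rows = []
    for t in traces:
        for idx, mean, low, high in t.entries:
            rows.append((t.child_id, t.domain, idx, mean, low, high))
    return pd.DataFrame(
        rows,
        columns=["child_id", "domain", "milestone_index", "post_mean", "hpd_low", "hpd_high"],
    )
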