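"""Rescaled area between a child's posterior-mean step function and the
"gold-standard" reference trajectory.

The reference is the posterior-mean sequence of a hypothetical child who
achieves every milestone starting from Beta(1, 1); its *i*-th mean is
``(i + 1) / (i + 2)``.  Both sequences are step functions over the milestone
index axis with unit spacing, so the rescaled area between them reduces to
the mean absolute difference of posterior means over the observed
milestones.  The area lies in [0, 1]: 0 means the child tracked the
reference exactly, values near 1 indicate pervasive failure to achieve.

The six per-domain areas of each child are logit-transformed (after
clamping away from {0, 1}) into the feature matrix clustered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequential import BetaState, MilestoneSequence, PosteriorTrace, posterior_trace

__all__ = [
    "DOMAINS",
    "DomainArea",
    "reference_trace",
    "area_between",
    "logit_areas",
    "areas_to_frame",
    "cohort_features",
]

#: Fixed feature-column order for the six functional domains.
DOMAINS = ("auditory", "hands", "movement", "speech", "tactile", "vision")


@dataclass(frozen=True)
class DomainArea:
    """Rescaled deviation area for one child within one functional domain."""

    child_id: str
    domain: str
    w: int  # number of observed milestones
    area: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.area <= 1.0):
            raise ValueError(f"area must lie in [0, 1], got {self.area}")


def reference_trace(n: int) -> PosteriorTrace:
    """Gold-standard trace: all ``n`` milestones achieved from Beta(1, 1)."""
    if n < 1:
        raise ValueError(f"reference length must be >= 1, got {n}")
    seq = MilestoneSequence(
        "__reference__", "reference", tuple((i + 1, i + 1, 1) for i in range(n))
    )
    return posterior_trace(seq)


def area_between(child: PosteriorTrace, ref: PosteriorTrace) -> DomainArea:
    """Rescaled area between a child's trace and the reference trace.

    The reference must be at least as long as the child's trace; it is
    truncated to the child's length so that children entering the program
    late are compared against a reference aligned to their own start.  With
    unit-spaced milestone indices and rescaling by the number of observed
    milestones ``w``, the area is the mean absolute difference of the two
    posterior-mean sequences.
    """
    n = len(child)
    if len(ref) < n:
        raise ValueError(
            f"reference trace (length {len(ref)}) is shorter than the child trace ({n})"
        )
    diff = np.abs(ref.means[:n] - child.means)
    return DomainArea(child.child_id, child.domain, w=n, area=float(diff.mean()))


def logit_areas(
    areas: Iterable[DomainArea],
    eps: float = 1e-3,
    domains: Sequence[str] = DOMAINS,
) -> pd.DataFrame:
    """Assemble the logit-transformed feature matrix (children x domains).

    Areas are clamped to ``[eps, 1 - eps]`` before the logit so that exact
    zeros (children matching the reference) stay finite.  Children missing
    any of the requested domains are rejected: the clustering stage requires
    a complete feature vector.
    """
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    rows: dict[str, dict[str, float]] = {}
    for da in areas:
        rows.setdefault(da.child_id, {})[da.domain] = da.area
    records = []
    for child in sorted(rows):
        vals = rows[child]
        missing = [d for d in domains if d not in vals]
        if missing:
            raise ValueError(f"child {child!r} is missing domains {missing}")
        clamped = np.clip([vals[d] for d in domains], eps, 1.0 - eps)
        records.append(np.log(clamped / (1.0 - clamped)))
    return pd.DataFrame(records, index=sorted(rows), columns=list(domains)).rename_axis(
        "child_id"
    )


def areas_to_frame(areas: Iterable[DomainArea], domains: Sequence[str] = DOMAINS) -> pd.DataFrame:
    """Raw (untransformed) areas as a children x domains table."""
    rows: dict[str, dict[str, float]] = {}
    for da in areas:
        rows.setdefault(da.child_id, {})[da.domain] = da.area
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(domains)
    ).sort_index().rename_axis("child_id")


def cohort_features(
    traces: Iterable[PosteriorTrace],
    eps: float = 1e-3,
    domains: Sequence[str] = DOMAINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute (raw areas, logit features) for a collection of traces.

    Each trace is compared to a reference of matching length.
    """
    traces = list(traces)
    max_len = max(len(t) for t in traces)
    ref = reference_trace(max_len)
    areas = [area_between(t, ref) for t in traces]
    return areas_to_frame(areas, domains), logit_areas(areas, eps=eps, domains=domains)
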