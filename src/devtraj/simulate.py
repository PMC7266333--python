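"""Synthetic data generators with ground truth for recovery testing.

Two families are provided:

* **Milestone cohorts** on the Developing Childhood assessment schedule
  (58 milestones per functional domain: three per month over months 1-12,
  two per month over months 13-18, one per month over months 19-25, then
  single milestones at months 28, 31 and 34; 348 milestones over the six
  domains).  Each child draws milestone achievements from a change-point
  Bernoulli profile — achievement probability ``p_before`` up to a
  per-domain onset index, ``p_after`` from the onset on — which is the
  simplest generator able to produce domain-specific deficit archetypes
  (global delay, isolated speech delay, ...) and the strongly right-skewed
  deviation-area distributions seen in real community cohorts.

* **Bivariate Gaussian cluster scenarios** used in the sensitivity analyses
  of the clustering stage: three isotropic clusters at the vertices of an
  equilateral triangle whose side length controls the overlap
  ("separated" = 8, "adjacent" = 6, "overlapping" = 4 at unit scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .areas import DOMAINS

__all__ = [
    "MilestoneSchedule",
    "DelayProfile",
    "ClusterSpec",
    "milestone_schedule",
    "generate_cohort",
    "generate_gaussian_clusters",
    "classification_accuracy",
    "TYPICAL",
    "GLOBAL_DELAY",
    "SPEECH_DELAY",
    "CLUSTER_PRESETS",
]


@dataclass(frozen=True)
class MilestoneSchedule:
    """Deterministic (milestone_index, scheduled_month) schedule per domain."""

    entries: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def months(self) -> np.ndarray:
        return np.array([m for _, m in self.entries], dtype=int)

    @property
    def total_milestones(self) -> int:
        return len(self.entries) * len(DOMAINS)


def milestone_schedule() -> MilestoneSchedule:
    """The 58-milestone-per-domain assessment schedule (348 in total)."""
    months: list[int] = []
    for m in range(1, 13):
        months += [m] * 3
    for m in range(13, 19):
        months += [m] * 2
    for m in range(19, 26):
        months += [m]
    months += [28, 31, 34]
    return MilestoneSchedule(tuple((i + 1, m) for i, m in enumerate(months)))


@dataclass(frozen=True)
class DelayProfile:
    """Change-point Bernoulli achievement profile, one triple per domain.

    ``domains`` maps each domain name to ``(onset_index, p_before, p_after)``;
    an onset of ``None`` means no change point (``p_before`` throughout).
    """

    name: str
    domains: dict[str, tuple[int | None, float, float]]

    def __post_init__(self) -> None:
        for d, (onset, pb, pa) in self.domains.items():
            if not (0.0 <= pa <= pb <= 1.0):
                raise ValueError(
                    f"profile {self.name!r}, domain {d!r}: need 0 <= p_after <= p_before <= 1"
                )
            if onset is not None and not (1 <= onset <= 58):
                raise ValueError(f"onset index must lie in 1..58, got {onset}")

    def probabilities(self, n_milestones: int, domain: str) -> np.ndarray:
        onset, pb, pa = self.domains[domain]
        p = np.full(n_milestones, pb)
        if onset is not None:
            p[onset - 1 :] = pa
        return p


def _uniform_profile(name: str, onset, pb, pa) -> DelayProfile:
    return DelayProfile(name, {d: (onset, pb, pa) for d in DOMAINS})


#: Archetypal profiles: a typically developing child, a child with global
#: delay from early infancy, and a child with an isolated speech deficit.
TYPICAL = _uniform_profile("typical", None, 0.95, 0.95)
GLOBAL_DELAY = _uniform_profile("global_delay", 10, 0.9, 0.25)
SPEECH_DELAY = DelayProfile(
    "speech_delay",
    {d: ((8, 0.9, 0.15) if d == "speech" else (None, 0.95, 0.95)) for d in DOMAINS},
)


def generate_cohort(
    profiles: list[tuple[DelayProfile, int]],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic milestone cohort.

    Each child samples every milestone independently as
    ``Bernoulli(p_before or p_after)`` according to its profile.  Returns
    the tidy cohort table (``child_id, domain, milestone_index, month,
    achieved``) and a ground-truth table (``child_id, profile``).
    """
    rng = np.random.default_rng(seed)
    sched = milestone_schedule()
    n_m = len(sched)
    rows = []
    truth = []
    child_no = 0
    for profile, n_children in profiles:
        if n_children < 1:
            raise ValueError("n_children must be >= 1 for every profile")
        for _ in range(n_children):
            child_no += 1
            cid = f"child_{child_no:04d}"
            truth.append((cid, profile.name))
            for domain in DOMAINS:
                p = profile.probabilities(n_m, domain)
                achieved = (rng.random(n_m) < p).astype(int)
                for (idx, month), y in zip(sched.entries, achieved):
                    rows.append((cid, domain, idx, month, y))
    cohort = pd.DataFrame(
        rows, columns=["child_id", "domain", "milestone_index", "month", "achieved"]
    )
    return cohort, pd.DataFrame(truth, columns=["child_id", "profile"])


# ---------------------------------------------------------------------------
# Gaussian cluster scenarios


@dataclass(frozen=True)
class ClusterSpec:
    """Isotropic Gaussian cluster layout with pairwise-distinct means."""

    means: np.ndarray  # (k, dim)
    n_per_cluster: int = 50
    scale: float = 1.0

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        object.__setattr__(self, "means", means)
        k = len(means)
        for i in range(k):
            for j in range(i + 1, k):
                if np.allclose(means[i], means[j]):
                    raise ValueError("cluster means must be pairwise distinct")
        if self.n_per_cluster < 1:
            raise ValueError("n_per_cluster must be >= 1")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")

    @property
    def k(self) -> int:
        return len(self.means)

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def _equilateral_means(distance: float) -> np.ndarray:
    """Three points at the vertices of an origin-centred equilateral triangle
    with the given side length."""
    r = distance / np.sqrt(3.0)
    ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


#: Three-cluster bivariate presets graded by overlap (pairwise mean distance
#: at unit noise scale).
CLUSTER_PRESETS = {
    "separated": ClusterSpec(_equilateral_means(8.0)),
    "adjacent": ClusterSpec(_equilateral_means(6.0)),
    "overlapping": ClusterSpec(_equilateral_means(4.0)),
}


def generate_gaussian_clusters(
    spec: ClusterSpec | str,
    seed: int = 0,
    n_per_cluster: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_per_cluster`` points per cluster from MVN(mean_j, scale^2 I).

    ``spec`` may be a :class:`ClusterSpec` or one of the preset names
    ``"separated" | "adjacent" | "overlapping"``.  Returns (points, labels).
    """
    if isinstance(spec, str):
        try:
            spec = CLUSTER_PRESETS[spec]
        except KeyError:
            raise ValueError(
                f"unknown preset {spec!r}; choose from {sorted(CLUSTER_PRESETS)}"
            ) from None
    if n_per_cluster is not None:
        spec = ClusterSpec(spec.means, n_per_cluster=n_per_cluster, scale=spec.scale)
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for j, mean in enumerate(spec.means):
        pts.append(mean + spec.scale * rng.standard_normal((spec.n_per_cluster, spec.dim)))
        labels.append(np.full(spec.n_per_cluster, j))
    return np.vstack(pts), np.concatenate(labels)


def classification_accuracy(true_labels, est_labels) -> float:
    """Percentage agreement under the best bijective label matching.

    The optimal one-to-one matching between estimated and true labels is
    found by the Hungarian algorithm on the confusion matrix; estimated
    clusters in excess of the truth stay unmatched and count as errors.
    """
    t = np.asarray(true_labels)
    e = np.asarray(est_labels)
    if t.shape != e.shape:
        raise ValueError(f"label vectors differ in length: {t.shape} vs {e.shape}")
    t_codes, _ = pd.factorize(t)
    e_codes, _ = pd.factorize(e)
    conf = np.zeros((t_codes.max() + 1, e_codes.max() + 1), dtype=int)
    np.add.at(conf, (t_codes, e_codes), 1)
    rows, cols = linear_sum_assignment(conf, maximize=True)
    return 100.0 * conf[rows, cols].sum() / len(t)
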