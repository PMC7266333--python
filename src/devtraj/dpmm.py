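"""Dirichlet process mixture of multivariate normals, fitted by slice sampling.

The mixing distribution follows the stick-breaking construction
``C_1 = V_1``, ``C_k = V_k * prod_{j<k} (1 - V_j)`` with ``V_j ~ Beta(1, alpha)``.
Component parameters carry a conjugate normal-inverse-Wishart base measure

    Sigma_k ~ IW(c0, C0),    mu_k | Sigma_k ~ MVN(b0, Sigma_k / N0),

and the concentration parameter ``alpha`` a Gamma(eta1, eta2) hyperprior,
resampled with the Escobar-West auxiliary-variable scheme.  Sampling uses
Walker's uniform slice variables, which truncate the infinite mixture to a
finite set of candidate components at every iteration, together with the
two Metropolis-Hastings label-switching moves of Papaspiliopoulos & Roberts
to counter the size-biased ordering of the stick weights.

The public surface is the :class:`DirichletProcessMixture` model object
whose :meth:`~DirichletProcessMixture.fit` returns a :class:`DPMMResults`
carrying the chain traces and the consensus post-processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import postprocess as _pp

__all__ = [
    "DPMMPriors",
    "MixtureState",
    "ChainTrace",
    "DirichletProcessMixture",
    "DPMMResults",
    "stick_weights",
    "sample_sticks",
    "stick_posterior_params",
    "niw_posterior",
    "sample_component_params",
    "allocation_probabilities",
    "sample_slice_and_labels",
    "sample_alpha",
    "label_switch_moves",
    "run_chain",
    "save_state",
    "load_state",
]

_CHAIN_SEED_STRIDE = 7919  # fixed offset between per-chain seeds


# ---------------------------------------------------------------------------
# Priors


@dataclass(frozen=True)
class DPMMPriors:
    """Normal-inverse-Wishart base measure and Gamma(eta1, eta2) prior on alpha.

    ``b0`` is the prior component-mean location, ``N0`` the prior precision
    scale (small values let cluster means spread far from ``b0``), ``c0`` the
    inverse-Wishart degrees of freedom (must exceed ``p - 1``) and ``C0`` its
    scale matrix.
    """

    b0: np.ndarray
    N0: float
    c0: float
    C0: np.ndarray
    eta1: float = 1.0
    eta2: float = 1.0

    def __post_init__(self) -> None:
        b0 = np.asarray(self.b0, dtype=float).ravel()
        C0 = np.asarray(self.C0, dtype=float)
        object.__setattr__(self, "b0", b0)
        object.__setattr__(self, "C0", C0)
        p = b0.size
        if C0.shape != (p, p):
            raise ValueError(f"C0 must be {p}x{p}, got {C0.shape}")
        if not np.allclose(C0, C0.T):
            raise ValueError("C0 must be symmetric")
        if np.any(np.linalg.eigvalsh(C0) <= 0):
            raise ValueError("C0 must be positive-definite")
        if self.N0 <= 0:
            raise ValueError("N0 must be positive")
        if self.c0 <= p - 1:
            raise ValueError(f"c0 must exceed p - 1 = {p - 1}, got {self.c0}")
        if self.eta1 <= 0 or self.eta2 <= 0:
            raise ValueError("eta1, eta2 must be positive")

    @property
    def p(self) -> int:
        return self.b0.size

    @classmethod
    def from_data(
        cls,
        y: np.ndarray,
        N0: float = 0.1,
        c0: float | None = None,
        eta1: float = 1.0,
        eta2: float = 1.0,
    ) -> "DPMMPriors":
        """Data-anchored defaults: b0 = column means, C0 = sample covariance,
        c0 = p + 1 inverse-Wishart degrees of freedom."""
        y = np.asarray(y, dtype=float)
        p = y.shape[1]
        return cls(
            b0=y.mean(axis=0),
            N0=N0,
            c0=float(p + 1) if c0 is None else c0,
            C0=regularized_covariance(y),
            eta1=eta1,
            eta2=eta2,
        )


def regularized_covariance(y: np.ndarray) -> np.ndarray:
    """Sample covariance, ridged just enough to be positive-definite when the
    data are (near-)degenerate (e.g. identical feature rows)."""
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.cov(y, rowvar=False, ddof=1))
    C = 0.5 * (C + C.T)
    min_eig = float(np.linalg.eigvalsh(C).min())
    scale = max(float(np.trace(C)) / len(C), 1.0)
    if min_eig < 1e-8 * scale:
        C = C + (1e-8 * scale - min(min_eig, 0.0)) * np.eye(len(C))
    return C


# ---------------------------------------------------------------------------
# Mixture state


@dataclass
class MixtureState:
    """Full sampler state: allocations, sticks, component parameters, alpha."""

    z: np.ndarray  # (n,) int allocations into represented components
    V: np.ndarray  # (K_rep,) stick fractions in (0, 1)
    mus: np.ndarray  # (K_rep, p) component means
    Sigmas: np.ndarray  # (K_rep, p, p) component covariances
    alpha: float
    u: np.ndarray | None = None  # (n,) slice variables

    @property
    def K_rep(self) -> int:
        return len(self.V)

    @property
    def K_occupied(self) -> int:
        return len(np.unique(self.z))

    @property
    def weights(self) -> np.ndarray:
        return stick_weights(self.V)

    def copy(self) -> "MixtureState":
        return MixtureState(
            self.z.copy(),
            self.V.copy(),
            self.mus.copy(),
            self.Sigmas.copy(),
            float(self.alpha),
            None if self.u is None else self.u.copy(),
        )


@dataclass
class ChainTrace:
    """Recorded per-iteration summaries for one MCMC chain."""

    chain_id: int
    K: np.ndarray  # (n_kept,) occupied-component counts
    alpha: np.ndarray  # (n_kept,)
    allocations: np.ndarray  # (n_kept, n) int16
    n_iter: int
    thin: int = 1
    accept_rates: dict = field(default_factory=dict)
    final_state: MixtureState | None = None

    def __len__(self) -> int:
        return len(self.K)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iteration": np.arange(len(self.K)) * self.thin,
                           "K": self.K, "alpha": self.alpha})
        df["chain"] = self.chain_id
        return df


# ---------------------------------------------------------------------------
# Elementary operations


def stick_weights(V: np.ndarray) -> np.ndarray:
    """Stick-breaking weights C_k = V_k * prod_{j<k} (1 - V_j)."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0) or np.any(V > 1):
        raise ValueError("stick fractions must lie in (0, 1]")
    tail = np.concatenate(([1.0], np.cumprod(1.0 - V)[:-1]))
    return V * tail


def stick_posterior_params(z: np.ndarray, alpha: float, K_rep: int) -> tuple[np.ndarray, np.ndarray]:
    """Beta posterior parameters for each stick: (1 + n_k, alpha + sum_{j>k} n_j)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    z = np.asarray(z)
    if z.size and z.max() >= K_rep:
        raise ValueError("K_rep must cover every represented label")
    counts = np.bincount(z, minlength=K_rep).astype(float)
    beyond = counts[::-1].cumsum()[::-1] - counts  # sum of counts for j > k
    return 1.0 + counts, alpha + beyond


def sample_sticks(z: np.ndarray, alpha: float, K_rep: int, rng: np.random.Generator) -> np.ndarray:
    """Draw stick fractions from their Beta full conditionals."""
    a, b = stick_posterior_params(z, alpha, K_rep)
    V = rng.beta(a, b)
    return np.clip(V, 1e-12, 1.0 - 1e-12)


def niw_posterior(
    y_k: np.ndarray, priors: DPMMPriors
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Closed-form normal-inverse-Wishart posterior (b_n, N_n, c_n, C_n).

    With ``n_k`` component members of mean ``ybar`` and scatter ``S``:
    ``N_n = N0 + n_k``, ``b_n = (N0*b0 + n_k*ybar)/N_n``, ``c_n = c0 + n_k``,
    ``C_n = C0 + S + (N0*n_k/N_n) (ybar-b0)(ybar-b0)^T``.  An empty component
    returns the prior unchanged.
    """
    y_k = np.atleast_2d(np.asarray(y_k, dtype=float))
    n_k = 0 if y_k.size == 0 else y_k.shape[0]
    if n_k == 0:
        return priors.b0.copy(), priors.N0, priors.c0, priors.C0.copy()
    ybar = y_k.mean(axis=0)
    dev = y_k - ybar
    S = dev.T @ dev
    N_n = priors.N0 + n_k
    b_n = (priors.N0 * priors.b0 + n_k * ybar) / N_n
    d = ybar - priors.b0
    C_n = priors.C0 + S + (priors.N0 * n_k / N_n) * np.outer(d, d)
    return b_n, N_n, priors.c0 + n_k, C_n


def _sample_invwishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bartlett-decomposition draw from IW(df, scale)."""
    p = scale.shape[0]
    try:
        L = np.linalg.cholesky(scale)
    except np.linalg.LinAlgError:
        warnings.warn("inverse-Wishart scale not Cholesky-decomposable; adding 1e-10 jitter")
        L = np.linalg.cholesky(scale + 1e-10 * np.eye(p))
    A = np.zeros((p, p))
    A[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    A[np.tril_indices(p, -1)] = rng.standard_normal(p * (p - 1) // 2)
    # If W = M M^T with M = L^{-T} A then W ~ Wishart(df, scale^{-1}) and
    # W^{-1} ~ IW(df, scale).
    from scipy.linalg import solve_triangular

    M = solve_triangular(L.T, A, lower=False)
    W = M @ M.T
    Sigma = np.linalg.inv(W)
    return 0.5 * (Sigma + Sigma.T)


def sample_component_params(
    y: np.ndarray,
    z: np.ndarray,
    k: int,
    priors: DPMMPriors,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu_k, Sigma_k) from the conjugate NIW posterior of component k.

    Empty components draw from the prior.
    """
    members = y[np.asarray(z) == k]
    b_n, N_n, c_n, C_n = niw_posterior(members, priors)
    Sigma = _sample_invwishart(c_n, C_n, rng)
    try:
        Lm = np.linalg.cholesky(Sigma / N_n)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"non-positive-definite posterior covariance for component {k}"
        ) from exc
    mu = b_n + Lm @ rng.standard_normal(priors.p)
    return mu, Sigma


def _log_mvn_density(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Log MVN density of every row of y, via a Cholesky solve."""
    p = mu.size
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(Sigma + 1e-10 * np.eye(p))
    from scipy.linalg import solve_triangular

    dev = (y - mu).T  # (p, n)
    sol = solve_triangular(L, dev, lower=True)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (p * np.log(2.0 * np.pi) + logdet + maha)


def _allocation_log_densities(y: np.ndarray, mus: np.ndarray, Sigmas: np.ndarray) -> np.ndarray:
    """(n, K_rep) matrix of log component densities."""
    return np.column_stack(
        [_log_mvn_density(y, mus[k], Sigmas[k]) for k in range(len(mus))]
    )


def allocation_probabilities(
    y: np.ndarray,
    weights: np.ndarray,
    mus: np.ndarray,
    Sigmas: np.ndarray,
    u: np.ndarray,
    likelihood_off: bool = False,
) -> np.ndarray:
    """Full-conditional allocation probabilities given slice variables.

    ``P(z_i = k) \\propto 1{C_k > u_i} * MVN(y_i; mu_k, Sigma_k)`` — the
    weights enter only through the slice indicator.
    """
    if likelihood_off:
        logdens = np.zeros((len(y), len(mus)))
    else:
        logdens = _allocation_log_densities(y, np.asarray(mus), np.asarray(Sigmas))
    allowed = np.asarray(weights)[None, :] > np.asarray(u)[:, None]
    if not allowed.any(axis=1).all():
        raise ValueError("some observation has no component with C_k > u_i")
    logdens = np.where(allowed, logdens, -np.inf)
    logdens -= logdens.max(axis=1, keepdims=True)
    probs = np.exp(logdens)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def sample_slice_and_labels(
    y: np.ndarray,
    state: MixtureState,
    priors: DPMMPriors,
    rng: np.random.Generator,
    likelihood_off: bool = False,
) -> MixtureState:
    """Walker slice step: draw slice variables, extend sticks, reallocate.

    ``u_i ~ Uniform(0, C_{z_i})``; new sticks (with prior-drawn parameters)
    are appended until the unbroken mass falls below ``min_i u_i``, making
    the candidate set finite; each ``z_i`` is then drawn from
    ``P(z_i = k) \\propto 1{C_k > u_i} * MVN(y_i; mu_k, Sigma_k)``.
    """
    C = state.weights
    u = rng.uniform(0.0, C[state.z])
    u_min = u.min()

    V = list(state.V)
    mus = list(state.mus)
    Sigmas = list(state.Sigmas)
    leftover = float(np.prod(1.0 - np.asarray(V)))
    n_ext = 0
    while leftover >= u_min:
        v_new = min(max(rng.beta(1.0, state.alpha), 1e-12), 1 - 1e-12)
        V.append(v_new)
        mu, Sig = sample_component_params(y, np.full(len(y), -1), 0, priors, rng)  # prior draw
        mus.append(mu)
        Sigmas.append(Sig)
        leftover *= 1.0 - v_new
        n_ext += 1

    V = np.asarray(V)
    mus = np.asarray(mus)
    Sigmas = np.asarray(Sigmas)
    C = stick_weights(V)

    probs = allocation_probabilities(y, C, mus, Sigmas, u, likelihood_off=likelihood_off)
    cum = probs.cumsum(axis=1)
    g = rng.random(len(y))
    z = (cum < g[:, None]).sum(axis=1).astype(int)

    new = MixtureState(z=z, V=V, mus=mus, Sigmas=Sigmas, alpha=state.alpha, u=u)
    return _trim_trailing(new)


def _trim_trailing(state: MixtureState) -> MixtureState:
    """Drop represented components beyond the last occupied label; interior
    unoccupied components must be kept because stick positions matter."""
    keep = int(state.z.max()) + 1
    state.V = state.V[:keep]
    state.mus = state.mus[:keep]
    state.Sigmas = state.Sigmas[:keep]
    return state


def sample_alpha(
    alpha: float,
    K_occupied: int,
    n: int,
    eta1: float,
    eta2: float,
    rng: np.random.Generator,
) -> float:
    """Escobar-West auxiliary-variable update for the DP concentration.

    Draws ``eta ~ Beta(alpha + 1, n)`` then alpha from the two-component
    Gamma mixture whose stationary distribution is p(alpha | K, n) under
    the Gamma(eta1, eta2) prior.
    """
    if K_occupied < 1 or n < 1:
        raise ValueError("K_occupied and n must be >= 1")
    if eta1 <= 0 or eta2 <= 0 or alpha <= 0:
        raise ValueError("alpha, eta1, eta2 must be positive")
    eta = rng.beta(alpha + 1.0, n)
    rate = eta2 - np.log(eta)
    odds = (eta1 + K_occupied - 1.0) / (n * rate)
    shape = eta1 + K_occupied if rng.random() < odds / (1.0 + odds) else eta1 + K_occupied - 1.0
    return float(rng.gamma(shape, 1.0 / rate))


def _log_accept_swap_any(C: np.ndarray, n_counts: np.ndarray, k: int, l: int) -> float:
    """Log acceptance ratio for swapping the labels of components k and l
    (parameters and members move; the stick weights stay put)."""
    return (n_counts[k] - n_counts[l]) * (np.log(C[l]) - np.log(C[k]))


def _log_accept_swap_adjacent(V: np.ndarray, n_counts: np.ndarray, k: int) -> float:
    """Log acceptance ratio for swapping adjacent components k and k+1
    together with their stick fractions."""
    return n_counts[k] * np.log1p(-V[k + 1]) - n_counts[k + 1] * np.log1p(-V[k])


def label_switch_moves(
    state: MixtureState, rng: np.random.Generator
) -> tuple[MixtureState, tuple[bool, bool]]:
    """The two Metropolis-Hastings label-switching moves.

    Move 1 proposes exchanging the parameters and members of two randomly
    chosen represented components while keeping the stick weights in place;
    move 2 proposes swapping an adjacent pair wholesale, sticks included.
    Both leave the joint posterior invariant.  Returns the new state and the
    per-move acceptance flags (degenerate states are no-ops).
    """
    accepted = [False, False]
    K = state.K_rep
    if K < 2:
        return state, tuple(accepted)
    n_counts = np.bincount(state.z, minlength=K)

    # Move 1: swap two random components' labels given the current weights.
    k, l = rng.choice(K, size=2, replace=False)
    C = state.weights
    if np.log(rng.random()) < _log_accept_swap_any(C, n_counts, k, l):
        _swap_components(state, k, l, swap_sticks=False)
        n_counts[[k, l]] = n_counts[[l, k]]
        accepted[0] = True

    # Move 2: swap an adjacent pair together with its stick fractions.
    k = int(rng.integers(0, K - 1))
    if np.log(rng.random()) < _log_accept_swap_adjacent(state.V, n_counts, k):
        _swap_components(state, k, k + 1, swap_sticks=True)
        accepted[1] = True

    return _trim_trailing(state), tuple(accepted)


def _swap_components(state: MixtureState, k: int, l: int, swap_sticks: bool) -> None:
    state.mus[[k, l]] = state.mus[[l, k]]
    state.Sigmas[[k, l]] = state.Sigmas[[l, k]]
    if swap_sticks:
        state.V[[k, l]] = state.V[[l, k]]
    zk = state.z == k
    zl = state.z == l
    state.z[zk] = l
    state.z[zl] = k


# ---------------------------------------------------------------------------
# Chain driver


def _init_state(
    y: np.ndarray, priors: DPMMPriors, init_K: int, rng: np.random.Generator, seed: int
) -> MixtureState:
    n = len(y)
    if init_K > n:
        warnings.warn(f"init_K={init_K} exceeds n={n}; reducing to n")
        init_K = n
    if init_K > 1:
        km = KMeans(n_clusters=init_K, n_init=10, random_state=seed % (2**31))
        z = km.fit_predict(y).astype(int)
    else:
        z = np.zeros(n, dtype=int)
    K_rep = int(z.max()) + 1
    alpha = 1.0
    V = sample_sticks(z, alpha, K_rep, rng)
    mus = np.empty((K_rep, priors.p))
    Sigmas = np.empty((K_rep, priors.p, priors.p))
    for k in range(K_rep):
        mus[k], Sigmas[k] = sample_component_params(y, z, k, priors, rng)
    return MixtureState(z=z, V=V, mus=mus, Sigmas=Sigmas, alpha=alpha)


def run_chain(
    y: np.ndarray,
    priors: DPMMPriors,
    n_iter: int,
    init_K: int = 5,
    seed: int = 0,
    thin: int = 1,
    chain_id: int = 0,
    init_state: MixtureState | None = None,
    label_switch: bool = True,
    likelihood_off: bool = False,
) -> ChainTrace:
    """Run one slice-sampler chain and record (K, alpha, allocations).

    Allocations are initialised by K-means with ``init_K`` centres unless an
    explicit ``init_state`` is given (segment-and-resume).  Each iteration
    resamples component parameters, sticks, slice variables and labels, the
    concentration parameter and finally applies the label-switching moves.
    ``K`` is recorded as the number of *occupied* components.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least two observations")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    state = init_state.copy() if init_state is not None else _init_state(y, priors, init_K, rng, seed)

    n_kept = n_iter // thin
    K_trace = np.empty(n_kept, dtype=np.int32)
    a_trace = np.empty(n_kept)
    z_trace = np.empty((n_kept, n), dtype=np.int16)
    acc = np.zeros(2, dtype=int)

    kept = 0
    for it in range(n_iter):
        for k in range(state.K_rep):
            state.mus[k], state.Sigmas[k] = sample_component_params(y, state.z, k, priors, rng)
        state.V = sample_sticks(state.z, state.alpha, state.K_rep, rng)
        state = sample_slice_and_labels(y, state, priors, rng, likelihood_off=likelihood_off)
        state.alpha = sample_alpha(
            state.alpha, state.K_occupied, n, priors.eta1, priors.eta2, rng
        )
        if label_switch:
            state, flags = label_switch_moves(state, rng)
            acc += np.asarray(flags, dtype=int)
        if (it + 1) % thin == 0:
            K_trace[kept] = state.K_occupied
            a_trace[kept] = state.alpha
            z_trace[kept] = state.z
            kept += 1

    return ChainTrace(
        chain_id=chain_id,
        K=K_trace[:kept],
        alpha=a_trace[:kept],
        allocations=z_trace[:kept],
        n_iter=n_iter,
        thin=thin,
        accept_rates={"swap_any": acc[0] / n_iter, "swap_adjacent": acc[1] / n_iter},
        final_state=state,
    )


def save_state(state: MixtureState, path) -> None:
    """Checkpoint a sampler state so long runs can proceed in segments."""
    np.savez(
        path,
        z=state.z,
        V=state.V,
        mus=state.mus,
        Sigmas=state.Sigmas,
        alpha=np.array([state.alpha]),
    )


def load_state(path) -> MixtureState:
    """Load a checkpoint written by :func:`save_state`."""
    with np.load(path) as f:
        return MixtureState(
            z=f["z"].astype(int),
            V=f["V"],
            mus=f["mus"],
            Sigmas=f["Sigmas"],
            alpha=float(f["alpha"][0]),
        )


# ---------------------------------------------------------------------------
# Model / Results objects


class DirichletProcessMixture:
    """DP mixture of multivariate normals over a feature matrix.

    Parameters
    ----------
    data : array-like or DataFrame, shape (n, p)
        One row per observation (for milestone cohorts: one child's six
        logit areas).
    priors : DPMMPriors, optional
        Defaults to the data-anchored specification (``b0`` the column
        means, ``C0`` the sample covariance, ``N0 = 0.1``, ``c0 = p + 1``,
        ``alpha ~ Gamma(1, 1)``).
    """

    def __init__(self, data, priors: DPMMPriors | None = None):
        if isinstance(data, pd.DataFrame):
            self.row_labels = list(data.index)
            self.column_names = list(data.columns)
            self.endog = data.to_numpy(dtype=float)
        else:
            self.endog = np.asarray(data, dtype=float)
            if self.endog.ndim != 2:
                raise ValueError("data must be two-dimensional")
            self.row_labels = list(range(len(self.endog)))
            self.column_names = [f"x{j}" for j in range(self.endog.shape[1])]
        if len(self.endog) < 2:
            raise ValueError("need at least two observations")
        self.priors = priors if priors is not None else DPMMPriors.from_data(self.endog)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns=None, priors=None):
        if columns is not None:
            df = df[list(columns)]
        return cls(df, priors=priors)

    @property
    def nobs(self) -> int:
        return len(self.endog)

    def fit(
        self,
        n_iter: int = 20_000,
        init_K=(5, 10, 15),
        seed: int = 0,
        thin: int = 1,
    ) -> "DPMMResults":
        """Run one chain per entry of ``init_K`` and wrap the traces.

        Chain seeds are derived from ``seed`` by fixed offsets so that runs
        are reproducible bit-for-bit.
        """
        traces = []
        for c, k0 in enumerate(np.atleast_1d(init_K)):
            traces.append(
                run_chain(
                    self.endog,
                    self.priors,
                    n_iter=n_iter,
                    init_K=int(k0),
                    seed=(seed + _CHAIN_SEED_STRIDE * c) % (2**31),
                    thin=thin,
                    chain_id=c,
                )
            )
        return DPMMResults(self, traces)


class DPMMResults:
    """Fitted-sampler results: chain traces, convergence diagnostics and the
    posterior-similarity consensus clustering."""

    def __init__(self, model: DirichletProcessMixture, traces: list[ChainTrace]):
        self.model = model
        self.traces = traces
        self._psm_cache: dict[float, np.ndarray] = {}

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def gelman_rubin(self) -> dict[str, float]:
        """Potential scale reduction factors for K and alpha across chains."""
        return {
            "K": _pp.gelman_rubin([t.K for t in self.traces]),
            "alpha": _pp.gelman_rubin([t.alpha for t in self.traces]),
        }

    def posterior_similarity(self, burn_in: float = 0.5) -> np.ndarray:
        """Pairwise co-clustering proportions pooled across chains."""
        if burn_in not in self._psm_cache:
            self._psm_cache[burn_in] = _pp.psm(self.traces, burn_in_fraction=burn_in)
        return self._psm_cache[burn_in]

    def consensus(
        self, k_min: int = 2, k_max: int = 20, burn_in: float = 0.5
    ) -> _pp.ClusteringResult:
        """PAM consensus partition of 1 - PSM, k selected by silhouette."""
        S = self.posterior_similarity(burn_in)
        return _pp.select_clustering(S, k_min=k_min, k_max=min(k_max, self.nobs - 1))

    def k_posterior(self, burn_in: float = 0.5) -> pd.Series:
        """Pooled post-burn-in posterior distribution of the occupied-cluster
        count K."""
        ks = np.concatenate(
            [t.K[int(burn_in * len(t)):] for t in self.traces]
        )
        return pd.Series(ks).value_counts(normalize=True).sort_index()

    def summary(self, burn_in: float = 0.5) -> str:
        gr = self.gelman_rubin() if len(self.traces) >= 2 else None
        kp = self.k_posterior(burn_in)
        lines = [
            "Dirichlet process mixture (slice sampler)",
            "=" * 57,
            f"Observations: {self.nobs}    Dimensions: {self.model.priors.p}",
            f"Chains: {len(self.traces)}    Iterations/chain: {self.traces[0].n_iter}"
            f"    Burn-in: {burn_in:.0%}",
            f"Priors: N0={self.model.priors.N0}, c0={self.model.priors.c0}, "
            f"alpha ~ Gamma({self.model.priors.eta1}, {self.model.priors.eta2})",
            (
                f"Gelman-Rubin: K = {gr['K']:.3f}, alpha = {gr['alpha']:.3f}"
                f"  ({'converged' if max(gr.values()) < 1.1 else 'NOT converged'} at 1.1)"
                if gr is not None
                else "Gelman-Rubin: not available (single chain)"
            ),
            "Posterior of K (pooled, post burn-in):",
        ]
        for k, p in kp.items():
            lines.append(f"    K = {k:<3d} {p:8.3f}")
        res = self.consensus(burn_in=burn_in)
        lines.append(
            f"Consensus clustering: k = {res.k}, average silhouette = {res.silhouette:.3f}"
        )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_trace(self, ax=None):
        """Trace plots of K and alpha per chain."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
        for t in self.traces:
            ax[0].plot(t.K, lw=0.5, label=f"chain {t.chain_id}")
            ax[1].plot(t.alpha, lw=0.5)
        ax[0].set_ylabel("K (occupied)")
        ax[1].set_ylabel("alpha")
        ax[1].set_xlabel("kept iteration")
        ax[0].legend(fontsize=8)
        return ax

    def plot_similarity(self, burn_in: float = 0.5, ax=None):
        """Heatmap of the posterior similarity matrix, ordered by consensus
        cluster."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        S = self.posterior_similarity(burn_in)
        order = np.argsort(self.consensus(burn_in=burn_in).assignment, kind="stable")
        im = ax.imshow(S[np.ix_(order, order)], vmin=0, vmax=1, cmap="viridis")
        ax.figure.colorbar(im, ax=ax, label="P(same cluster)")
        ax.set_xlabel("observation (cluster-ordered)")
        return ax
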