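"""Microstate discretization and reversible Markov state model estimation.

The estimation chain is the standard one for equilibrium MD data:

1. k-means discretization of the TICA-projected trajectories into
   microstates (centers are kept so later rounds of adaptive sampling can be
   assigned without re-clustering);
2. sliding-window transition counts at a lag time tau, restricted to the
   largest connected set of the symmetrized count graph;
3. maximum-likelihood estimation of a reversible transition matrix P(tau)
   under the detailed-balance constraint, by the self-consistent fixed-point
   iteration on symmetric edge weights x_ij (pi_i P_ij = pi_j P_ji holds by
   construction, pi_i = x_i / sum x);
4. Bayesian uncertainty quantification by Markov-chain Monte Carlo over
   reversible transition matrices posterior to the counts (a Metropolis
   random walk on the log edge weights), giving confidence intervals for any
   scalar functional (stationary probabilities, MFPTs, implied timescales);
5. validation by implied-timescale convergence and the Chapman-Kolmogorov
   test P(k*tau) = P(tau)^k, with bands from bootstrapping whole
   trajectories;
6. model selection over the microstate count by a cross-validated
   variational score (sum of squared estimated eigenvalues of the leading
   processes on held-out trajectories).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
from sklearn.cluster import KMeans

from .exceptions import NotConvergedError, UnreachableStateError, ValidationError

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

from .types import DiscreteTrajectory

__all__ = [
    "CountModel", "TransitionModel", "BayesianEnsemble",
    "kmeans_discretize", "assign_to_centers", "count_matrix",
    "estimate_reversible_mle", "bayesian_sample", "implied_timescales",
    "mfpt", "mfpt_from_matrix", "ck_test", "variational_cv_score",
    "ITSResult", "CKResult",
]


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def kmeans_discretize(projected: list[np.ndarray], k: int, seed: int,
                      dt: float = 1.0, condition: str = "",
                      trajectory_ids: list[str] | None = None
                      ) -> tuple[list[DiscreteTrajectory], np.ndarray]:
    """k-means discretization of pooled projected frames into k microstates.

    k-means++ initialization with a fixed seed; frames are assigned to the
    nearest center (ties resolved to the lowest center index). The centers
    are returned so that frames from later sampling rounds can be assigned
    consistently.
    """
    arrays = [np.atleast_2d(np.asarray(p, dtype=float)) for p in projected]
    pooled = np.concatenate(arrays, axis=0)
    if len(pooled) < k:
        raise ValidationError(f"cannot form {k} microstates from {len(pooled)} frames")
    n_distinct = len(np.unique(pooled, axis=0))
    if n_distinct < k:
        raise ValidationError(
            f"cannot form {k} microstates from {n_distinct} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                random_state=int(seed) % (2 ** 31)).fit(pooled)
    centers = km.cluster_centers_
    dtrajs, offset = [], 0
    for i, arr in enumerate(arrays):
        tid = trajectory_ids[i] if trajectory_ids else f"traj{i:03d}"
        dtrajs.append(DiscreteTrajectory(states=km.labels_[offset:offset + len(arr)],
                                         n_microstates=k, dt=dt,
                                         trajectory_id=tid, condition=condition))
        offset += len(arr)
    return dtrajs, centers


def assign_to_centers(projected: list[np.ndarray], centers: np.ndarray,
                      dt: float = 1.0, condition: str = "",
                      trajectory_ids: list[str] | None = None
                      ) -> list[DiscreteTrajectory]:
    """Assign new frames to existing k-means centers (nearest, lowest-index tie)."""
    k = len(centers)
    out = []
    for i, arr in enumerate(projected):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        d2 = ((arr[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        tid = trajectory_ids[i] if trajectory_ids else f"traj{i:03d}"
        out.append(DiscreteTrajectory(states=np.argmin(d2, axis=1),
                                      n_microstates=k, dt=dt,
                                      trajectory_id=tid, condition=condition))
    return out


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class CountModel:
    lag: int  # frames
    counts: np.ndarray  # full (n_microstates, n_microstates)
    active_set: np.ndarray  # global microstate indices, sorted
    dt: float = 1.0  # ns per frame
    n_frames_outside: int = 0

    @property
    def lag_time(self) -> float:
        """Lag in ns."""
        return self.lag * self.dt

    @property
    def active_counts(self) -> np.ndarray:
        return self.counts[np.ix_(self.active_set, self.active_set)]


def count_matrix(dtrajs: list[DiscreteTrajectory], lag: int) -> CountModel:
    """Sliding-window transition counts at the given lag (frames).

    Counts never cross trajectory boundaries. The active set is the largest
    connected component of the symmetrized count graph; frames outside it
    are reported via ``n_frames_outside``, never silently dropped.
    """
    if lag < 1:
        raise ValidationError("lag must be >= 1 frame")
    n = dtrajs[0].n_microstates
    C = np.zeros(n * n)
    hist = np.zeros(n, dtype=np.int64)
    any_usable = False
    for d in dtrajs:
        s = d.states
        hist += np.bincount(s, minlength=n)
        if len(s) > lag:
            any_usable = True
            C += np.bincount(s[:-lag] * n + s[lag:], minlength=n * n)
    C = C.reshape(n, n)
    if not any_usable:
        raise ValidationError(f"all trajectories are shorter than lag {lag}")
    adj = (C + C.T) > 0
    visited = np.flatnonzero(adj.any(axis=1))
    # largest connected component of the undirected count graph (BFS)
    labels = -np.ones(n, dtype=np.int64)
    comp = 0
    for start in visited:
        if labels[start] >= 0:
            continue
        frontier = np.zeros(n, dtype=bool)
        frontier[start] = True
        member = frontier.copy()
        while frontier.any():
            frontier = adj[frontier].any(axis=0) & ~member
            member |= frontier
        labels[member] = comp
        comp += 1
    sizes = np.bincount(labels[visited], minlength=max(comp, 1))
    active = np.flatnonzero(labels == np.argmax(sizes))
    mask = np.zeros(n, dtype=bool)
    mask[active] = True
    outside = int(hist[~mask].sum())
    return CountModel(lag=lag, counts=C, active_set=np.sort(active),
                      dt=dtrajs[0].dt, n_frames_outside=outside)


# ---------------------------------------------------------------------------
# reversible maximum-likelihood estimation
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Reversible row-stochastic transition matrix with stationary law."""

    transition_matrix: np.ndarray  # on the active set
    stationary: np.ndarray
    lag: int  # frames
    dt: float = 1.0  # ns per frame
    active_set: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        P, pi = self.transition_matrix, self.stationary
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-10:
            raise ValidationError("transition-matrix rows must sum to 1 within 1e-10")
        flux = pi[:, None] * P
        if np.max(np.abs(flux - flux.T)) > 1e-10:
            raise ValidationError("detailed balance violated beyond 1e-10")
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValidationError("stationary distribution must sum to 1")
        if len(self.active_set) == 0:
            self.active_set = np.arange(P.shape[0])

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_time(self) -> float:
        """Lag in ns (one application of P advances time by this much)."""
        return self.lag * self.dt

    def _symmetrized_eig(self) -> tuple[np.ndarray, np.ndarray]:
        sqrt_pi = np.sqrt(self.stationary)
        A = (sqrt_pi[:, None] * self.transition_matrix) / sqrt_pi[None, :]
        lam, phi = scipy.linalg.eigh((A + A.T) / 2)
        order = np.argsort(lam)[::-1]
        return lam[order], phi[:, order]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues, descending; the first is 1."""
        return self._symmetrized_eig()[0]

    def right_eigenvectors(self, n: int) -> np.ndarray:
        """Leading n right eigenvectors (columns), pi-orthonormal, first constant."""
        lam, phi = self._symmetrized_eig()
        psi = phi[:, :n] / np.sqrt(self.stationary)[:, None]
        return psi / np.sign(psi[np.argmax(np.abs(psi[:, 0])), 0])

    @property
    def timescales(self) -> np.ndarray:
        """Implied timescales -tau/ln|lambda_i| (ns) of the non-stationary processes."""
        lam = np.abs(self.eigenvalues[1:])
        with np.errstate(divide="ignore"):
            return np.where(lam >= 1.0, np.inf, -self.lag_time / np.log(lam))


def _reversible_x(C: np.ndarray, tol: float = 1e-12, max_iter: int = 10 ** 6
                  ) -> np.ndarray:
    """Fixed-point iteration for the reversible MLE edge weights x (symmetric).

    Stopping rule: relative log-likelihood change below ``tol`` (plus a small
    edge-weight-change floor so flat likelihoods are resolved to full
    precision), or the ``max_iter`` sweep cap. Near-decomposable chains make
    the flat direction of the likelihood converge only linearly at the rate
    of the slowest process, so the cap can be reached with the iterate still
    crawling; every iterate satisfies detailed balance exactly (P derives
    from symmetric weights), so the capped iterate is returned with a
    warning rather than discarded. A non-finite likelihood is an error.
    """
    x, ll, ll_old, n_it = _reversible_x_kernel(np.ascontiguousarray(C, dtype=np.float64),
                                               float(tol), int(max_iter), 1e-13)
    if not np.isfinite(ll):
        raise NotConvergedError(
            f"reversible MLE diverged (log-likelihood {ll}) after {n_it} iterations",
            n_iterations=int(n_it), last_change=float(ll - ll_old))
    if n_it >= max_iter:
        warnings.warn(
            f"reversible MLE stopped at the {max_iter}-sweep cap before "
            f"reaching tolerance; returning the current (reversible) iterate",
            stacklevel=3)
    return x


@njit(cache=True)
def _reversible_x_kernel(C, tol, max_iter, x_tol):  # pragma: no cover - numba
    # The x_tol polish applies only during the first sweeps: it resolves the
    # flat likelihood of small well-conditioned problems to full precision,
    # while near-decomposable chains (whose flat direction converges at the
    # rate of the slowest process) fall back to the likelihood criterion.
    n = C.shape[0]
    c_row = C.sum(axis=1)
    S = C + C.T
    total = S.sum()
    if total <= 0:
        total = 1.0
    x = S / total
    ll_old = -1e300
    ll = ll_old
    stalled = 0
    for it in range(max_iter):
        xr = x.sum(axis=1)
        q = np.zeros(n)
        for i in range(n):
            if xr[i] > 0:
                q[i] = c_row[i] / xr[i]
        x_new = np.zeros((n, n))
        s_tot = 0.0
        for i in range(n):
            for j in range(n):
                if S[i, j] > 0:
                    d = q[i] + q[j]
                    if d > 0:
                        x_new[i, j] = S[i, j] / d
                        s_tot += x_new[i, j]
        dx = 0.0
        for i in range(n):
            for j in range(n):
                d = abs(x_new[i, j] / s_tot - x[i, j])
                if d > dx:
                    dx = d
        x = x_new / s_tot
        xr = x.sum(axis=1)
        ll = 0.0
        for i in range(n):
            for j in range(n):
                if C[i, j] > 0 and x[i, j] > 0:
                    ll += C[i, j] * (np.log(x[i, j]) - np.log(xr[i]))
        denom = abs(ll) if abs(ll) > 1.0 else 1.0
        # a persistent exact tie catches machine-precision limit cycles
        stalled = stalled + 1 if ll == ll_old else 0
        if abs(ll - ll_old) <= tol * denom and (
                dx <= x_tol or it >= 10_000 or stalled >= 1000):
            return x, ll, ll_old, it
        ll_old = ll
    return x, ll, ll_old, max_iter


def estimate_reversible_mle(counts: CountModel, tol: float = 1e-12) -> TransitionModel:
    """Maximum-likelihood reversible transition matrix on the active set."""
    if len(counts.active_set) == 0:
        raise ValidationError("empty active set")
    C = counts.active_counts
    if C.shape[0] == 1:
        return TransitionModel(transition_matrix=np.ones((1, 1)),
                               stationary=np.ones(1), lag=counts.lag,
                               dt=counts.dt, active_set=counts.active_set)
    x = _reversible_x(C, tol=tol)
    xr = x.sum(axis=1)
    P = x / xr[:, None]
    P[np.arange(len(P)), np.arange(len(P))] += 1.0 - P.sum(axis=1)  # exact rows
    pi = xr / xr.sum()
    return TransitionModel(transition_matrix=P, stationary=pi, lag=counts.lag,
                           dt=counts.dt, active_set=counts.active_set)


# ---------------------------------------------------------------------------
# Bayesian sampling of reversible transition matrices
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mh_edge_sweeps(edges_i, edges_j, s_edge, sigma_edge, c_row, x,
                    n_burn, n_samples, thin, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = c_row.shape[0]
    n_edges = edges_i.shape[0]
    samples = np.empty((n_samples, n, n))
    stored = 0
    total = n_burn + n_samples * thin
    for sweep in range(total):
        xr = x.sum(axis=1)
        for e in range(n_edges):
            i = edges_i[e]
            j = edges_j[e]
            old = x[i, j]
            new = old * np.exp(sigma_edge[e] * np.random.normal())
            d = new - old
            dll = (s_edge[e] + 1.0) * (np.log(new) - np.log(old))
            dll -= c_row[i] * (np.log(xr[i] + d) - np.log(xr[i]))
            if i != j:
                dll -= c_row[j] * (np.log(xr[j] + d) - np.log(xr[j]))
            if np.log(np.random.random()) < dll:
                x[i, j] = new
                xr[i] += d
                if i != j:
                    x[j, i] = new
                    xr[j] += d
        if sweep >= n_burn and (sweep - n_burn + 1) % thin == 0:
            samples[stored] = x / x.sum()
            stored += 1
    return samples


@dataclass
class BayesianEnsemble:
    """Posterior samples of reversible transition matrices given the counts."""

    samples_P: np.ndarray  # (n_samples, k, k)
    samples_pi: np.ndarray  # (n_samples, k)
    reference: TransitionModel  # maximum-likelihood model
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.samples_P.shape[0]

    @property
    def active_set(self) -> np.ndarray:
        return self.reference.active_set

    def sample_models(self):
        for P, pi in zip(self.samples_P, self.samples_pi):
            yield P, pi

    def summarize(self, fn, level: float = 0.6827) -> dict:
        """Mean/SD and central interval of a scalar functional fn(P, pi).

        ``level=0.6827`` gives the 1-sigma band; 0.95 the 95% interval.
        """
        vals = np.array([fn(P, pi) for P, pi in self.sample_models()], dtype=float)
        lo, hi = np.quantile(vals, [(1 - level) / 2, (1 + level) / 2])
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                "lower": float(lo), "upper": float(hi)}


def bayesian_sample(counts: CountModel, n: int = 500, seed: int = 0,
                    burn_in: int | None = None, thin: int = 1,
                    step_scale: float = 2.4) -> BayesianEnsemble:
    """MCMC over reversible transition matrices posterior to the counts.

    A Metropolis random walk on the logarithms of the symmetric edge weights
    x_ij (only edges observed in either direction are sampled); one sweep
    updates every edge once, with per-edge step sizes shrinking with the edge
    count so that acceptance stays useful for well- and poorly-sampled edges
    alike. Burn-in defaults to 10 * n_states sweeps; samples are taken
    ``thin`` sweeps apart. P and pi of each sample derive from its weights.
    """
    if n < 2:
        raise ValidationError("need at least 2 posterior samples")
    mle = estimate_reversible_mle(counts)
    C = counts.active_counts
    k = C.shape[0]
    if k == 1:
        samples_P = np.ones((n, 1, 1))
        return BayesianEnsemble(samples_P=samples_P, samples_pi=np.ones((n, 1)),
                                reference=mle, seed=seed)
    if burn_in is None:
        burn_in = 10 * k
    S = C + C.T
    ii, jj = np.nonzero(np.triu(S) > 0)
    s_edge = np.where(ii == jj, np.diag(C)[ii], S[ii, jj])
    sigma_edge = np.minimum(1.0, step_scale / np.sqrt(1.0 + s_edge))
    x0 = _reversible_x(C, tol=1e-10)
    x0 = np.where(S > 0, np.maximum(x0, 1e-300), 0.0)
    xw = _mh_edge_sweeps(ii.astype(np.int64), jj.astype(np.int64),
                         s_edge.astype(np.float64), sigma_edge.astype(np.float64),
                         C.sum(axis=1).astype(np.float64), x0.copy(),
                         int(burn_in), int(n), max(1, int(thin)),
                         int(seed) % (2 ** 31))
    xr = xw.sum(axis=2)
    samples_P = xw / xr[:, :, None]
    samples_pi = xr / xr.sum(axis=1)[:, None]
    return BayesianEnsemble(samples_P=samples_P, samples_pi=samples_pi,
                            reference=mle, seed=seed)


# ---------------------------------------------------------------------------
# implied timescales
# ---------------------------------------------------------------------------

@dataclass
class ITSResult:
    lags: np.ndarray  # frames
    dt: float
    timescales: np.ndarray  # (n_lags, n_its), ns; ML estimates
    lower: np.ndarray | None = None  # 95% band from Bayesian sampling
    upper: np.ndarray | None = None


def implied_timescales(dtrajs: list[DiscreteTrajectory], lags,
                       n_timescales: int = 2, n_samples: int = 0,
                       seed: int = 0) -> ITSResult:
    """Implied timescales t_i(tau) = -tau*dt/ln|lambda_{i+1}(tau)| per lag.

    With ``n_samples`` > 0, 95% confidence bands are computed from a
    Bayesian transition-matrix ensemble at each lag.
    """
    lags = np.asarray(lags, dtype=int)
    its = np.full((len(lags), n_timescales), np.nan)
    lo = np.full_like(its, np.nan)
    hi = np.full_like(its, np.nan)
    for a, lag in enumerate(lags):
        cm = count_matrix(dtrajs, int(lag))
        model = estimate_reversible_mle(cm)
        if model.n_states <= n_timescales:
            raise ValidationError(
                f"requested {n_timescales} timescales but the active set at "
                f"lag {lag} has only {model.n_states} states")
        its[a] = model.timescales[:n_timescales]
        if n_samples > 0:
            ens = bayesian_sample(cm, n=n_samples, seed=seed + a)
            ts = []
            for P, pi in ens.sample_models():
                m = TransitionModel(transition_matrix=P, stationary=pi,
                                    lag=int(lag), dt=cm.dt,
                                    active_set=cm.active_set)
                ts.append(m.timescales[:n_timescales])
            ts = np.array(ts)
            lo[a] = np.nanquantile(ts, 0.025, axis=0)
            hi[a] = np.nanquantile(ts, 0.975, axis=0)
    return ITSResult(lags=lags, dt=dtrajs[0].dt, timescales=its,
                     lower=lo if n_samples else None,
                     upper=hi if n_samples else None)


# ---------------------------------------------------------------------------
# mean first passage times
# ---------------------------------------------------------------------------

def mfpt_from_matrix(P: np.ndarray, source, target, dt: float = 1.0,
                     stationary: np.ndarray | None = None) -> float:
    """MFPT (in units of dt) from a source set to a target set of P.

    Solves the absorbing-chain linear system for the expected hitting time of
    the target and averages over the source states weighted by the stationary
    distribution restricted to the source.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    source = np.atleast_1d(np.asarray(source, dtype=int))
    target = np.atleast_1d(np.asarray(target, dtype=int))
    if np.intersect1d(source, target).size:
        raise ValidationError("source and target sets must be disjoint")
    if source.min() < 0 or source.max() >= n or target.min() < 0 or target.max() >= n:
        raise ValidationError("state index outside the transition matrix")
    # reachability: every source state must reach the target in the count graph
    graph = scipy.sparse.csr_matrix(P > 0)
    dist = scipy.sparse.csgraph.shortest_path(graph, method="D", unweighted=True,
                                              indices=source)
    if not np.all(np.isfinite(dist[:, target]).any(axis=1)):
        raise UnreachableStateError(
            f"target set {target.tolist()} unreachable from source {source.tolist()}")
    others = np.setdiff1d(np.arange(n), target)
    A = np.eye(len(others)) - P[np.ix_(others, others)]
    h = np.zeros(n)
    h[others] = np.linalg.solve(A, np.ones(len(others)))
    if stationary is None:
        stationary = _stationary_of(P)
    w = stationary[source]
    w = w / w.sum()
    return float((w * h[source]).sum() * dt)


def _stationary_of(P: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eig(P.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def mfpt(model: TransitionModel, source, target) -> float:
    """MFPT (ns) between microstate sets of a transition model; the inverse
    is reported as the transition rate."""
    return mfpt_from_matrix(model.transition_matrix, source, target,
                            dt=model.lag_time, stationary=model.stationary)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKResult:
    k_values: np.ndarray
    predicted: np.ndarray  # (n_sets, n_k)
    estimated: np.ndarray  # (n_sets, n_k); NaN where data insufficient
    lower: np.ndarray
    upper: np.ndarray
    passed: np.ndarray  # per-set bool: prediction inside band at all available k
    gaps: list[int] = field(default_factory=list)  # k values lacking data


def _set_occupation(P: np.ndarray, pi: np.ndarray, local_set: np.ndarray,
                    n_applications: int) -> float:
    """Probability of remaining in `local_set` after n applications of P,
    starting from pi restricted to the set."""
    w = np.zeros(len(pi))
    w[local_set] = pi[local_set] / pi[local_set].sum()
    for _ in range(n_applications):
        w = w @ P
    return float(w[local_set].sum())


def _estimated_occupation(dtrajs, lag, active_global, set_global, pi_ref) -> float:
    cm = count_matrix(dtrajs, lag)
    mdl = estimate_reversible_mle(cm)
    common = np.intersect1d(mdl.active_set, set_global)
    if common.size == 0:
        return np.nan
    local = np.searchsorted(mdl.active_set, common)
    return _set_occupation(mdl.transition_matrix, mdl.stationary, local, 1)


def ck_test(dtrajs: list[DiscreteTrajectory], model: TransitionModel,
            memberships: np.ndarray, k_values, n_bootstrap: int = 500,
            seed: int = 0, conf: float = 0.95) -> CKResult:
    """Chapman-Kolmogorov test: does P(tau)^k predict the data at k*tau?

    For each metastable set (crisp argmax of the membership matrix, aligned
    with the model's active set) the population is initialized in the set and
    its survival is propagated with P(tau)^k (prediction) and re-estimated
    from the data at lag k*tau (reference). Confidence bands come from
    bootstrapping whole trajectories; a set passes if the prediction lies
    inside the band at every k with sufficient data.
    """
    k_values = np.asarray(sorted(int(k) for k in k_values))
    if k_values.min() < 1:
        raise ValidationError("k values must be >= 1")
    chi = np.asarray(memberships, dtype=float)
    crisp = np.argmax(chi, axis=1)
    n_sets = chi.shape[1]
    sets_local = [np.flatnonzero(crisp == m) for m in range(n_sets)]
    sets_global = [model.active_set[s] for s in sets_local]
    max_len = max(len(d) for d in dtrajs)

    pred = np.full((n_sets, len(k_values)), np.nan)
    est = np.full_like(pred, np.nan)
    lo = np.full_like(pred, np.nan)
    hi = np.full_like(pred, np.nan)
    gaps = []
    rng = np.random.default_rng(seed)
    for a, k in enumerate(k_values):
        lag_k = int(k) * model.lag
        for m in range(n_sets):
            if sets_local[m].size == 0:
                continue
            pred[m, a] = _set_occupation(model.transition_matrix, model.stationary,
                                         sets_local[m], int(k))
        if lag_k >= max_len:
            gaps.append(int(k))
            continue
        for m in range(n_sets):
            if sets_local[m].size == 0:
                continue
            est[m, a] = _estimated_occupation(dtrajs, lag_k, model.active_set,
                                              sets_global[m], model.stationary)
        boot = np.full((n_bootstrap, n_sets), np.nan)
        for b in range(n_bootstrap):
            idx = rng.integers(0, len(dtrajs), len(dtrajs))
            sample = [dtrajs[i] for i in idx]
            try:
                for m in range(n_sets):
                    if sets_local[m].size:
                        boot[b, m] = _estimated_occupation(
                            sample, lag_k, model.active_set, sets_global[m],
                            model.stationary)
            except (ValidationError, NotConvergedError):
                continue
        q_lo, q_hi = (1 - conf) / 2, (1 + conf) / 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo[:, a] = np.nanquantile(boot, q_lo, axis=0)
            hi[:, a] = np.nanquantile(boot, q_hi, axis=0)
    ok = np.ones(n_sets, dtype=bool)
    for m in range(n_sets):
        have = ~np.isnan(lo[m]) & ~np.isnan(pred[m])
        ok[m] = bool(np.all((pred[m][have] >= lo[m][have]) &
                            (pred[m][have] <= hi[m][have])))
    return CKResult(k_values=k_values, predicted=pred, estimated=est,
                    lower=lo, upper=hi, passed=ok, gaps=gaps)


# ---------------------------------------------------------------------------
# cross-validated variational score
# ---------------------------------------------------------------------------

def _test_correlations(dtrajs, lag, active_global):
    """Indicator-feature C(0) and symmetrized C(tau) on held-out data,
    restricted to the training active set (unseen states drop their pairs)."""
    k = len(active_global)
    pos = -np.ones(int(max(active_global)) + 2, dtype=int)
    pos[active_global] = np.arange(k)
    C = np.zeros((k, k))
    d0 = np.zeros(k)
    for d in dtrajs:
        s = d.states
        if len(s) <= lag:
            continue
        a = s[:-lag]
        b = s[lag:]
        a_ok = (a <= max(active_global)) & (pos[np.minimum(a, len(pos) - 1)] >= 0)
        b_ok = (b <= max(active_global)) & (pos[np.minimum(b, len(pos) - 1)] >= 0)
        keep = a_ok & b_ok
        la, lb = pos[a[keep]], pos[b[keep]]
        np.add.at(C, (la, lb), 1.0)
        np.add.at(d0, la, 0.5)
        np.add.at(d0, lb, 0.5)
    return np.diag(d0), (C + C.T) / 2


def variational_cv_score(projected: list[np.ndarray], lag: int,
                         k_candidates=(50, 75, 100, 150, 200, 300),
                         n_folds: int = 2, m: int = 5, seed: int = 0,
                         dt: float = 1.0):
    """Cross-validated variational (GMRQ/VAMP-2-type) score per microstate count.

    Folds split whole trajectories. For each candidate k the training folds
    are re-discretized and a reversible MSM estimated; the score on the
    held-out folds is the sum of squared estimated eigenvalues of the leading
    m processes (the stationary process contributes 1, so k=1 scores 1).
    Returns a DataFrame with mean and SD over folds per candidate, plus a
    ``skipped`` counter for folds whose active set was empty.
    """
    import pandas as pd

    if len(projected) < 2:
        raise ValidationError("need >= 2 trajectories to form whole-trajectory folds")
    n_folds = min(n_folds, len(projected))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(projected))
    folds = np.array_split(order, n_folds)
    rows = []
    for k in k_candidates:
        scores, skipped = [], 0
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            train = [projected[i] for i in train_idx]
            test = [projected[i] for i in test_idx]
            try:
                dtrain, centers = kmeans_discretize(train, k, seed=seed + 1000 * f,
                                                    dt=dt)
                cm = count_matrix(dtrain, lag)
                mdl = estimate_reversible_mle(cm)
            except (ValidationError, NotConvergedError):
                skipped += 1
                warnings.warn(f"fold {f} skipped for k={k}", stacklevel=2)
                continue
            m_eff = min(m, mdl.n_states)
            V = mdl.right_eigenvectors(m_eff)
            dtest = assign_to_centers(test, centers, dt=dt)
            C00, C0t = _test_correlations(dtest, lag, mdl.active_set)
            A = V.T @ C00 @ V
            B = V.T @ C0t @ V
            A = A + 1e-12 * np.trace(A) / m_eff * np.eye(m_eff)
            try:
                mu = scipy.linalg.eigh(B, A, eigvals_only=True)
            except scipy.linalg.LinAlgError:
                skipped += 1
                continue
            scores.append(float(np.sum(np.clip(mu, -1.0, 1.0) ** 2)))
        rows.append({"k": int(k),
                     "score_mean": float(np.mean(scores)) if scores else np.nan,
                     "score_sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                     "n_folds_used": len(scores), "skipped": skipped})
    return pd.DataFrame(rows)
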