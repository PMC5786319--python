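"""Time-lagged independent component analysis (TICA).

Finds the slow linear subspace of a set of feature trajectories by solving
the generalized eigenproblem C(tau) v = lambda C(0) v, where C(0) and C(tau)
are the instantaneous and time-lagged covariance matrices pooled over
trajectories. C(tau) is symmetrized, which for data in equilibrium yields
real eigenvalues |lambda| <= 1; the implied relaxation timescale of component
i is -tau/ln|lambda_i|. The "kinetic variance" carried by a component is
lambda_i^2, and the cumulative kinetic variance is the running fraction of
the total, used to pick how many components to keep.

Covariances use the symmetrized pair estimator over all (t, t+lag) pairs:
with m the mean of all pair endpoints,

    C(0)   = 1/(2N) sum_t [ (x_t-m)(x_t-m)^T + (x_{t+lag}-m)(x_{t+lag}-m)^T ]
    C(tau) = 1/(2N) sum_t [ (x_t-m)(x_{t+lag}-m)^T + transpose ]

so frames within `lag` of a trajectory end contribute only through the pairs
they belong to. C(0) is regularized by eps*I with eps = 1e-10 * trace/k to
make near-duplicate distance features harmless.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import ValidationError
from .types import FeatureTrajectory

__all__ = ["TICAModel", "fit_tica", "project"]


@dataclass
class TICAModel:
    lag: int  # frames
    mean: np.ndarray
    instantaneous_cov: np.ndarray
    lagged_cov: np.ndarray
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # (features, components), C(0)-orthonormal columns
    feature_names: list[str]
    dt: float = 1.0

    @property
    def cumulative_kinetic_variance(self) -> np.ndarray:
        kv = self.eigenvalues ** 2
        return np.cumsum(kv) / kv.sum()

    @property
    def timescales(self) -> np.ndarray:
        """Implied TICA timescales -tau/ln|lambda_i| in frames."""
        lam = np.abs(self.eigenvalues)
        with np.errstate(divide="ignore"):
            return np.where(lam >= 1.0, np.inf, -self.lag / np.log(lam))


def fit_tica(trajs: list[FeatureTrajectory], lag: int,
             epsilon_scale: float = 1e-10) -> TICAModel:
    """Fit TICA on the pooled (t, t+lag) pairs of all trajectories."""
    if lag < 1:
        raise ValidationError("lag must be >= 1 frame")
    usable = [t for t in trajs if t.n_frames > lag]
    if not usable:
        raise ValidationError("lag must be shorter than at least one trajectory")
    names = usable[0].feature_names
    k = len(names)
    if k < 2:
        raise ValidationError("TICA needs at least 2 features")
    for t in usable:
        if t.feature_names != names:
            raise ValidationError("feature names differ between trajectories")

    n_pairs = 0
    s = np.zeros(k)
    for t in usable:
        x, y = t.values[:-lag], t.values[lag:]
        n_pairs += x.shape[0]
        s += x.sum(axis=0) + y.sum(axis=0)
    mean = s / (2 * n_pairs)

    c0 = np.zeros((k, k))
    ct = np.zeros((k, k))
    for t in usable:
        x = t.values[:-lag] - mean
        y = t.values[lag:] - mean
        c0 += x.T @ x + y.T @ y
        ct += x.T @ y
    c0 /= 2 * n_pairs
    ct = (ct + ct.T) / (2 * n_pairs)

    var = np.diag(c0)
    degenerate = var <= 1e-14 * max(var.max(), 1.0)
    if degenerate.any():
        bad = [names[i] for i in np.flatnonzero(degenerate)]
        raise ValidationError(f"features with (near-)zero variance: {bad}")

    eps = epsilon_scale * np.trace(c0) / k
    c0_reg = c0 + eps * np.eye(k)
    try:
        lam, vecs = scipy.linalg.eigh(ct, c0_reg)
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise ValidationError(f"C(0) is rank-deficient beyond regularization: {err}")
    order = np.argsort(lam)[::-1]
    lam, vecs = lam[order], vecs[:, order]
    # deterministic sign: each component's largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return TICAModel(lag=lag, mean=mean, instantaneous_cov=c0, lagged_cov=ct,
                     eigenvalues=lam, components=vecs, feature_names=list(names),
                     dt=usable[0].dt)


def project(model: TICAModel, traj: FeatureTrajectory,
            n_components: int | None = None,
            variance_threshold: float | None = None) -> np.ndarray:
    """Project a feature trajectory on the leading TICA components.

    If ``variance_threshold`` is given, the smallest number of components
    whose cumulative kinetic variance reaches it is used.
    """
    if traj.feature_names != model.feature_names:
        raise ValidationError("feature names of trajectory and model differ")
    if variance_threshold is not None:
        ckv = model.cumulative_kinetic_variance
        n_components = int(np.searchsorted(ckv, variance_threshold) + 1)
        n_components = min(n_components, model.components.shape[1])
    if n_components is None:
        n_components = model.components.shape[1]
    if n_components > model.components.shape[1]:
        raise ValidationError("more components requested than available")
    return (traj.values - model.mean) @ model.components[:, :n_components]
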