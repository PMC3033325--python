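"""Latent class models: cardinality rules, EM fitting, imputation, validation.

A latent class model (LCM) here is a star-shaped Bayesian network: one
discrete latent root H with prior P(H) and a set of observed children
X_1..X_c, each with a conditional probability table P(X_j | H).  Children
are conditionally independent given H, so the model factorizes as
P(H) ∏_j P(X_j | H).  Parameters are fitted by expectation–maximization on
complete child data; the latent column is then imputed per individual either
as the posterior mode (MAP) or by sampling the exact posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .info import mutual_information, scaled_mutual_information

#: Laplace-style smoothing added to responsibilities before M-step
#: normalization, to avoid zero-probability lock-in.
EM_SMOOTHING = 1e-9


@dataclass
class EmConfig:
    """EM settings: restarts, convergence tolerance, iteration cap."""

    n_restarts: int = 3
    max_iter: int = 500
    tol: float = 1e-6


@dataclass
class LatentClassModel:
    """A fitted one-latent-root LCM.

    Attributes
    ----------
    latent_id : str
        Identifier of the latent variable (``H<layer>_<index>`` nomenclature).
    cardinality : int
        Number of latent states (>= 2).
    child_ids : list
        Identifiers of the child variables, in column order.
    prior : ndarray, shape (cardinality,)
        P(H); sums to 1.
    child_cpts : list of ndarray
        Per child, P(X_j | H) as a (child_card × cardinality) table whose
        columns each sum to 1.
    loglik_trace : list of float
        Log-likelihood per iteration of the winning restart (non-decreasing).
    n_restarts_used : int
    """

    latent_id: str
    cardinality: int
    child_ids: list
    prior: np.ndarray
    child_cpts: list[np.ndarray]
    loglik_trace: list[float] = field(default_factory=list)
    n_restarts_used: int = 1

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise ValueError("latent cardinality must be >= 2")
        if len(self.child_ids) < 2:
            raise ValueError("an LCM needs at least 2 children")
        self.prior = np.asarray(self.prior, dtype=float)
        if abs(self.prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")
        for cpt in self.child_cpts:
            if np.abs(cpt.sum(axis=0) - 1.0).max() > 1e-9:
                raise ValueError("every CPT column must sum to 1")


def latent_cardinality(cluster_size: int, a: float, b: float,
                       card_max: int) -> int:
    """Affine cardinality rule: min(floor(a·size + b), card_max), floored at 2."""
    if card_max < 2:
        raise ValueError("card_max must be >= 2")
    if cluster_size < 2:
        raise ValueError("cluster size must be >= 2")
    card = min(int(np.floor(a * cluster_size + b)), card_max)
    return max(card, 2)


def regularization_cardinality(child_cards: list[int]) -> int:
    """Product of child cardinalities divided by their maximum.

    The classical regularization rule for a latent variable's cardinality;
    kept as a utility because it grows exponentially in the cluster size
    (ten ternary children already yield 3^9 = 19683 states), which is why
    the affine rule above is used in the construction instead.
    """
    if not child_cards:
        raise ValueError("need at least one child cardinality")
    if any(c < 2 for c in child_cards):
        raise ValueError("child cardinalities must be >= 2")
    prod = 1
    for c in child_cards:
        prod *= int(c)
    return prod // max(child_cards)


def _log_posterior(data: np.ndarray, prior: np.ndarray,
                   cpts: list[np.ndarray]) -> np.ndarray:
    """Unnormalized log P(H=h | x_i) for all individuals; shape (n, K)."""
    with np.errstate(divide="ignore"):
        lp = np.log(prior)[None, :].repeat(data.shape[0], axis=0)
        for j, cpt in enumerate(cpts):
            lp += np.log(cpt)[data[:, j], :]
    return lp


def em_learn(data, cardinality: int, config: EmConfig | None = None,
             seed=None, child_ids=None, child_cards=None,
             latent_id: str = "H") -> LatentClassModel:
    """Fit an LCM by EM with random restarts; return the best fit.

    Parameters
    ----------
    data : ndarray of int, shape (n, c)
        Complete categorical child observations, c >= 2 columns.
    cardinality : int
        Latent cardinality K >= 2.
    config : EmConfig
    seed : int, numpy Generator or SeedSequence
        Drives restart initialization.
    child_cards : list of int, optional
        Number of states per child column; defaults to ``max+1`` (min 2).
    """
    data = np.asarray(data, dtype=np.int64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 child columns")
    if cardinality < 2:
        raise ValueError("latent cardinality must be >= 2")
    config = config or EmConfig()
    rng = np.random.default_rng(seed)
    n, c = data.shape
    if child_cards is None:
        child_cards = [max(int(data[:, j].max()) + 1, 2) for j in range(c)]
    if child_ids is None:
        child_ids = list(range(c))
    if all(np.ptp(data[:, j]) == 0 for j in range(c)):
        warnings.warn("all child columns constant; returning a degenerate LCM",
                      stacklevel=2)
    onehots = [np.eye(k)[data[:, j]] for j, k in enumerate(child_cards)]

    best = None
    for _ in range(config.n_restarts):
        prior = rng.dirichlet(np.ones(cardinality))
        cpts = [rng.dirichlet(np.ones(k), size=cardinality).T
                for k in child_cards]
        trace: list[float] = []
        for _ in range(config.max_iter):
            lp = _log_posterior(data, prior, cpts)
            norm = logsumexp(lp, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(lp - norm[:, None])
            trace.append(loglik)
            if len(trace) > 1:
                prev = trace[-2]
                if abs(loglik - prev) <= config.tol * (abs(prev) + 1e-12):
                    break
            # M-step
            resp_s = resp + EM_SMOOTHING
            prior = resp_s.sum(axis=0)
            prior /= prior.sum()
            cpts = []
            for oh in onehots:
                tab = oh.T @ resp_s  # (child_card, K)
                cpts.append(tab / tab.sum(axis=0, keepdims=True))
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], prior, cpts, trace)

    _, prior, cpts, trace = best
    return LatentClassModel(
        latent_id=latent_id, cardinality=cardinality,
        child_ids=list(child_ids), prior=prior, child_cpts=cpts,
        loglik_trace=trace, n_restarts_used=config.n_restarts)


def posterior(model: LatentClassModel, data) -> np.ndarray:
    """P(H | children) per individual; shape (n, K)."""
    data = np.asarray(data, dtype=np.int64)
    if data.shape[1] != len(model.child_ids):
        raise ValueError("column count does not match the model's children")
    lp = _log_posterior(data, model.prior, model.child_cpts)
    return np.exp(lp - logsumexp(lp, axis=1)[:, None])


def impute(model: LatentClassModel, data, mode: str = "map",
           seed=None) -> np.ndarray:
    """Impute the latent column: posterior argmax (``map``) or posterior draw.

    MAP ties break toward the lowest state index; sampling uses the exact
    per-individual posterior and is reproducible given ``seed``.
    """
    post = posterior(model, data)
    if mode == "map":
        return post.argmax(axis=1)
    if mode == "sample":
        rng = np.random.default_rng(seed)
        u = rng.random(post.shape[0])
        return (post.cumsum(axis=1) < u[:, None]).sum(axis=1)
    raise ValueError(f"unknown imputation mode: {mode}")


def criterion_c(model: LatentClassModel, child_data, latent_values) -> float:
    """Average scaled MI between each child and the imputed latent column.

    This is the information-decay criterion: the mean over children of
    I(X_j, H) / min(H(X_j), H(H)) computed on imputed latent values.  A value
    near 1 means the latent variable captures nearly all the information of
    each child; a candidate latent variable is validated when the criterion
    reaches the dilution threshold t.
    """
    child_data = np.asarray(child_data, dtype=np.int64)
    latent_values = np.asarray(latent_values, dtype=np.int64)
    terms = [scaled_mutual_information(child_data[:, j], latent_values)
             for j in range(child_data.shape[1])]
    return float(np.mean(terms))


def delta_information(model: LatentClassModel, child_data,
                      latent_values) -> float:
    """Sum of MI over all LCM edges (bits): Σ_j I(X_j, H)."""
    child_data = np.asarray(child_data, dtype=np.int64)
    latent_values = np.asarray(latent_values, dtype=np.int64)
    return float(sum(mutual_information(child_data[:, j], latent_values)
                     for j in range(child_data.shape[1])))
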