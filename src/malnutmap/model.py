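"""Bayesian hierarchical binomial space-time model for district prevalence.

For each nutritional outcome independently, weighted numerator counts Y_ij in
district i = 1..I and survey wave j = 1..J are modelled as

    Y_ij ~ Binomial(n_ij, pi_ij),
    logit(pi_ij) = alpha + phi_i + gamma_j + nu_ij,

with an improper flat prior on the intercept alpha, an intrinsic conditional
autoregressive (CAR) prior on the spatial effects phi (each district's effect
is conditionally normal around the mean of its common-boundary neighbours,
with conditional variance 1/(tau_phi * m_i)), a first-order random-walk (RW1)
prior on the wave effects gamma, and exchangeable N(0, 1/tau_nu) space-time
interactions nu.  The three precisions get Gamma(0.5, 0.0005) priors.  phi
and gamma are recentred to sum to zero after every sweep (their means are
absorbed into alpha, which leaves the likelihood and the shift-invariant
improper priors unchanged) so that alpha is identifiable.

Sampling is Metropolis-within-Gibbs: conjugate Gamma draws for the three
precisions and scalar Gaussian random-walk Metropolis for alpha, each phi_i,
gamma_j and nu_ij.  Scalar sites are swept in graph-colour classes — sites in
one class are conditionally independent given the rest, so their single-site
accept/reject steps can be executed simultaneously without changing the
kernel.  Proposal scales adapt towards a 44% acceptance rate during burn-in
only.  The sampler keeps drawing (in blocks) until the Monte Carlo error of
every monitored parameter is below 5% of its posterior SD and the
Gelman-Rubin statistic is below the configured threshold, or an iteration cap
is reached, in which case the results are flagged unconverged.

Cells with n_ij = 0 contribute no likelihood; their prevalence is purely
model-smoothed, which is how empty district-waves are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .spatial import AdjacencyGraph

__all__ = [
    "CountPanel",
    "McmcConfig",
    "SpaceTimeCARModel",
    "SpaceTimeCARResults",
    "build_count_panel",
    "car_full_conditional",
    "rw1_full_conditional",
    "precision_gibbs_update",
    "gelman_rubin",
    "mc_error",
    "dic",
    "exceedance_probability",
    "holdout_validation",
    "prior_sensitivity",
    "SIGNIFICANCE_LEVEL",
]

#: Exceedance probabilities strictly above this level are deemed significant.
SIGNIFICANCE_LEVEL = 0.8


class ModelError(ValueError):
    pass


class DiagnosticError(ValueError):
    pass


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class CountPanel:
    """District x wave numerators and denominators for one outcome."""

    outcome: str
    Y: np.ndarray  # (I, J) integer numerators
    n: np.ndarray  # (I, J) integer denominators; 0 encodes a missing cell
    wave_labels: Sequence = ()

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.Y.shape != self.n.shape or self.Y.ndim != 2:
            raise ModelError("Y and n must be equal-shape (I, J) matrices")
        if np.any(self.n < 0) or np.any(self.Y < 0) or np.any(self.Y > self.n):
            raise ModelError("need 0 <= Y_ij <= n_ij")
        if not self.wave_labels:
            self.wave_labels = list(range(1, self.J + 1))

    @property
    def I(self) -> int:  # noqa: E743 - field name matches the model index
        return self.Y.shape[0]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(np.arange(self.I), np.arange(self.J), indexing="ij")
        return pd.DataFrame(
            {
                "district_id": ii.ravel() + 1,
                "wave": jj.ravel() + 1,
                "Y": self.Y.ravel().astype(int),
                "n": self.n.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome: str = "") -> "CountPanel":
        I = int(df["district_id"].max())
        J = int(df["wave"].max())
        Y = np.zeros((I, J))
        n = np.zeros((I, J))
        Y[df["district_id"] - 1, df["wave"] - 1] = df["Y"]
        n[df["district_id"] - 1, df["wave"] - 1] = df["n"]
        return cls(outcome=outcome, Y=Y, n=n)

    @classmethod
    def from_csv(cls, path, outcome: str = "") -> "CountPanel":
        return cls.from_frame(pd.read_csv(path), outcome=outcome)


def build_count_panel(
    prevalence: np.ndarray, sample_sizes: np.ndarray, outcome: str = ""
) -> CountPanel:
    """Turn survey-weighted prevalence estimates and per-cell sample sizes
    into integer binomial counts: Y_ij = round(p_ij * n_ij), clamped."""
    p = np.asarray(prevalence, dtype=float)
    n = np.asarray(sample_sizes, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ModelError("prevalence estimates must lie in [0, 1]")
    Y = np.clip(np.round(p * n), 0, n)
    return CountPanel(outcome=outcome, Y=Y, n=n)


@dataclass
class McmcConfig:
    """Sampler settings; defaults follow the two-chain, 10 000 burn-in
    protocol with Gamma(0.5, 0.0005) precision hyperpriors."""

    n_chains: int = 2
    burn_in: int = 10_000
    n_keep: int = 2_000
    thin: int = 10
    seed: int = 0
    hyper_shape: float = 0.5
    hyper_rate: float = 0.0005
    proposal_sds: dict = field(
        default_factory=lambda: {"alpha": 0.1, "phi": 0.3, "gamma": 0.2, "nu": 0.5}
    )
    adapt: bool = True
    rhat_threshold: float = 1.1
    mc_error_fraction: float = 0.05
    max_extra_blocks: int = 3  # extension blocks of n_keep draws each
    extend_until_converged: bool = True
    # toy-model devices: freeze blocks / precisions for oracle comparisons
    fix_gamma: bool = False
    fix_nu: bool = False
    fixed_tau_phi: Optional[float] = None
    fixed_tau_gamma: Optional[float] = None
    fixed_tau_nu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.n_keep <= 0 or self.thin <= 0:
            raise ModelError("burn_in, n_keep and thin must be positive")
        if self.hyper_shape <= 0 or self.hyper_rate <= 0:
            raise ModelError("hyperprior shape and rate must be positive")


# --------------------------------------------------------------------------
# full conditionals and conjugate updates (also used as test probes)
# --------------------------------------------------------------------------

def car_full_conditional(
    phi: np.ndarray, i: int, graph: AdjacencyGraph, tau_phi: float
) -> tuple[float, float]:
    """Prior full conditional of phi_i under the intrinsic CAR: normal with
    mean = neighbours' average and variance 1/(tau_phi * m_i).  Isolated
    nodes fall back to the exchangeable N(0, 1/tau_phi)."""
    nb = sorted(graph.neighbours.get(i + 1, set()))
    if not nb:
        return 0.0, 1.0 / tau_phi
    vals = np.asarray([phi[j - 1] for j in nb])
    m = len(nb)
    return float(vals.mean()), 1.0 / (tau_phi * m)


def rw1_full_conditional(
    gamma: np.ndarray, j: int, J: int, tau_gamma: float
) -> tuple[float, float]:
    """Prior full conditional of gamma_j under the RW1 (path-graph CAR):
    interior points average their two temporal neighbours with variance
    1/(2 tau), endpoints take their single neighbour with variance 1/tau."""
    if J < 2:
        raise ModelError("RW1 prior needs at least two periods")
    if not 0 <= j < J:
        raise ModelError(f"period index {j} outside 0..{J - 1}")
    if j == 0:
        return float(gamma[1]), 1.0 / tau_gamma
    if j == J - 1:
        return float(gamma[J - 2]), 1.0 / tau_gamma
    return float(0.5 * (gamma[j - 1] + gamma[j + 1])), 1.0 / (2.0 * tau_gamma)


def precision_gibbs_update(
    effects: np.ndarray,
    structure: str,
    hyper_shape: float,
    hyper_rate: float,
    rng: np.random.Generator,
    graph: Optional[AdjacencyGraph] = None,
) -> float:
    """Conjugate Gamma draw for a random-effect precision.

    The Gaussian Markov random field contributes the quadratic form q and its
    rank r to the Gamma(shape + r/2, rate + q/2) posterior:
      * CAR:  q = sum over unique neighbour pairs of (phi_i - phi_i')^2
              (+ phi^2 for isolated fallback nodes); r = I - #components
              (+ #isolated);
      * RW1:  q = sum of squared increments; r = J - 1;
      * IID:  q = sum of squares; r = number of effects.
    """
    effects = np.asarray(effects, dtype=float)
    if structure == "car":
        if graph is None:
            raise ModelError("CAR precision update needs the adjacency graph")
        import networkx as nx

        q = sum(
            (effects[a - 1] - effects[b - 1]) ** 2 for a, b in graph.edge_list()
        )
        iso = graph.isolated_nodes
        q += float(sum(effects[i - 1] ** 2 for i in iso))
        n_comp = nx.number_connected_components(graph.to_networkx())
        r = graph.n_nodes - n_comp + len(iso)
    elif structure == "rw1":
        q = float(np.sum(np.diff(effects) ** 2))
        r = len(effects) - 1
    elif structure == "iid":
        q = float(np.sum(effects**2))
        r = effects.size
    else:
        raise ModelError(f"unknown structure {structure!r}")
    shape = hyper_shape + r / 2.0
    rate = hyper_rate + q / 2.0
    return float(rng.gamma(shape, 1.0 / rate))


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains."""
    chains = [np.asarray(c, dtype=float) for c in chains]
    if len(chains) < 2:
        raise DiagnosticError("Gelman-Rubin needs at least two chains")
    n = len(chains[0])
    if any(len(c) != n for c in chains):
        raise DiagnosticError("chains must have equal length")
    draws = np.stack(chains)  # (m, n)
    return float(_rhat_stack(draws[:, :, None])[0])


def _rhat_stack(draws: np.ndarray) -> np.ndarray:
    """Vectorized R-hat for draws of shape (m chains, n draws, P params)."""
    m, n, _ = draws.shape
    chain_means = draws.mean(axis=1)              # (m, P)
    W = draws.var(axis=1, ddof=1).mean(axis=0)    # (P,)
    B = n * chain_means.var(axis=0, ddof=1)       # (P,)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    rhat = np.where((W < 1e-300) & (B < 1e-300), 1.0, rhat)
    return np.where(np.isfinite(rhat), rhat, np.inf)


def mc_error(draws: np.ndarray, batch_size: Optional[int] = None) -> float:
    """Batch-means standard error of the posterior mean of one parameter."""
    draws = np.asarray(draws, dtype=float)
    N = len(draws)
    if batch_size is None:
        batch_size = max(1, N // 30)
    n_batches = N // batch_size
    if n_batches < 20:
        raise DiagnosticError("need at least 20 batches for a batch-means SE")
    trimmed = draws[: n_batches * batch_size].reshape(n_batches, batch_size)
    means = trimmed.mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))


def _mc_error_stack(draws: np.ndarray) -> np.ndarray:
    """Batch-means MC error per parameter, (m, n, P) -> (P,), averaged over
    chains in quadrature."""
    m, n, P = draws.shape
    bs = max(1, n // 30)
    nb = n // bs
    if nb < 2:
        return np.full(P, np.inf)
    t = draws[:, : nb * bs, :].reshape(m, nb, bs, P).mean(axis=2)  # (m, nb, P)
    per_chain = t.std(axis=1, ddof=1) / math.sqrt(nb)              # (m, P)
    return np.sqrt((per_chain**2).mean(axis=0))


def _binomial_deviance(pi: np.ndarray, Y: np.ndarray, n: np.ndarray,
                       lchoose: float) -> float:
    """-2 log binomial likelihood at cell probabilities pi (constants incl.)."""
    eps = 1e-12
    p = np.clip(pi, eps, 1 - eps)
    ll = lchoose + float(np.sum(Y * np.log(p) + (n - Y) * np.log1p(-p)))
    return -2.0 * ll


def dic(pi_draws: np.ndarray, panel: CountPanel) -> tuple[float, float]:
    """Deviance information criterion from posterior draws of the cell
    probabilities: DIC = Dbar + pD, pD = Dbar - D(theta_bar), with theta_bar
    the posterior mean of the cell logits."""
    Y, n = panel.Y, panel.n
    lchoose = float(np.sum(gammaln(n + 1) - gammaln(Y + 1) - gammaln(n - Y + 1)))
    devs = np.array(
        [_binomial_deviance(p, Y, n, lchoose) for p in pi_draws]
    )
    dbar = float(devs.mean())
    eta_bar = np.mean(_logit(pi_draws), axis=0)
    d_at_mean = _binomial_deviance(expit(eta_bar), Y, n, lchoose)
    pD = dbar - d_at_mean
    return dbar + pD, pD


def _logit(p: np.ndarray) -> np.ndarray:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return np.log(p / (1 - p))


def exceedance_probability(
    pi_draws: np.ndarray, i: int, j: int, threshold: float, direction: str = "below"
) -> float:
    """Fraction of posterior draws with pi_ij below (or above) a threshold.

    ``i``/``j`` are 1-based district and wave indices; significance under the
    Richardson criterion requires the probability to exceed 0.8 strictly.
    """
    cell = pi_draws[:, i - 1, j - 1]
    if direction == "below":
        return float(np.mean(cell < threshold))
    if direction == "above":
        return float(np.mean(cell > threshold))
    raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")


def is_significant(prob: float) -> bool:
    """Richardson criterion: strictly greater than 0.8."""
    return prob > SIGNIFICANCE_LEVEL


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _colour_classes(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Greedy proper colouring; returns 0-based index arrays per colour."""
    import networkx as nx

    colours = nx.coloring.greedy_color(graph.to_networkx(), strategy="largest_first")
    classes: dict[int, list[int]] = {}
    for node, col in colours.items():
        classes.setdefault(col, []).append(node - 1)
    return [np.array(sorted(v)) for _, v in sorted(classes.items())]


class _ChainState:
    """One chain of the Metropolis-within-Gibbs sampler, retaining its RNG,
    parameter state and adaptive proposal scales across extension blocks."""

    def __init__(self, model: "SpaceTimeCARModel", config: McmcConfig,
                 rng: np.random.Generator, start_spread: float):
        self.m = model
        self.cfg = config
        self.rng = rng
        I, J = model.panel.I, model.panel.J
        pbar = (model.panel.Y.sum() + 0.5) / (model.panel.n.sum() + 1.0)
        self.alpha = float(np.log(pbar / (1 - pbar)) + start_spread * rng.normal())
        self.phi = 0.1 * start_spread * rng.normal(size=I)
        self.phi -= self.phi.mean()
        self.gamma = np.zeros(J) if config.fix_gamma else 0.1 * start_spread * rng.normal(size=J)
        self.gamma -= self.gamma.mean()
        self.nu = np.zeros((I, J)) if config.fix_nu else 0.05 * start_spread * rng.normal(size=(I, J))
        self.tau_phi = config.fixed_tau_phi or 10.0
        self.tau_gamma = config.fixed_tau_gamma or 10.0
        self.tau_nu = config.fixed_tau_nu or 10.0
        self.sds = dict(config.proposal_sds)
        self.eta = self.alpha + self.phi[:, None] + self.gamma[None, :] + self.nu
        self.accept: dict[str, list] = {k: [0, 0] for k in self.sds}

    # -- block updates ------------------------------------------------------

    def _ll_delta_matrix(self, eps: np.ndarray, rows=None, cols=None) -> np.ndarray:
        """Log-likelihood change for adding eps to eta on a row/column slice."""
        Y, n, eta = self.m.panel.Y, self.m.panel.n, self.eta
        if rows is not None:
            Y, n, eta = Y[rows], n[rows], eta[rows]
        if cols is not None:
            Y, n, eta = Y[:, cols], n[:, cols], eta[:, cols]
        return Y * eps - n * (_softplus(eta + eps) - _softplus(eta))

    def update_alpha(self) -> None:
        eps = self.sds["alpha"] * self.rng.normal()
        delta = float(self._ll_delta_matrix(eps).sum())  # flat prior on alpha
        self.accept["alpha"][1] += 1
        if math.log(self.rng.random()) < delta:
            self.alpha += eps
            self.eta += eps
            self.accept["alpha"][0] += 1

    def update_phi(self) -> None:
        m = self.m
        for idx in m._phi_colours:
            eps = self.sds["phi"] * self.rng.normal(size=len(idx))
            S = m._adj @ self.phi          # neighbour sums (isolated rows -> 0)
            mdeg = m._deg_eff[idx]
            phi_i = self.phi[idx]
            d_prior = -0.5 * self.tau_phi * (
                mdeg * ((phi_i + eps) ** 2 - phi_i**2) - 2.0 * eps * S[idx]
            )
            d_ll = self._ll_delta_matrix(eps[:, None], rows=idx).sum(axis=1)
            acc = np.log(self.rng.random(size=len(idx))) < d_prior + d_ll
            self.phi[idx[acc]] += eps[acc]
            self.eta[idx[acc], :] += eps[acc][:, None]
            self.accept["phi"][0] += int(acc.sum())
            self.accept["phi"][1] += len(idx)
        mean = self.phi.mean()
        self.alpha += mean
        self.phi -= mean  # eta unchanged: mean moved into alpha

    def update_gamma(self) -> None:
        if self.cfg.fix_gamma:
            return
        J = self.m.panel.J
        for idx in (np.arange(0, J, 2), np.arange(1, J, 2)):
            if len(idx) == 0:
                continue
            eps = self.sds["gamma"] * self.rng.normal(size=len(idx))
            d_prior = np.zeros(len(idx))
            for k, j in enumerate(idx):
                for jn in (j - 1, j + 1):
                    if 0 <= jn < J:
                        old = (self.gamma[j] - self.gamma[jn]) ** 2
                        new = (self.gamma[j] + eps[k] - self.gamma[jn]) ** 2
                        d_prior[k] += -0.5 * self.tau_gamma * (new - old)
            d_ll = self._ll_delta_matrix(eps[None, :], cols=idx).sum(axis=0)
            acc = np.log(self.rng.random(size=len(idx))) < d_prior + d_ll
            self.gamma[idx[acc]] += eps[acc]
            self.eta[:, idx[acc]] += eps[acc][None, :]
            self.accept["gamma"][0] += int(acc.sum())
            self.accept["gamma"][1] += len(idx)
        mean = self.gamma.mean()
        self.alpha += mean
        self.gamma -= mean

    def update_nu(self) -> None:
        if self.cfg.fix_nu:
            return
        I, J = self.m.panel.I, self.m.panel.J
        eps = self.sds["nu"] * self.rng.normal(size=(I, J))
        d_prior = -0.5 * self.tau_nu * ((self.nu + eps) ** 2 - self.nu**2)
        d_ll = self._ll_delta_matrix(eps)
        acc = np.log(self.rng.random(size=(I, J))) < d_prior + d_ll
        self.nu[acc] += eps[acc]
        self.eta[acc] += eps[acc]
        self.accept["nu"][0] += int(acc.sum())
        self.accept["nu"][1] += acc.size

    def update_precisions(self) -> None:
        cfg = self.cfg
        if cfg.fixed_tau_phi is None:
            q = self.m._car_quadform(self.phi)
            self.tau_phi = float(
                self.rng.gamma(cfg.hyper_shape + self.m._car_rank / 2.0,
                               1.0 / (cfg.hyper_rate + q / 2.0))
            )
        if cfg.fixed_tau_gamma is None and not cfg.fix_gamma:
            q = float(np.sum(np.diff(self.gamma) ** 2))
            self.tau_gamma = float(
                self.rng.gamma(cfg.hyper_shape + (self.m.panel.J - 1) / 2.0,
                               1.0 / (cfg.hyper_rate + q / 2.0))
            )
        if cfg.fixed_tau_nu is None and not cfg.fix_nu:
            q = float(np.sum(self.nu**2))
            self.tau_nu = float(
                self.rng.gamma(cfg.hyper_shape + self.nu.size / 2.0,
                               1.0 / (cfg.hyper_rate + q / 2.0))
            )

    def sweep(self) -> None:
        self.update_alpha()
        self.update_phi()
        self.update_gamma()
        self.update_nu()
        self.update_precisions()

    def adapt_step(self) -> None:
        for block, (a, t) in self.accept.items():
            if t == 0:
                continue
            rate = a / t
            self.sds[block] = float(
                np.clip(self.sds[block] * math.exp(1.2 * (rate - 0.44)), 1e-3, 10.0)
            )
        self.accept = {k: [0, 0] for k in self.sds}

    def run(self, n_sweeps: int, adapt: bool = False, record: bool = False,
            thin: int = 1) -> Optional[dict]:
        store = None
        if record:
            kept = n_sweeps // thin
            I, J = self.m.panel.I, self.m.panel.J
            store = {
                "pi": np.empty((kept, I, J)),
                "alpha": np.empty(kept),
                "tau_phi": np.empty(kept),
                "tau_gamma": np.empty(kept),
                "tau_nu": np.empty(kept),
            }
        k = 0
        for s in range(n_sweeps):
            self.sweep()
            if adapt and (s + 1) % 50 == 0:
                self.adapt_step()
            if record and (s + 1) % thin == 0:
                store["pi"][k] = expit(self.eta)
                store["alpha"][k] = self.alpha
                store["tau_phi"][k] = self.tau_phi
                store["tau_gamma"][k] = self.tau_gamma
                store["tau_nu"][k] = self.tau_nu
                k += 1
        return store

    def acceptance_rates(self) -> dict:
        return {k: (a / t if t else float("nan")) for k, (a, t) in self.accept.items()}


def metropolis_update_block(
    state: _ChainState, block: str
) -> tuple[_ChainState, float]:
    """Run one Metropolis sweep of a named block ('alpha', 'phi', 'gamma',
    'nu') on a chain state; returns the state and the block acceptance rate."""
    state.accept[block] = [0, 0]
    {"alpha": state.update_alpha, "phi": state.update_phi,
     "gamma": state.update_gamma, "nu": state.update_nu}[block]()
    a, t = state.accept[block]
    return state, (a / t if t else float("nan"))


class SpaceTimeCARModel:
    """Model object binding a :class:`CountPanel` to an adjacency graph.

    Mirrors the statsmodels convention: construct from data, call
    :meth:`fit` to obtain a :class:`SpaceTimeCARResults`.
    """

    def __init__(self, panel: CountPanel, graph: AdjacencyGraph):
        if panel.I != graph.n_nodes:
            raise ModelError(
                f"panel has {panel.I} districts but graph has {graph.n_nodes} nodes"
            )
        if panel.I < 2 and panel.J < 2:
            raise ModelError("model undefined for a single district and single wave")
        self.panel = panel
        self.graph = graph
        self._adj = graph.binary_matrix()
        deg = self._adj.sum(axis=1)
        # isolated nodes: exchangeable N(0, 1/tau) fallback -> unit 'degree',
        # zero neighbour sum
        self._deg_eff = np.where(deg > 0, deg, 1.0)
        self._iso = np.where(deg == 0)[0]
        if len(self._iso):
            import warnings

            warnings.warn(
                f"{len(self._iso)} isolated district(s); exchangeable prior used",
                stacklevel=2,
            )
        self._phi_colours = _colour_classes(graph)
        import networkx as nx

        n_comp = nx.number_connected_components(graph.to_networkx())
        self._car_rank = graph.n_nodes - n_comp + len(self._iso)
        self._edges = graph.edge_list()

    def _car_quadform(self, phi: np.ndarray) -> float:
        q = sum((phi[a - 1] - phi[b - 1]) ** 2 for a, b in self._edges)
        q += float(np.sum(phi[self._iso] ** 2))
        return float(q)

    @classmethod
    def from_csv(cls, panel_path, edges_path, n_districts: Optional[int] = None,
                 outcome: str = "") -> "SpaceTimeCARModel":
        from .spatial import read_edge_list

        panel = CountPanel.from_csv(panel_path, outcome=outcome)
        graph = read_edge_list(edges_path, n_districts or panel.I)
        return cls(panel, graph)

    def fit(self, config: Optional[McmcConfig] = None) -> "SpaceTimeCARResults":
        cfg = config or McmcConfig()
        if self.panel.J < 2 and not cfg.fix_gamma:
            raise ModelError("RW1 temporal prior needs J >= 2 (or fix_gamma)")
        if cfg.n_chains < 1:
            raise ModelError("need at least one chain")
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        chains: list[_ChainState] = []
        stores: list[dict] = []
        for c in range(cfg.n_chains):
            rng = np.random.default_rng(seeds[c])
            state = _ChainState(self, cfg, rng, start_spread=0.5 * (c + 1))
            state.run(cfg.burn_in, adapt=cfg.adapt)
            state.accept = {k: [0, 0] for k in state.sds}  # post-burn-in rates
            stores.append(state.run(cfg.n_keep * cfg.thin, record=True, thin=cfg.thin))
            chains.append(state)

        def _merge(old: dict, new: dict) -> dict:
            return {k: np.concatenate([old[k], new[k]]) for k in old}

        converged, diag = self._diagnose(stores, cfg)
        blocks_used = 0
        while (
            not converged
            and cfg.extend_until_converged
            and blocks_used < cfg.max_extra_blocks
        ):
            for c, state in enumerate(chains):
                extra = state.run(cfg.n_keep * cfg.thin, record=True, thin=cfg.thin)
                stores[c] = _merge(stores[c], extra)
            blocks_used += 1
            converged, diag = self._diagnose(stores, cfg)

        acc = {
            k: float(np.mean([s.acceptance_rates()[k] for s in chains]))
            for k in chains[0].sds
        }
        return SpaceTimeCARResults(
            model=self, config=cfg, chain_stores=stores, converged=converged,
            diagnostics=diag, acceptance_rates=acc,
            n_kept_per_chain=len(stores[0]["alpha"]),
        )

    def _diagnose(self, stores: list[dict], cfg: McmcConfig):
        """Convergence check on the monitored set: alpha, precisions, all pi."""
        m = len(stores)
        n = len(stores[0]["alpha"])
        cells = self.panel.I * self.panel.J
        P = 4 + cells
        draws = np.empty((m, n, P))
        for c, s in enumerate(stores):
            draws[c, :, 0] = s["alpha"]
            draws[c, :, 1] = np.log(s["tau_phi"])
            draws[c, :, 2] = np.log(s["tau_gamma"])
            draws[c, :, 3] = np.log(s["tau_nu"])
            draws[c, :, 4:] = s["pi"].reshape(n, cells)
        names = ["alpha", "log_tau_phi", "log_tau_gamma", "log_tau_nu"] + [
            f"pi[{i + 1},{j + 1}]"
            for i in range(self.panel.I)
            for j in range(self.panel.J)
        ]
        # frozen blocks have constant draws; drop them from the check
        sd_pooled = draws.reshape(m * n, P).std(axis=0, ddof=1)
        active = sd_pooled > 1e-12
        rhat = np.where(active, _rhat_stack(draws), 1.0)
        mce = np.where(active, _mc_error_stack(draws), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(active, mce / np.where(sd_pooled > 0, sd_pooled, 1.0), 0.0)
        ok_rhat = (m < 2) or bool(np.all(rhat[active] < cfg.rhat_threshold))
        ok_mce = bool(np.all(ratio[active] < cfg.mc_error_fraction))
        diag = pd.DataFrame(
            {"parameter": names,
             "posterior_mean": draws.reshape(m * n, P).mean(axis=0),
             "posterior_sd": sd_pooled, "mc_error": mce,
             "mc_error_sd_ratio": ratio, "rhat": rhat}
        )
        return ok_rhat and ok_mce, diag


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

@dataclass
class SpaceTimeCARResults:
    """Posterior draws, summaries and diagnostics for one fitted outcome."""

    model: SpaceTimeCARModel
    config: McmcConfig
    chain_stores: list
    converged: bool
    diagnostics: pd.DataFrame
    acceptance_rates: dict
    n_kept_per_chain: int

    @property
    def pi_draws(self) -> np.ndarray:
        """All chains pooled: (total draws, I, J)."""
        return np.concatenate([s["pi"] for s in self.chain_stores])

    def scalar_draws(self, name: str) -> list[np.ndarray]:
        return [s[name] for s in self.chain_stores]

    def pi_median(self) -> np.ndarray:
        return np.median(self.pi_draws, axis=0)

    def pi_interval(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = (1 - level) / 2
        d = self.pi_draws
        return np.quantile(d, a, axis=0), np.quantile(d, 1 - a, axis=0)

    def dic(self) -> tuple[float, float]:
        return dic(self.pi_draws, self.model.panel)

    def exceedance_probability(
        self, district: int, wave: int, threshold: float, direction: str = "below"
    ) -> float:
        return exceedance_probability(
            self.pi_draws, district, wave, threshold, direction
        )

    def gelman_rubin(self, name: str = "alpha") -> float:
        return gelman_rubin(self.scalar_draws(name))

    def mc_error(self, name: str = "alpha") -> float:
        return mc_error(np.concatenate(self.scalar_draws(name)))

    def summary_frame(self) -> pd.DataFrame:
        """Per district-wave posterior median, 95% credibility interval."""
        med = self.pi_median()
        lo, hi = self.pi_interval()
        rows = []
        for i in range(self.model.panel.I):
            for j in range(self.model.panel.J):
                rows.append(
                    {
                        "district_id": i + 1,
                        "wave": j + 1,
                        "median": med[i, j],
                        "bci_low": lo[i, j],
                        "bci_high": hi[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.model.panel
        d, pD = self.dic()
        lines = [
            "Space-time binomial CAR model results",
            "=" * 48,
            f"Outcome:            {p.outcome or '(unnamed)'}",
            f"Districts x waves:  {p.I} x {p.J}  "
            f"({int((p.n > 0).sum())} observed cells)",
            f"Chains:             {self.config.n_chains} x "
            f"{self.n_kept_per_chain} kept draws (thin {self.config.thin}, "
            f"burn-in {self.config.burn_in})",
            f"Converged:          {self.converged} "
            f"(max R-hat {self.diagnostics['rhat'].max():.3f}, "
            f"max MC-error/SD {self.diagnostics['mc_error_sd_ratio'].max():.3f})",
            f"DIC:                {d:.1f}  (pD = {pD:.1f})",
            "Acceptance rates:   "
            + ", ".join(f"{k}={v:.2f}" for k, v in self.acceptance_rates.items()),
            "-" * 48,
        ]
        for name in ("alpha", "tau_phi", "tau_gamma", "tau_nu"):
            pooled = np.concatenate(self.scalar_draws(name))
            lines.append(
                f"{name:<10} mean {pooled.mean():>9.4f}   sd {pooled.std(ddof=1):>9.4f}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# validation and sensitivity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HoldoutResult:
    table: pd.DataFrame
    rmse: float
    correlation: float
    coverage: float


def holdout_validation(
    panel: CountPanel,
    graph: AdjacencyGraph,
    config: McmcConfig,
    fraction: float = 0.1,
    seed: int = 0,
) -> HoldoutResult:
    """Out-of-sample check: mask a random fraction of observed cells (their n
    is set to 0 so they contribute no likelihood), refit, and compare the
    held-out observed crude rates Y/n with their posterior predictive
    distribution (binomial draws at each posterior prevalence, so the
    interval accounts for the sampling noise in the held-out rate as well as
    the uncertainty in the smoothed prevalence)."""
    rng = np.random.default_rng(seed)
    obs = np.argwhere(panel.n > 0)
    k = int(round(fraction * len(obs)))
    if k == 0:
        return HoldoutResult(pd.DataFrame(
            columns=["district_id", "wave", "observed", "predicted",
                     "bci_low", "bci_high"]), float("nan"), float("nan"), float("nan"))
    mask = obs[rng.choice(len(obs), size=k, replace=False)]
    Y2, n2 = panel.Y.copy(), panel.n.copy()
    for i, j in mask:
        Y2[i, j] = 0
        n2[i, j] = 0
    masked = CountPanel(outcome=panel.outcome, Y=Y2, n=n2,
                        wave_labels=panel.wave_labels)
    res = SpaceTimeCARModel(masked, graph).fit(config)
    med = res.pi_median()
    draws = res.pi_draws
    rows = []
    for i, j in mask:
        n_cell = int(panel.n[i, j])
        ystar = rng.binomial(n_cell, draws[:, i, j]) / n_cell
        rows.append(
            {
                "district_id": i + 1,
                "wave": j + 1,
                "observed": panel.Y[i, j] / panel.n[i, j],
                "predicted": med[i, j],
                "bci_low": float(np.quantile(ystar, 0.025)),
                "bci_high": float(np.quantile(ystar, 0.975)),
            }
        )
    tab = pd.DataFrame(rows)
    err = tab["predicted"] - tab["observed"]
    rmse = float(np.sqrt(np.mean(err**2)))
    corr = float(np.corrcoef(tab["observed"], tab["predicted"])[0, 1]) if len(tab) > 1 else float("nan")
    cover = float(np.mean((tab["observed"] >= tab["bci_low"]) & (tab["observed"] <= tab["bci_high"])))
    return HoldoutResult(tab, rmse, corr, cover)


def prior_sensitivity(
    panel: CountPanel,
    graph: AdjacencyGraph,
    config: McmcConfig,
    alt_hypers: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Refit under alternative Gamma hyperpriors for the precisions and
    report the maximum absolute change in posterior median prevalence."""
    if not alt_hypers:
        raise ModelError("need at least one alternative hyperprior")
    base = SpaceTimeCARModel(panel, graph).fit(config)
    base_med = base.pi_median()
    rows = [
        {"hyper_shape": config.hyper_shape, "hyper_rate": config.hyper_rate,
         "max_abs_change": 0.0, "mean_abs_change": 0.0}
    ]
    for shape, rate in alt_hypers:
        alt_cfg = replace(config, hyper_shape=shape, hyper_rate=rate)
        alt = SpaceTimeCARModel(panel, graph).fit(alt_cfg)
        diff = np.abs(alt.pi_median() - base_med)
        rows.append(
            {"hyper_shape": shape, "hyper_rate": rate,
             "max_abs_change": float(diff.max()),
             "mean_abs_change": float(diff.mean())}
        )
    return pd.DataFrame(rows)
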