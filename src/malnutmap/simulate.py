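"""Synthetic inputs for the district-level malnutrition pipeline.

Everything the pipeline consumes can be generated here with a fixed seed:
a district contiguity graph, space-time prevalence surfaces drawn from the
model's own random-effect structure, binomial count panels, child-level
survey records with a two-stage stratified cluster design and Table-1-style
covariates, and a synthetic LMS growth-reference table.  The generator is
the exact forward counterpart of the fitted model, so full-loop parameter
recovery is well defined.

The defaults emulate the scale of the motivating panel survey: 52 districts,
5 waves, roughly 2 000-4 700 children sampled per wave, hence many small and
some empty district-wave cells — the condition that motivates spatial
smoothing in the first place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .anthropometry import ChildRecord, ReferenceTable, lms_inverse
from .model import CountPanel
from .spatial import AdjacencyGraph, build_adjacency

__all__ = [
    "SimulationTruth",
    "DesignSpec",
    "make_district_graph",
    "simulate_truth",
    "simulate_counts",
    "default_cell_sizes",
    "simulate_children",
    "make_reference_fixture",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters and prevalence surface for one outcome."""

    alpha: float
    phi: np.ndarray
    gamma: np.ndarray
    nu: np.ndarray
    tau_phi: float
    tau_gamma: float
    tau_nu: float
    pi: np.ndarray  # (I, J)
    seed: int


def make_district_graph(
    I: int = 52, style: str = "grid", seed: int = 0
) -> AdjacencyGraph:
    """Connected symmetric stand-in for the district contiguity map.

    ``grid`` builds a wide rook-adjacent lattice (at most 4 rows, so 52
    districts form a 4 x 13 lattice) trimmed to I nodes; ``random_planar``
    triangulates seeded random points (Delaunay), which is always planar and
    connected.
    """
    if I < 4:
        raise ValueError("need at least 4 districts")
    if style == "grid":
        nrows = min(4, math.isqrt(I))
        ncols = math.ceil(I / nrows)
        edges = []
        def node(r, c):
            return r * ncols + c + 1
        for r in range(nrows):
            for c in range(ncols):
                if node(r, c) > I:
                    continue
                if c + 1 < ncols and node(r, c + 1) <= I:
                    edges.append((node(r, c), node(r, c + 1)))
                if r + 1 < nrows and node(r + 1, c) <= I:
                    edges.append((node(r, c), node(r + 1, c)))
        return build_adjacency(edges, I)
    if style == "random_planar":
        from scipy.spatial import Delaunay

        rng = np.random.default_rng(seed)
        for _ in range(20):
            pts = rng.random((I, 2))
            tri = Delaunay(pts)
            edges = set()
            for simplex in tri.simplices:
                for a in range(3):
                    i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                    edges.add((i + 1, j + 1))
            g = build_adjacency(sorted(edges), I)
            import networkx as nx

            if nx.is_connected(g.to_networkx()):
                return g
        raise RuntimeError("failed to draw a connected planar graph")
    raise ValueError(f"unknown style {style!r}")


def _car_draw(graph: AdjacencyGraph, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the sum-to-zero-constrained intrinsic CAR field.

    The intrinsic CAR is improper (flat in the component means); restricted
    to the sum-zero subspace it is a proper Gaussian with covariance
    (tau * L)^+, the pseudo-inverse of the scaled graph Laplacian.  Sampling
    through the Laplacian eigenbasis (zero modes dropped) realises exactly
    the distribution the fitted model's recentred prior assigns, component
    by component.  Isolated nodes get the exchangeable N(0, 1/tau) fallback.
    """
    import networkx as nx

    g = graph.to_networkx()
    phi = np.zeros(graph.n_nodes)
    for comp in nx.connected_components(g):
        idx = np.array(sorted(comp)) - 1
        if len(idx) == 1:
            phi[idx[0]] = rng.normal() / math.sqrt(tau)
            continue
        A = graph.binary_matrix()[np.ix_(idx, idx)]
        L = np.diag(A.sum(axis=1)) - A
        lam, V = np.linalg.eigh(L)
        keep = lam > 1e-9
        z = rng.normal(size=int(keep.sum()))
        phi[idx] = V[:, keep] @ (z / np.sqrt(tau * lam[keep]))
    return phi - phi.mean()


def simulate_truth(
    graph: AdjacencyGraph,
    J: int = 5,
    alpha: float = -2.2,
    tau_phi: float = 2.5,
    tau_gamma: float = 45.0,
    tau_nu: float = 100.0,
    gamma_trend: float = 0.0,
    gamma_profile: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> SimulationTruth:
    """Ground-truth surface logit(pi_ij) = alpha + phi_i + gamma_j + nu_ij.

    phi is a constrained intrinsic-CAR draw, gamma a recentred Gaussian
    random walk with increment precision tau_gamma plus an optional linear
    per-wave drift, nu i.i.d. N(0, 1/tau_nu).  ``gamma_profile`` replaces the
    random walk with a fixed wave trajectory (recentred), e.g. logits of an
    observed national series.
    """
    if min(tau_phi, tau_gamma, tau_nu) <= 0:
        raise ValueError("precisions must be positive")
    rng = np.random.default_rng(seed)
    phi = _car_draw(graph, tau_phi, rng)
    if gamma_profile is not None:
        gamma = np.asarray(gamma_profile, dtype=float)
        if len(gamma) != J:
            raise ValueError("gamma_profile must have one entry per wave")
    else:
        inc = rng.normal(0.0, 1.0 / math.sqrt(tau_gamma), size=J - 1)
        gamma = np.concatenate([[0.0], np.cumsum(inc)])
        gamma = gamma + gamma_trend * np.arange(J)
    gamma = gamma - gamma.mean()
    nu = rng.normal(0.0, 1.0 / math.sqrt(tau_nu), size=(graph.n_nodes, J))
    pi = expit(alpha + phi[:, None] + gamma[None, :] + nu)
    return SimulationTruth(
        alpha=alpha, phi=phi, gamma=gamma, nu=nu,
        tau_phi=tau_phi, tau_gamma=tau_gamma, tau_nu=tau_nu, pi=pi, seed=seed,
    )


def default_cell_sizes(
    I: int = 52,
    J: int = 5,
    mean_per_cell: float = 55.0,
    dispersion: float = 0.6,
    empty_fraction: float = 0.04,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell sample sizes mimicking the survey's sparse district coverage:
    lognormal-Poisson sizes around ~55 children per district-wave (so a few
    thousand valid measurements per wave over 52 districts) with a small
    fraction of empty cells."""
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.normal(math.log(mean_per_cell) - dispersion**2 / 2,
                            dispersion, size=(I, J)))
    n = rng.poisson(lam).astype(float)
    if empty_fraction > 0:
        mask = rng.random((I, J)) < empty_fraction
        n[mask] = 0
    return n


def simulate_counts(
    truth: SimulationTruth, n_matrix: np.ndarray, seed: int = 0,
    outcome: str = "",
) -> CountPanel:
    """Binomial forward simulation: Y_ij ~ Binomial(n_ij, pi_ij)."""
    n = np.asarray(n_matrix, dtype=float)
    if np.any(n < 0):
        raise ValueError("sample sizes must be non-negative")
    rng = np.random.default_rng(seed)
    Y = rng.binomial(n.astype(int), truth.pi).astype(float)
    return CountPanel(outcome=outcome, Y=Y, n=n)


# --------------------------------------------------------------------------
# child-level survey records
# --------------------------------------------------------------------------

# Approximate category frequencies of the study population (marginals).
DEFAULT_COVARIATE_FREQUENCIES: dict[str, dict[str, float]] = {
    "ethnicity": {"African": 0.87, "Coloured": 0.09, "White": 0.03, "Indian": 0.01},
    "birth_weight_class": {"Normal": 0.73, "LBW": 0.12, "Missing": 0.15},
    "income_class": {"low": 0.42, "high": 0.58},
    "environment": {
        "Tribal authority area": 0.46, "Urban formal": 0.37,
        "Urban informal": 0.08, "Rural formal": 0.09,
    },
    "maternal_education": {
        "None": 0.07, "Primary": 0.22, "Secondary": 0.55, "Tertiary": 0.16,
    },
    "child_hunger": {"Never": 0.70, "Seldom": 0.09, "Sometimes": 0.16, "Often": 0.05},
}

#: Under-5 population scale used for the design weights (children).
POPULATION_UNDER5 = 5_800_000


@dataclass
class DesignSpec:
    """Two-stage stratified cluster design for the synthetic survey."""

    n_strata: int = 9                  # pseudo-provinces partitioning districts
    psus_per_district: int = 8         # ~400 PSUs nationally over 52 districts
    weight_cv: float = 0.5             # lognormal variability of design weights
    missing_fraction: float = 0.03     # weight/height measurements set missing
    covariate_frequencies: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_FREQUENCIES.items()
        }
    )
    income_stunting_or: float = 1.0    # >1 enables the correlated-covariate mode


def _two_tail_normal(p_lower: float, p_upper: float) -> tuple[float, float]:
    """Mean and SD of a normal z-distribution hitting P(z < -2) = p_lower and
    P(z >= 2) = p_upper simultaneously."""
    if p_lower + p_upper >= 1.0:
        raise ValueError("tail probabilities must sum to less than 1")
    p_lower = min(max(p_lower, 1e-6), 1 - 1e-6)
    p_upper = min(max(p_upper, 1e-6), 1 - 1e-6)
    a = norm.ppf(p_lower)          # (-2 - mu)/sigma
    b = norm.ppf(1.0 - p_upper)    # (2 - mu)/sigma
    sigma = 4.0 / (b - a)
    mu = -2.0 - a * sigma
    return mu, sigma


def simulate_children(
    truths: Union[SimulationTruth, dict],
    per_wave_sizes: Sequence[int],
    design_spec: Optional[DesignSpec] = None,
    reference_table: Optional[ReferenceTable] = None,
    seed: int = 0,
) -> list[ChildRecord]:
    """Child-level records whose classified prevalences match the truth.

    ``truths`` maps outcome name ('stunting', 'thinness_wasting', 'obesity')
    to a :class:`SimulationTruth`; a single truth is taken as the stunting
    surface with flat 4% thinness and 13% obesity.  For each child, a latent
    height-for-age z is drawn from N(mu, 1) with mu chosen so the < -2 tail
    equals the district-wave stunting prevalence, and a latent weight-based z
    from a normal whose two tails match thinness and obesity; measurements
    are produced by inverting the LMS transform, so classifying them
    reproduces the generating prevalences up to binomial noise.
    """
    spec = design_spec or DesignSpec()
    table = reference_table or make_reference_fixture()
    if isinstance(truths, SimulationTruth):
        s = truths
        flat = lambda p: SimulationTruth(  # noqa: E731
            alpha=0.0, phi=np.zeros(s.pi.shape[0]), gamma=np.zeros(s.pi.shape[1]),
            nu=np.zeros(s.pi.shape), tau_phi=1, tau_gamma=1, tau_nu=1,
            pi=np.full(s.pi.shape, p), seed=s.seed,
        )
        truths = {"stunting": s, "thinness_wasting": flat(0.04), "obesity": flat(0.13)}
    pi_s = truths["stunting"].pi
    pi_t = truths["thinness_wasting"].pi
    pi_o = truths["obesity"].pi
    if np.any(pi_t + pi_o >= 1.0):
        raise ValueError("thinness + obesity prevalence must be below 1 per cell")
    I, J = pi_s.shape
    if len(per_wave_sizes) != J:
        raise ValueError("per_wave_sizes must have one entry per wave")

    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.full(I, 5.0))
    district_stratum = 1 + (np.arange(I) * spec.n_strata) // I

    records: list[ChildRecord] = []
    cid = 0
    for j in range(J):
        counts = rng.multinomial(int(per_wave_sizes[j]), shares)
        base_w = POPULATION_UNDER5 / max(int(per_wave_sizes[j]), 1)
        for d in range(I):
            mu_h = -2.0 - norm.ppf(min(max(pi_s[d, j], 1e-6), 1 - 1e-6))
            mu_w, sd_w = _two_tail_normal(pi_t[d, j], pi_o[d, j])
            for c in range(counts[d]):
                cid += 1
                age = float(rng.uniform(0.0, 60.0))
                sex = "male" if rng.random() < 0.5 else "female"
                zh = float(rng.normal(mu_h, 1.0))
                zw = float(rng.normal(mu_w, sd_w))
                height, weight = _invert_measurements(table, sex, age, zh, zw)
                if rng.random() < spec.missing_fraction:
                    if rng.random() < 0.5:
                        height = None
                        weight = None
                    else:
                        weight = None
                stunted_latent = zh < -2.0
                cov = _draw_covariates(rng, spec, stunted_latent)
                w = base_w * float(
                    rng.lognormal(-spec.weight_cv**2 / 2, spec.weight_cv)
                )
                psu = 1 + int(rng.integers(spec.psus_per_district))
                records.append(
                    ChildRecord(
                        child_id=f"c{cid:06d}",
                        wave=j + 1,
                        district_id=d + 1,
                        age_months=age,
                        sex=sex,
                        weight_kg=weight,
                        height_cm=height,
                        design_weight=w,
                        stratum_id=f"prov{district_stratum[d]}",
                        psu_id=f"d{d + 1}w{j + 1}p{psu}",
                        covariates=cov,
                    )
                )
    return records


def _invert_measurements(table, sex, age, zh, zw):
    """Measurements from latent z-scores via the inverse LMS transform."""
    L, M, S = table.lookup("height_for_age", sex, age)
    try:
        height = lms_inverse(zh, L, M, S)
    except ValueError:
        height = M  # unrepresentably extreme z; fall back to the median
    if age < 24.0:
        block = table._blocks[("weight_for_length", sex)]
        lo, hi = block["index_value"].iloc[0], block["index_value"].iloc[-1]
        length = float(np.clip(height, lo, hi))
        L, M, S = table.lookup("weight_for_length", sex, length)
        try:
            weight = lms_inverse(zw, L, M, S)
        except ValueError:
            weight = M
    else:
        L, M, S = table.lookup("bmi_for_age", sex, age)
        try:
            bmi = lms_inverse(zw, L, M, S)
        except ValueError:
            bmi = M
        weight = bmi * (height / 100.0) ** 2
    return height, weight


def _draw_covariates(rng, spec: DesignSpec, stunted: bool) -> dict:
    cov = {}
    for name, freqs in spec.covariate_frequencies.items():
        cats = list(freqs)
        probs = np.array([freqs[c] for c in cats], dtype=float)
        probs /= probs.sum()
        if name == "income_class" and spec.income_stunting_or != 1.0 and "low" in freqs:
            p0 = freqs["low"]
            odds = p0 / (1 - p0)
            if stunted:
                odds *= spec.income_stunting_or
            p_low = odds / (1 + odds)
            cov[name] = "low" if rng.random() < p_low else "high"
            continue
        cov[name] = cats[int(rng.choice(len(cats), p=probs))]
    return cov


# --------------------------------------------------------------------------
# synthetic growth reference
# --------------------------------------------------------------------------

def make_reference_fixture() -> ReferenceTable:
    """Synthetic LMS growth-reference table (a stand-in for real growth
    standards; smooth, monotone-median curves by sex, not real reference
    values).

    height_for_age and bmi_for_age are indexed by age 0-60 months,
    weight_for_length by length 40-120 cm; M is strictly increasing in the
    index, S stays in [0.05, 0.2] and L in [-2, 2].
    """
    rows = []
    ages = np.arange(0, 61, 1.0)
    for sex, off in (("male", 0.0), ("female", -0.7)):
        for a in ages:
            rows.append(
                {
                    "indicator": "height_for_age", "sex": sex, "index_value": a,
                    "L": 1.0,
                    "M": 50.0 + off + 1.0 * a - 0.003 * a**2,
                    "S": 0.05 + 0.0002 * a,
                }
            )
        for a in ages:
            rows.append(
                {
                    "indicator": "bmi_for_age", "sex": sex, "index_value": a,
                    "L": -0.6 + 0.005 * a,
                    "M": 13.0 + (0.0 if sex == "male" else -0.2) + 0.02 * a,
                    "S": 0.08 + 0.0003 * a,
                }
            )
    lengths = np.arange(40.0, 121.0, 1.0)
    for sex, scale in (("male", 1.0), ("female", 0.98)):
        for ln in lengths:
            rows.append(
                {
                    "indicator": "weight_for_length", "sex": sex, "index_value": ln,
                    "L": 0.3,
                    "M": scale * (3.0 + 0.12 * (ln - 50.0) + 0.0008 * (ln - 50.0) ** 2),
                    "S": 0.11,
                }
            )
    return ReferenceTable(pd.DataFrame(rows))
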