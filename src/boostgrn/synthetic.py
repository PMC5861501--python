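"""Synthetic ground-truth networks and DREAM4-style time-course data.

The generator emulates the structure of the DREAM4 in-silico time-course
challenge: several replicates of 21 time points; at t=0 about one third
of the genes (a different subset per replicate) receive a perturbation
that is held for the first 10 time points and then removed.

The dynamics are deliberately simple — a stable linear lag-1 Gaussian
system rather than a thermodynamic ODE model — because a linear vector
autoregression is sufficient to exercise lag-1 tree regression and
admits a closed-form least-squares recovery oracle:

    x_g(t+1) = rho_g * x_g(t) + sum_r a_{r->g} * x_r(t) + u_g(t+1) + noise

where rho_g in (0,1) is the gene's self-decay, a_{r->g} the signed edge
weights of the planted network, and u the transient perturbation forcing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import EdgeSet, TimeCourseDataset

_STABILITY_RADIUS = 0.95
_DECAY_RANGE = (0.3, 0.7)
_PERTURB_RANGE = (0.5, 1.0)


@dataclass
class GroundTruthNetwork:
    """Planted regulatory network with linear lag-1 dynamics.

    ``weights[r, g]`` is the signed influence of regulator r on gene g
    (zero diagonal); ``decay[g]`` the self-decay rho_g in (0, 1).
    """

    weights: np.ndarray
    decay: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        p = self.weights.shape[0]
        if self.weights.shape != (p, p):
            raise ValueError("weights must be a square matrix")
        if np.any(np.diagonal(self.weights) != 0):
            raise ValueError("planted networks carry no self-edges")
        if self.decay.shape != (p,) or np.any((self.decay <= 0) | (self.decay >= 1)):
            raise ValueError("decay must be length-P with entries in (0, 1)")
        if self.spectral_radius() >= 1:
            raise ValueError("transition matrix is unstable (spectral radius >= 1)")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    def transition_matrix(self) -> np.ndarray:
        """M with x(t+1) = M @ x(t): decay on the diagonal, edges off it."""
        return np.diag(self.decay) + self.weights.T

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.transition_matrix()))))

    def edge_set(self) -> EdgeSet:
        i_idx, j_idx = np.nonzero(self.weights)
        return EdgeSet(
            positives={(int(i), int(j)) for i, j in zip(i_idx, j_idx)},
            n_genes=self.n_genes,
        )

    def gene_names(self) -> list[str]:
        return [f"G{g + 1}" for g in range(self.n_genes)]


def generate_network(
    P: int,
    density: float = 0.15,
    weight_range: tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
) -> GroundTruthNetwork:
    """Draw a random stable ground-truth network.

    Every ordered non-self pair becomes an edge with probability
    ``density``; edge weights are uniform on ±[low, high].  If the linear
    system is too close to instability the edge weights are shrunk until
    the transition matrix's spectral radius drops below 0.95.
    """
    if P < 2:
        raise ValueError("need at least 2 genes")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    low, high = weight_range
    if not 0 < low <= high:
        raise ValueError("weight_range must satisfy 0 < low <= high")
    rng = np.random.default_rng(seed)

    adjacency = rng.random((P, P)) < density
    np.fill_diagonal(adjacency, False)
    magnitudes = rng.uniform(low, high, size=(P, P))
    signs = rng.choice([-1.0, 1.0], size=(P, P))
    weights = np.where(adjacency, signs * magnitudes, 0.0)
    decay = rng.uniform(*_DECAY_RANGE, size=P)

    # shrink edge weights (not the decay) until the dynamics are stable
    for _ in range(200):
        radius = np.max(
            np.abs(np.linalg.eigvals(np.diag(decay) + weights.T))
        )
        if radius < _STABILITY_RADIUS:
            break
        weights = weights * 0.9
    return GroundTruthNetwork(weights=weights, decay=decay)


def simulate_timecourse(
    net: GroundTruthNetwork,
    n_replicates: int = 5,
    T: int = 21,
    noise_sd: float = 0.05,
    perturb_fraction: float = 1 / 3,
    perturb_duration: int = 10,
    seed: int = 0,
) -> TimeCourseDataset:
    """Simulate replicate time courses under transient perturbations.

    Each replicate perturbs a fresh random subset of about
    ``perturb_fraction`` of the genes with a signed additive offset
    (magnitude uniform on [0.5, 1.0]) held for the first
    ``perturb_duration`` time points and removed afterwards.  Trajectories
    start at the perturbation offsets and evolve by the network's linear
    lag-1 dynamics with i.i.d. Gaussian noise at every time point.
    """
    if T < 2:
        raise ValueError("need at least 2 time points per replicate")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 <= perturb_fraction <= 1:
        raise ValueError("perturb_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = net.n_genes
    M = net.transition_matrix()
    n_perturbed = int(round(perturb_fraction * p))

    blocks = []
    for _ in range(n_replicates):
        offsets = np.zeros(p)
        if n_perturbed > 0:
            chosen = rng.choice(p, size=n_perturbed, replace=False)
            offsets[chosen] = rng.choice([-1.0, 1.0], size=n_perturbed) * rng.uniform(
                *_PERTURB_RANGE, size=n_perturbed
            )
        block = np.empty((T, p))
        block[0] = offsets + noise_sd * rng.standard_normal(p)
        for t in range(T - 1):
            forcing = offsets if (t + 1) < perturb_duration else 0.0
            block[t + 1] = (
                M @ block[t] + forcing + noise_sd * rng.standard_normal(p)
            )
        blocks.append(block)

    return TimeCourseDataset(gene_names=net.gene_names(), replicates=blocks)
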