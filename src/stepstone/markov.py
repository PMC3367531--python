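"""Continuous-time Markov model over a stepping-stone network.

Off-diagonal K[A, B] is the analytic jump rate A -> B (units of the
mutation-rate prefactor mu); diagonals make rows sum to zero.  Row
distributions act from the left: p(t) = p0 expm(K t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.linalg import expm, null_space

from .ratefit import RateSurfaceParams, log_rate
from .structgen import Structure, common_contacts

__all__ = [
    "MarkovNetwork",
    "build_rate_matrix",
    "stationary_distribution",
    "propagate",
    "global_balance_residual",
]


@dataclass
class MarkovNetwork:
    ids: list[str]
    K: np.ndarray
    pi: np.ndarray | None = None
    structures: list[Structure] | None = None

    @property
    def n_states(self) -> int:
        return len(self.ids)


def build_rate_matrix(
    structures: list[Structure],
    params: RateSurfaceParams,
    overlap=None,
) -> MarkovNetwork:
    """Generator matrix from the fitted rate family.

    ``overlap`` maps a structure pair to its shared-contact fraction q;
    default uses the structures' contact sets directly.
    """
    n = len(structures)
    if n < 2:
        raise ValueError("need at least two structures")
    if overlap is None:
        overlap = lambda a, b: common_contacts(a, b).q_frac
    K = np.zeros((n, n))
    for i, a in enumerate(structures):
        for j, b in enumerate(structures):
            if i == j:
                continue
            q = overlap(a, b)
            rate = float(
                np.exp(
                    log_rate(
                        params,
                        b.hb_energy - a.hb_energy,
                        b.n_contacts - a.n_contacts,
                        q,
                    )
                )
            )
            if not np.isfinite(rate):
                raise ValueError(f"non-finite rate for pair ({a.id}, {b.id})")
            K[i, j] = rate
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))
    net = MarkovNetwork(ids=[s.id for s in structures], K=K, structures=list(structures))
    net.pi = stationary_distribution(net)
    return net


def _component_stationary(K: np.ndarray) -> np.ndarray:
    ns = null_space(K.T)
    if ns.shape[1] == 0:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("no stationary vector found")
    # an irreducible generator has a one-dimensional, single-signed null space
    v = np.real(ns[:, 0])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def stationary_distribution(net: MarkovNetwork) -> np.ndarray:
    """pi solving pi K = 0, sum pi = 1, via a null-space solve.

    A disconnected network gets per-component stationary distributions,
    each normalized within its component and weighted equally, with a
    warning.
    """
    n = net.n_states
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and (net.K[i, j] > 0 or net.K[j, i] > 0):
                g.add_edge(i, j)
    comps = list(nx.connected_components(g))
    pi = np.zeros(n)
    if len(comps) > 1:
        warnings.warn(f"network is disconnected ({len(comps)} components)")
    for comp in comps:
        idx = np.asarray(sorted(comp))
        sub = net.K[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, 0.0)
        np.fill_diagonal(sub, -sub.sum(axis=1))
        pi[idx] = _component_stationary(sub) / len(comps)
    return pi


def propagate(net: MarkovNetwork, p0, times) -> np.ndarray:
    """p(t) = p0 expm(K t) for each requested time; rows are distributions."""
    p0 = np.asarray(p0, dtype=float)
    times = np.asarray(times, dtype=float)
    if p0.shape != (net.n_states,):
        raise ValueError("p0 must have one entry per state")
    if not np.isclose(p0.sum(), 1.0) or np.any(p0 < 0):
        raise ValueError("p0 must be a probability distribution")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    out = np.empty((len(times), net.n_states))
    for k, t in enumerate(times):
        out[k] = p0 @ expm(net.K * t)
    return out


def global_balance_residual(net: MarkovNetwork) -> tuple[np.ndarray, float]:
    """Per-state net-flux residuals sum_B (pi_A K_AB - pi_B K_BA) and the
    maximum detailed-balance violation max_AB |pi_A K_AB - pi_B K_BA|."""
    if net.pi is None:
        net.pi = stationary_distribution(net)
    K = net.K.copy()
    np.fill_diagonal(K, 0.0)
    flux = net.pi[:, None] * K
    residual = (flux - flux.T).sum(axis=1)
    violation = float(np.max(np.abs(flux - flux.T)))
    return residual, violation
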