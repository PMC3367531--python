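"""Committor-based transition rates between sequence islands.

The evolutionary jump rate from the island of structure A to that of B is
the Boltzmann-ensemble-A average of the committor indicator

    Lambda_AB(S) = 1  iff  E(S, B) < E(S, A)      (ties commit to neither)

i.e. the equilibrium fraction of A's sequences already committed to B.
Because committed sequences are exponentially rare, the average is taken
in the biased joint ensemble with weight

    exp(-[E_A(S) + E_B(S) - E_R ln N_perm(S)] / T)

whose samples concentrate near the committor surface, and is reweighted
back to the single-structure ensemble in log-space.  An exhaustive
enumeration oracle over tiny alphabets verifies the estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .energy import AMINO_ACIDS, N_RESIDUE_TYPES, InteractionMatrix, decode, encode, total_energy
from .structgen import Structure

__all__ = [
    "RateConfig",
    "JointSample",
    "JointSamples",
    "RateEstimate",
    "committor",
    "joint_acceptance",
    "sample_joint",
    "estimate_rate_constants",
    "estimate_rates_direct",
    "exact_rate_oracle",
    "relative_probabilities",
]

#: effective-sample-size threshold below which estimates are flagged
ESS_WARN_THRESHOLD = 100.0

#: numerical tie tolerance for the committor's Heaviside step.  Ties commit
#: to neither direction, and exactly tied energies (symmetric structure
#: pairs) accumulate O(1e-12) float drift under incremental updates, which
#: would otherwise flip the indicator at random.
TIE_TOL = 1e-9


def _committor_indicators(e_a, e_b):
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    tol = TIE_TOL * np.maximum(1.0, np.maximum(np.abs(e_a), np.abs(e_b)))
    lam_ab = e_b < e_a - tol
    lam_ba = e_a < e_b - tol
    return lam_ab.astype(int), lam_ba.astype(int)


@dataclass
class RateConfig:
    """Joint-ensemble sampling parameters (reduced units, k_B = 1).

    ``mu`` is the uniform mutation-rate prefactor converting rates per
    mutation attempt into absolute rates; 1 by default so rates are
    reported per attempt.
    """

    t: float = 1.0
    e_r: float = 2.0
    mu: float = 1.0
    n_samples: int = 10_000
    burn_in: int = 1_000
    rng_seed: int = 0
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        if self.t <= 0:
            raise ValueError("temperature must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.e_r < 0:
            raise ValueError("e_r must be non-negative")
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet needs at least two letters")


@dataclass(frozen=True)
class JointSample:
    sequence: str
    e_a: float
    e_b: float
    committed_ab: int
    committed_ba: int


class JointSamples:
    """Column-wise container of joint-ensemble samples."""

    def __init__(self, sequences, e_a, e_b):
        self.sequences = sequences
        self.e_a = np.asarray(e_a, dtype=float)
        self.e_b = np.asarray(e_b, dtype=float)
        self.lam_ab, self.lam_ba = _committor_indicators(self.e_a, self.e_b)

    def __len__(self) -> int:
        return len(self.e_a)

    def __getitem__(self, k: int) -> JointSample:
        return JointSample(
            sequence=self.sequences[k],
            e_a=float(self.e_a[k]),
            e_b=float(self.e_b[k]),
            committed_ab=int(self.lam_ab[k]),
            committed_ba=int(self.lam_ba[k]),
        )


@dataclass
class RateEstimate:
    """Rate constants per mutation attempt (dimensionless, in [0, 1])."""

    k_ab: float
    k_ba: float
    se_ab: float
    se_ba: float
    n_effective_a: float
    n_effective_b: float
    low_ess: bool = False
    r_ratio: float | None = None
    extras: dict = field(default_factory=dict)


def committor(seq: str, a: Structure, b: Structure, m: InteractionMatrix) -> tuple[int, int]:
    """(Lambda_AB, Lambda_BA); ties yield (0, 0)."""
    e_a = total_energy(seq, a, m)
    e_b = total_energy(seq, b, m)
    lam_ab, lam_ba = _committor_indicators([e_a], [e_b])
    return int(lam_ab[0]), int(lam_ba[0])


def joint_acceptance(de_a: float, de_b: float, d_log_nperm: float, cfg: RateConfig) -> float:
    """Metropolis rule for the effective two-structure system E_A + E_B
    with the permutation (anti-homopolymer) term."""
    if cfg.t <= 0:
        raise ValueError("temperature must be positive")
    arg = -(de_a + de_b - cfg.e_r * d_log_nperm) / cfg.t
    return 1.0 if arg >= 0 else float(np.exp(arg))


def sample_joint(a: Structure, b: Structure, m: InteractionMatrix, cfg: RateConfig) -> JointSamples:
    """Markov chain over sequences with stationary weight proportional to
    exp(-[E_A + E_B - E_R ln N_perm]/T); one sample per proposal after
    burn-in; deterministic given the seed."""
    if a.length != b.length:
        raise ValueError("structures must share one length")
    rng = np.random.default_rng(cfg.rng_seed)
    alpha_codes = encode(cfg.alphabet)
    n_letters = len(alpha_codes)
    nbrs_a = a.neighbors()
    nbrs_b = b.neighbors()
    eps = m.eps
    length = a.length

    codes = alpha_codes[rng.integers(n_letters, size=length)]
    counts = np.bincount(codes, minlength=N_RESIDUE_TYPES)
    e_a = _contact_energy(codes, nbrs_a, eps) + a.hb_energy
    e_b = _contact_energy(codes, nbrs_b, eps) + b.hb_energy

    n_total = cfg.burn_in + cfg.n_samples
    seqs: list[str] = []
    out_a = np.empty(cfg.n_samples)
    out_b = np.empty(cfg.n_samples)
    for step in range(n_total):
        site = int(rng.integers(length))
        old = codes[site]
        new = int(alpha_codes[rng.integers(n_letters)])
        if new != old:
            pa = nbrs_a[site]
            pb = nbrs_b[site]
            de_a = float(np.sum(eps[new, codes[pa]]) - np.sum(eps[old, codes[pa]])) if pa.size else 0.0
            de_b = float(np.sum(eps[new, codes[pb]]) - np.sum(eps[old, codes[pb]])) if pb.size else 0.0
            dlnp = float(np.log(counts[old]) - np.log(counts[new] + 1))
            arg = -(de_a + de_b - cfg.e_r * dlnp) / cfg.t
            if arg >= 0 or rng.random() < np.exp(arg):
                codes[site] = new
                counts[old] -= 1
                counts[new] += 1
                e_a += de_a
                e_b += de_b
        if step >= cfg.burn_in:
            k = step - cfg.burn_in
            out_a[k] = e_a
            out_b[k] = e_b
            seqs.append(decode(codes))
    return JointSamples(seqs, out_a, out_b)


def _contact_energy(codes, nbrs, eps) -> float:
    e = 0.0
    for i, part in enumerate(nbrs):
        if part.size:
            e += float(np.sum(eps[codes[i], codes[part]]))
    return 0.5 * e


def _reweighted_mean(indicator, log_w) -> tuple[float, float]:
    """Self-normalized importance-sampling mean and its ESS, in log-space."""
    shift = log_w - np.max(log_w)
    w = np.exp(shift)
    total = w.sum()
    mean = float(np.dot(indicator, w) / total)
    ess = float(total**2 / np.dot(w, w))
    return mean, ess


def estimate_rate_constants(
    samples: JointSamples,
    cfg: RateConfig,
    n_blocks: int = 50,
    n_boot: int = 200,
) -> RateEstimate:
    """k_AB and k_BA with block-bootstrap standard errors.

    Reweighting from the joint ensemble to the single-structure ensemble of
    A multiplies each sample by exp(+E_B/T) (and symmetrically for B), so

        k_AB = <Lambda_AB e^{E_B/T}>_joint / <e^{E_B/T}>_joint
    """
    n = len(samples)
    if n == 0:
        raise ValueError("no samples")
    log_wb = samples.e_b / cfg.t  # removes B's Boltzmann factor -> ensemble A
    log_wa = samples.e_a / cfg.t
    k_ab, ess_a = _reweighted_mean(samples.lam_ab, log_wb)
    k_ba, ess_b = _reweighted_mean(samples.lam_ba, log_wa)

    rng = np.random.default_rng(cfg.rng_seed + 1)
    n_blocks = min(n_blocks, n)
    bounds = np.linspace(0, n, n_blocks + 1, dtype=int)
    blocks = [slice(bounds[i], bounds[i + 1]) for i in range(n_blocks)]
    boots_ab = np.empty(n_boot)
    boots_ba = np.empty(n_boot)
    for r in range(n_boot):
        pick = rng.integers(n_blocks, size=n_blocks)
        idx = np.concatenate([np.arange(blocks[p].start, blocks[p].stop) for p in pick])
        boots_ab[r], _ = _reweighted_mean(samples.lam_ab[idx], log_wb[idx])
        boots_ba[r], _ = _reweighted_mean(samples.lam_ba[idx], log_wa[idx])

    return RateEstimate(
        k_ab=cfg.mu * k_ab,
        k_ba=cfg.mu * k_ba,
        se_ab=cfg.mu * float(np.std(boots_ab, ddof=1)),
        se_ba=cfg.mu * float(np.std(boots_ba, ddof=1)),
        n_effective_a=ess_a,
        n_effective_b=ess_b,
        low_ess=min(ess_a, ess_b) < ESS_WARN_THRESHOLD,
    )


def _committor_chain(
    x: Structure,
    other: Structure,
    m: InteractionMatrix,
    cfg: RateConfig,
    rng_seed: int,
) -> np.ndarray:
    """Committor indicator trace along a Metropolis chain in the single
    ensemble of ``x`` (weight exp(-[E_x - E_R ln N_perm]/T))."""
    rng = np.random.default_rng(rng_seed)
    alpha_codes = encode(cfg.alphabet)
    n_letters = len(alpha_codes)
    nb_x = x.neighbors()
    nb_o = other.neighbors()
    eps = m.eps
    length = x.length
    codes = alpha_codes[rng.integers(n_letters, size=length)]
    counts = np.bincount(codes, minlength=N_RESIDUE_TYPES)
    e_x = _contact_energy(codes, nb_x, eps) + x.hb_energy
    e_o = _contact_energy(codes, nb_o, eps) + other.hb_energy
    lam = np.empty(cfg.n_samples, dtype=np.int8)
    for step in range(cfg.burn_in + cfg.n_samples):
        site = int(rng.integers(length))
        old = codes[site]
        new = int(alpha_codes[rng.integers(n_letters)])
        if new != old:
            px, po = nb_x[site], nb_o[site]
            de_x = float(np.sum(eps[new, codes[px]]) - np.sum(eps[old, codes[px]])) if px.size else 0.0
            de_o = float(np.sum(eps[new, codes[po]]) - np.sum(eps[old, codes[po]])) if po.size else 0.0
            dlnp = float(np.log(counts[old]) - np.log(counts[new] + 1))
            arg = -(de_x - cfg.e_r * dlnp) / cfg.t
            if arg >= 0 or rng.random() < np.exp(arg):
                codes[site] = new
                counts[old] -= 1
                counts[new] += 1
                e_x += de_x
                e_o += de_o
        if step >= cfg.burn_in:
            tol = TIE_TOL * max(1.0, abs(e_x), abs(e_o))
            lam[step - cfg.burn_in] = 1 if e_o < e_x - tol else 0
    return lam


def estimate_rates_direct(
    a: Structure,
    b: Structure,
    m: InteractionMatrix,
    cfg: RateConfig,
    n_blocks: int = 25,
) -> RateEstimate:
    """k_AB and k_BA by direct sampling of each island's own ensemble.

    k_AB is the equilibrium fraction of A's designed ensemble already
    committed to B — the defining average — estimated as the committor
    indicator mean along a chain sampling A's ensemble (and symmetrically
    for B).  No reweighting: preferable whenever the committed fractions
    are large enough to observe directly, where it avoids the effective-
    sample-size collapse of the biased joint-ensemble route.  Block means
    give the standard errors.
    """
    if a.length != b.length:
        raise ValueError("structures must share one length")
    out = {}
    for tag, (x, other) in (("ab", (a, b)), ("ba", (b, a))):
        lam = _committor_chain(x, other, m, cfg, cfg.rng_seed + (0 if tag == "ab" else 1))
        k = float(lam.mean())
        blocks = np.array([blk.mean() for blk in np.array_split(lam, n_blocks)])
        se = float(blocks.std(ddof=1) / np.sqrt(n_blocks))
        out[tag] = (k, se, float(len(lam)))
    return RateEstimate(
        k_ab=cfg.mu * out["ab"][0],
        k_ba=cfg.mu * out["ba"][0],
        se_ab=cfg.mu * out["ab"][1],
        se_ba=cfg.mu * out["ba"][1],
        n_effective_a=out["ab"][2],
        n_effective_b=out["ba"][2],
        low_ess=False,
    )


def exact_rate_oracle(
    a: Structure,
    b: Structure,
    m: InteractionMatrix,
    cfg: RateConfig,
    alphabet: str | None = None,
    max_states: int = 10_000_000,
) -> tuple[float, float]:
    """Exact k_AB, k_BA by full enumeration of the sequence space.

    Ensemble-A weights include the permutation term, matching what the
    Monte Carlo estimator converges to.  Testing utility only.
    """
    alphabet = alphabet or cfg.alphabet
    n_letters = len(alphabet)
    if n_letters**a.length > max_states:
        raise ValueError(
            f"state space {n_letters}^{a.length} exceeds the enumeration bound {max_states}"
        )
    log_wa = []
    log_wb = []
    lam_ab = []
    lam_ba = []
    codes_alpha = encode(alphabet)
    for combo in itertools.product(codes_alpha, repeat=a.length):
        seq = decode(np.asarray(combo))
        e_a = total_energy(seq, a, m)
        e_b = total_energy(seq, b, m)
        counts = np.bincount(np.asarray(combo), minlength=N_RESIDUE_TYPES)
        lnp = float(gammaln(a.length + 1) - gammaln(counts + 1).sum())
        log_wa.append(-(e_a - cfg.e_r * lnp) / cfg.t)
        log_wb.append(-(e_b - cfg.e_r * lnp) / cfg.t)
        ab, ba = _committor_indicators([e_a], [e_b])
        lam_ab.append(int(ab[0]))
        lam_ba.append(int(ba[0]))
    log_wa = np.asarray(log_wa)
    log_wb = np.asarray(log_wb)
    lam_ab = np.asarray(lam_ab, dtype=float)
    lam_ba = np.asarray(lam_ba, dtype=float)

    def avg(lam, log_w):
        denom = logsumexp(log_w)
        if not np.any(lam > 0):
            return 0.0
        return float(np.exp(logsumexp(log_w[lam > 0]) - denom))

    return cfg.mu * avg(lam_ab, log_wa), cfg.mu * avg(lam_ba, log_wb)


def relative_probabilities(
    rate_table: dict[tuple[str, str], tuple[float, float]],
    reference: str,
) -> tuple[dict[str, float], list[tuple[list[str], float]]]:
    """Relative equilibrium probabilities by rescaling rate ratios.

    ``rate_table`` maps ordered pairs (A, B) to (k_AB, k_BA).  Detailed
    balance gives P_B / P_A = k_AB / k_BA, propagated along a spanning tree
    from the reference (P_ref = 1).  Returns the probabilities and the
    per-cycle log-inconsistency residuals of the non-tree edges.
    """
    g = nx.Graph()
    for (u, v), (k_uv, k_vu) in rate_table.items():
        g.add_edge(u, v, log_ratio=None)
    if reference not in g:
        raise ValueError(f"reference {reference!r} not in the pair graph")
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(f"pair graph is disconnected: components {sorted(map(sorted, comps))}")

    def log_ratio(u: str, v: str) -> float:
        # log(P_v / P_u)
        if (u, v) in rate_table:
            k_uv, k_vu = rate_table[(u, v)]
        else:
            k_vu, k_uv = rate_table[(v, u)]
        if k_uv <= 0 or k_vu <= 0:
            raise ValueError(f"zero rate on pair ({u}, {v}); cannot rescale")
        return float(np.log(k_uv) - np.log(k_vu))

    tree = nx.minimum_spanning_tree(g)
    log_p = {reference: 0.0}
    for u, v in nx.bfs_edges(tree, reference):
        log_p[v] = log_p[u] + log_ratio(u, v)

    residuals: list[tuple[list[str], float]] = []
    for u, v in g.edges:
        if not tree.has_edge(u, v):
            res = log_p[u] + log_ratio(u, v) - log_p[v]
            cycle = nx.shortest_path(tree, v, u) + [v]
            residuals.append((cycle, float(res)))
    probs = {s: float(np.exp(lp)) for s, lp in log_p.items()}
    return probs, residuals
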