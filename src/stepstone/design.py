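"""Sequence design by Monte Carlo on a fixed target structure.

Single-point mutations are accepted with

    p = min{1, exp(-[dE - E_R * d ln N_perm] / T)}

which minimizes the target-structure energy while maximizing the
multinomial permutation count of the composition — the entropy
regularization that keeps designed populations away from homopolymers.
A replica-exchange ladder of design temperatures improves mixing; the
designed population attached to one structure is its "island".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .energy import AMINO_ACIDS, N_RESIDUE_TYPES, InteractionMatrix, decode, encode
from .structgen import Structure

__all__ = [
    "DesignConfig",
    "Island",
    "design_acceptance",
    "run_design",
    "site_entropy",
    "compare_entropy_distributions",
    "select_design_temperature",
    "free_energy_from_histogram",
]


@dataclass
class DesignConfig:
    """Design Monte Carlo parameters (reduced units, k_B = 1).

    ``e_r`` scales the permutation (sequence-entropy) term; ``ladder`` is a
    strictly increasing list of replica temperatures containing
    ``t_design``, the temperature whose replica is recorded.
    """

    t_design: float = 1.0
    e_r: float = 2.0
    n_sweeps: int = 200
    ladder: list[float] | None = None
    exchange_interval: int = 5
    rng_seed: int = 0
    burn_in_fraction: float = 0.1
    alphabet: str = AMINO_ACIDS

    def __post_init__(self):
        if self.t_design <= 0:
            raise ValueError("t_design must be positive")
        if self.e_r < 0:
            raise ValueError("e_r must be non-negative")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.ladder is None:
            self.ladder = [self.t_design]
        if any(b <= a for a, b in zip(self.ladder, self.ladder[1:])):
            raise ValueError("temperature ladder must be strictly increasing")
        if self.t_design not in self.ladder:
            raise ValueError("t_design must be a member of the ladder")
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet needs at least two letters")


@dataclass
class Island:
    """The designed sequence population of one stepping stone."""

    structure_id: str
    sequences: list[str]
    energies: list[float]
    temperature: float
    acceptance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)


def design_acceptance(de: float, d_log_nperm: float, t: float, e_r: float) -> float:
    """Acceptance probability of one design move."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    return float(min(1.0, np.exp(-(de - e_r * d_log_nperm) / t)))


class _Replica:
    """Mutable sampler state on one structure at one temperature."""

    __slots__ = ("codes", "counts", "energy", "log_nperm", "t")

    def __init__(self, codes, counts, energy, log_nperm, t):
        self.codes = codes
        self.counts = counts
        self.energy = energy
        self.log_nperm = log_nperm
        self.t = t


def _contact_energy(codes, nbrs, eps) -> float:
    e = 0.0
    for i, part in enumerate(nbrs):
        if part.size:
            e += float(np.sum(eps[codes[i], codes[part]]))
    return 0.5 * e  # each contact visited from both ends


def _log_nperm_counts(counts) -> float:
    n = int(counts.sum())
    return float(gammaln(n + 1) - gammaln(counts + 1).sum())


def run_design(x: Structure, m: InteractionMatrix, cfg: DesignConfig) -> Island:
    """Replica-exchange design Monte Carlo; deterministic given the seed.

    One sweep is ``length`` single-site proposals per replica; neighboring
    replicas attempt a swap every ``exchange_interval`` sweeps with the
    standard exchange rule on the generalized energy E - E_R ln N_perm.
    One sequence per sweep is recorded from the ``t_design`` replica after
    a burn-in fraction of the run.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    alpha_codes = encode(cfg.alphabet)
    n_letters = len(alpha_codes)
    nbrs = x.neighbors()
    eps = m.eps
    e_r = cfg.e_r

    replicas = []
    for t in cfg.ladder:
        codes = alpha_codes[rng.integers(n_letters, size=x.length)]
        counts = np.bincount(codes, minlength=N_RESIDUE_TYPES)
        energy = _contact_energy(codes, nbrs, eps) + x.hb_energy
        replicas.append(_Replica(codes, counts, energy, _log_nperm_counts(counts), t))
    record_idx = cfg.ladder.index(cfg.t_design)

    burn = int(cfg.burn_in_fraction * cfg.n_sweeps)
    sequences: list[str] = []
    energies: list[float] = []
    n_prop = 0
    n_acc = 0
    n_swap_acc = 0
    n_swap = 0

    for sweep in range(cfg.n_sweeps):
        for rep in replicas:
            for _ in range(x.length):
                site = int(rng.integers(x.length))
                old = rep.codes[site]
                new = int(alpha_codes[rng.integers(n_letters)])
                if new == old:
                    continue
                part = nbrs[site]
                de = float(np.sum(eps[new, rep.codes[part]]) - np.sum(eps[old, rep.codes[part]])) if part.size else 0.0
                dlnp = float(np.log(rep.counts[old]) - np.log(rep.counts[new] + 1))
                n_prop += 1
                if de - e_r * dlnp <= 0 or rng.random() < np.exp(-(de - e_r * dlnp) / rep.t):
                    rep.codes[site] = new
                    rep.counts[old] -= 1
                    rep.counts[new] += 1
                    rep.energy += de
                    rep.log_nperm += dlnp
                    n_acc += 1
        if len(replicas) > 1 and (sweep + 1) % cfg.exchange_interval == 0:
            k = int(rng.integers(len(replicas) - 1))
            lo, hi = replicas[k], replicas[k + 1]
            g_lo = lo.energy - e_r * lo.log_nperm
            g_hi = hi.energy - e_r * hi.log_nperm
            ln_p = (1.0 / lo.t - 1.0 / hi.t) * (g_lo - g_hi)
            n_swap += 1
            if ln_p >= 0 or rng.random() < np.exp(ln_p):
                lo.codes, hi.codes = hi.codes, lo.codes
                lo.counts, hi.counts = hi.counts, lo.counts
                lo.energy, hi.energy = hi.energy, lo.energy
                lo.log_nperm, hi.log_nperm = hi.log_nperm, lo.log_nperm
                n_swap_acc += 1
        if sweep >= burn:
            rep = replicas[record_idx]
            sequences.append(decode(rep.codes))
            energies.append(rep.energy)

    return Island(
        structure_id=x.id,
        sequences=sequences,
        energies=energies,
        temperature=cfg.t_design,
        acceptance={
            "proposals": n_prop,
            "accepted": n_acc,
            "swap_attempts": n_swap,
            "swaps_accepted": n_swap_acc,
        },
    )


def site_entropy(island: Island) -> np.ndarray:
    """Per-site Shannon entropy S_i (nats) of the island's population."""
    if not island.sequences:
        raise ValueError("empty island")
    arr = np.stack([encode(s) for s in island.sequences])
    n_seq, length = arr.shape
    s = np.empty(length)
    for i in range(length):
        p = np.bincount(arr[:, i], minlength=N_RESIDUE_TYPES) / n_seq
        p = p[p > 0]
        s[i] = -np.sum(p * np.log(p))
    return s


def compare_entropy_distributions(profile, reference, bins=None) -> float:
    """Total-variation-style distance between the histograms of two
    per-site entropy profiles; 0 iff identical histograms, at most 2."""
    profile = np.asarray(profile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if profile.size == 0 or reference.size == 0:
        raise ValueError("empty entropy profile")
    if bins is None:
        bins = np.linspace(0.0, np.log(N_RESIDUE_TYPES), 21)
    hp, _ = np.histogram(profile, bins=bins)
    hr, _ = np.histogram(reference, bins=bins)
    return float(np.abs(hp / hp.sum() - hr / hr.sum()).sum())


def select_design_temperature(
    x: Structure,
    m: InteractionMatrix,
    cfg: DesignConfig,
    reference,
) -> tuple[float, dict[float, float]]:
    """Ladder member whose designed population's site-entropy histogram is
    closest to a reference profile (e.g. one from a natural alignment)."""
    scores: dict[float, float] = {}
    for t in cfg.ladder:
        sub = DesignConfig(
            t_design=t,
            e_r=cfg.e_r,
            n_sweeps=cfg.n_sweeps,
            ladder=[t],
            exchange_interval=cfg.exchange_interval,
            rng_seed=cfg.rng_seed,
            burn_in_fraction=cfg.burn_in_fraction,
            alphabet=cfg.alphabet,
        )
        island = run_design(x, m, sub)
        scores[t] = compare_entropy_distributions(site_entropy(island), reference)
    best = min(scores, key=scores.get)
    return best, scores


def free_energy_from_histogram(hist, t: float) -> np.ndarray:
    """F(Q) = -T ln H(Q) per bin, shifted so min F = 0; empty bins NaN."""
    h = np.asarray(hist, dtype=float)
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if not np.any(h > 0):
        raise ValueError("histogram has no occupied bin")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = -t * np.log(h)
    f = np.where(h > 0, f, np.nan)
    return f - np.nanmin(f)
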