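"""Fixed-backbone contact energetics and the sequence-permutation term.

The energy of a sequence threaded onto a structure X is

    E(S, X) = sum over contacts (i, j) of X of eps[s_i][s_j]  +  E_HB(X)

with a symmetric 20x20 residue interaction matrix eps (reduced units,
k_B = 1) and the structure's sequence-independent hydrogen-bond energy.
The multinomial permutation count N_perm = N! / prod_k n_k! measures the
compositional heterogeneity of a sequence; its natural log enters the
design and joint-sampling acceptance rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
from scipy.special import gammaln

from .structgen import Structure

__all__ = [
    "AMINO_ACIDS",
    "N_RESIDUE_TYPES",
    "InteractionMatrix",
    "default_matrix",
    "encode",
    "decode",
    "composition",
    "total_energy",
    "mutation_delta",
    "log_n_perm",
    "delta_log_n_perm",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUE_TYPES = 20
_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric 20x20 residue-pair interaction energies (reduced units)."""

    eps: np.ndarray

    def __post_init__(self):
        eps = np.asarray(self.eps, dtype=float)
        if eps.shape != (N_RESIDUE_TYPES, N_RESIDUE_TYPES):
            raise ValueError("interaction matrix must be 20x20")
        if not np.all(np.isfinite(eps)):
            raise ValueError("interaction matrix entries must be finite")
        if not np.allclose(eps, eps.T):
            raise ValueError("interaction matrix must be symmetric")
        object.__setattr__(self, "eps", eps)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.eps[_INDEX[a], _INDEX[b]])

    @classmethod
    def from_text(cls, text: str) -> "InteractionMatrix":
        """Whitespace-delimited 20x20 table with a header row of one-letter
        codes; rows may carry a leading letter code.  Lines starting with
        '#' are comments."""
        rows = [ln.split() for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
        header = rows[0]
        if len(header) != N_RESIDUE_TYPES or set(header) != set(AMINO_ACIDS):
            raise ValueError("header must list the 20 one-letter amino-acid codes")
        order = [_INDEX[a] for a in header]
        eps = np.empty((N_RESIDUE_TYPES, N_RESIDUE_TYPES))
        body = rows[1:]
        if len(body) != N_RESIDUE_TYPES:
            raise ValueError("expected 20 data rows")
        for r, fields in enumerate(body):
            if len(fields) == N_RESIDUE_TYPES + 1:
                row_letter, values = fields[0], fields[1:]
                ri = _INDEX[row_letter]
            elif len(fields) == N_RESIDUE_TYPES:
                values, ri = fields, order[r]
            else:
                raise ValueError(f"row {r} has {len(fields)} fields")
            for c, v in enumerate(values):
                eps[ri, order[c]] = float(v)
        return cls(eps=eps)

    def to_text(self) -> str:
        buf = StringIO()
        buf.write(" ".join(AMINO_ACIDS) + "\n")
        for k, a in enumerate(AMINO_ACIDS):
            buf.write(a + " " + " ".join(f"{v:.4f}" for v in self.eps[k]) + "\n")
        return buf.getvalue()


def default_matrix() -> InteractionMatrix:
    """The bundled default interaction table (hydrophobicity-derived)."""
    text = resources.files("stepstone.data").joinpath("default_matrix.txt").read_text()
    return InteractionMatrix.from_text(text)


def encode(seq: str) -> np.ndarray:
    """Letters -> integer codes 0..19."""
    try:
        return np.array([_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"unknown amino-acid letter {exc.args[0]!r}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[k] for k in codes)


def composition(seq: str) -> np.ndarray:
    """Counts n_1..n_20 in the fixed alphabet order."""
    return np.bincount(encode(seq), minlength=N_RESIDUE_TYPES)


def total_energy(seq: str, x: Structure, m: InteractionMatrix) -> float:
    """Contact energy plus the structure's hydrogen-bond energy."""
    if len(seq) != x.length:
        raise ValueError(f"sequence length {len(seq)} != structure length {x.length}")
    codes = encode(seq)
    e = x.hb_energy
    for i, j in x.contacts:
        e += m.eps[codes[i], codes[j]]
    return float(e)


def mutation_delta(seq: str, site: int, new_letter: str, x: Structure, m: InteractionMatrix) -> float:
    """Energy change of a single substitution, touching only contacts
    incident to ``site``.  Equals the difference of full recomputes."""
    if not 0 <= site < x.length:
        raise ValueError(f"site {site} out of range")
    codes = encode(seq)
    new = _INDEX.get(new_letter)
    if new is None:
        raise ValueError(f"unknown amino-acid letter {new_letter!r}")
    old = codes[site]
    if new == old:
        return 0.0
    partners = [j for i, j in x.contacts if i == site] + [i for i, j in x.contacts if j == site]
    if not partners:
        return 0.0
    pc = codes[np.asarray(partners)]
    return float(np.sum(m.eps[new, pc]) - np.sum(m.eps[old, pc]))


def log_n_perm(seq_or_counts) -> float:
    """ln N_perm = ln N! - sum_k ln n_k!, via log-gamma."""
    if isinstance(seq_or_counts, str):
        counts = composition(seq_or_counts)
    else:
        counts = np.asarray(seq_or_counts)
    n = int(counts.sum())
    return float(gammaln(n + 1) - gammaln(counts + 1).sum())


def delta_log_n_perm(counts: np.ndarray, old: int, new: int) -> float:
    """Change of ln N_perm when one residue of type ``old`` becomes type
    ``new``: ln(n_old) - ln(n_new + 1)."""
    if old == new:
        return 0.0
    return float(np.log(counts[old]) - np.log(counts[new] + 1))
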