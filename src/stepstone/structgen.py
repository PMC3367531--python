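"""Stepping-stone structures as contact maps with hydrogen-bond counts.

A structure is reduced to the data the rate theory consumes: the set of
residue-residue contacts (N_c of them) and the hydrogen-bond count whose
energy E_HB = -eps_HB * n_hbonds enters every sequence's energy as a
sequence-independent offset.  Synthetic structures are generated from a
secondary-structure string: helices contribute their backbone H-bonds and
local (i, i+3)/(i, i+4) contacts, adjacent strands pair antiparallel in
chain order, and additional long-range contacts are drawn uniformly at
random up to a requested compactness.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .sspath import parse_elements

__all__ = [
    "Structure",
    "ContactOverlap",
    "synth_structure",
    "secondary_structure_contacts",
    "common_contacts",
    "contacts_from_coords",
    "drmsd",
]

#: minimum sequence separation |j - i| for a pair to count as a contact
MIN_SEPARATION = 3

#: default Calpha cutoff in Angstrom (strict '<')
DEFAULT_CUTOFF = 8.0


@dataclass(frozen=True)
class Structure:
    """A stepping stone: contact set plus hydrogen-bond bookkeeping."""

    id: str
    length: int
    ss: str
    contacts: frozenset[tuple[int, int]]
    n_hbonds: int
    eps_hb: float = 1.0

    def __post_init__(self):
        for i, j in self.contacts:
            if not (0 <= i < j < self.length):
                raise ValueError(f"contact ({i}, {j}) out of range for length {self.length}")
            if j - i < MIN_SEPARATION:
                raise ValueError(f"contact ({i}, {j}) closer than {MIN_SEPARATION} in sequence")
        if self.n_hbonds < 0:
            raise ValueError("n_hbonds must be non-negative")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def hb_energy(self) -> float:
        """E_HB = -eps_HB * n_hbonds, in reduced units (always <= 0)."""
        return -self.eps_hb * self.n_hbonds

    def neighbors(self) -> list[np.ndarray]:
        """Contact partners per site, for incremental energy updates."""
        nbr: list[list[int]] = [[] for _ in range(self.length)]
        for i, j in self.contacts:
            nbr[i].append(j)
            nbr[j].append(i)
        return [np.asarray(sorted(p), dtype=np.intp) for p in nbr]

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "length": self.length,
                "ss": self.ss,
                "contacts": sorted(map(list, self.contacts)),
                "n_hbonds": self.n_hbonds,
                "eps_hb": self.eps_hb,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Structure":
        d = json.loads(text)
        return cls(
            id=d["id"],
            length=d["length"],
            ss=d["ss"],
            contacts=frozenset((int(i), int(j)) for i, j in d["contacts"]),
            n_hbonds=int(d["n_hbonds"]),
            eps_hb=float(d.get("eps_hb", 1.0)),
        )


@dataclass(frozen=True)
class ContactOverlap:
    """Shared contacts between two structures: count Q and symmetric fraction q."""

    q_count: int
    q_frac: float
    frac_vs_a: float = field(default=0.0)
    frac_vs_b: float = field(default=0.0)


def secondary_structure_contacts(ss: str, pair_hbond: bool = True):
    """Deterministic contacts and H-bond count implied by an SS string.

    Helices of length l contribute l-4 hydrogen bonds and the local
    (i, i+3), (i, i+4) contacts within the run; adjacent strands (in chain
    order) pair antiparallel, each aligned residue pair contributing one
    hydrogen bond (if ``pair_hbond``) and one cross contact.
    """
    contacts: set[tuple[int, int]] = set()
    n_hb = 0
    elements = parse_elements(ss)
    for el in elements:
        if el.kind == "H":
            n_hb += max(el.length - 4, 0)
            for i in range(el.start, el.end - 3):
                contacts.add((i, i + 3))
            for i in range(el.start, el.end - 4):
                contacts.add((i, i + 4))
    strands = [el for el in elements if el.kind == "E"]
    for a, b in itertools.pairwise(strands):
        m = min(a.length, b.length)
        for t in range(m):
            i, j = a.start + t, b.end - 1 - t
            lo, hi = min(i, j), max(i, j)
            if hi - lo >= MIN_SEPARATION:
                contacts.add((lo, hi))
            if pair_hbond:
                n_hb += 1
    return contacts, n_hb


def synth_structure(
    ss: str,
    target_contacts: int | None = None,
    *,
    pair_hbond: bool = True,
    eps_hb: float = 1.0,
    rng_seed: int = 0,
    id: str | None = None,
) -> Structure:
    """Synthetic stepping stone from an SS string.

    The deterministic secondary-structure contacts form the floor; extra
    long-range contacts are added uniformly at random (seeded) until
    ``target_contacts`` is reached exactly.  ``target_contacts=None`` keeps
    the floor.  Reproducible given the seed.
    """
    n = len(ss)
    contacts, n_hb = secondary_structure_contacts(ss, pair_hbond=pair_hbond)
    if target_contacts is None:
        target_contacts = len(contacts)
    if target_contacts < len(contacts):
        raise ValueError(
            f"target_contacts={target_contacts} below the {len(contacts)} contacts implied by the SS string"
        )
    all_pairs = [
        (i, j) for i in range(n) for j in range(i + MIN_SEPARATION, n)
    ]
    if target_contacts > len(all_pairs):
        raise ValueError(
            f"target_contacts={target_contacts} exceeds the {len(all_pairs)} admissible pairs"
        )
    rng = np.random.default_rng(rng_seed)
    free = [p for p in all_pairs if p not in contacts]
    extra = target_contacts - len(contacts)
    if extra:
        chosen = rng.choice(len(free), size=extra, replace=False)
        contacts.update(free[k] for k in chosen)
    return Structure(
        id=id or f"synth-{rng_seed}",
        length=n,
        ss=ss,
        contacts=frozenset(contacts),
        n_hbonds=n_hb,
        eps_hb=eps_hb,
    )


def common_contacts(a: Structure, b: Structure) -> ContactOverlap:
    """Shared-contact count Q and symmetric fraction q = 2Q/(N_c^A + N_c^B)."""
    if a.length != b.length:
        raise ValueError("structures must share one length")
    q_count = len(a.contacts & b.contacts)
    denom = a.n_contacts + b.n_contacts
    q_frac = 2.0 * q_count / denom if denom else 0.0
    return ContactOverlap(
        q_count=q_count,
        q_frac=q_frac,
        frac_vs_a=q_count / a.n_contacts if a.n_contacts else 0.0,
        frac_vs_b=q_count / b.n_contacts if b.n_contacts else 0.0,
    )


def contacts_from_coords(coords, cutoff: float = DEFAULT_CUTOFF) -> frozenset[tuple[int, int]]:
    """Contacts from Calpha coordinates: Euclidean distance strictly below
    ``cutoff`` (Angstrom) and sequence separation >= 3."""
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 4:
        raise ValueError("coordinates must be an (n >= 4, 3) array")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = squareform(pdist(xyz))
    n = len(xyz)
    return frozenset(
        (i, j)
        for i in range(n)
        for j in range(i + MIN_SEPARATION, n)
        if dist[i, j] < cutoff
    )


def drmsd(coords_x, coords_y) -> float:
    """Distance-matrix RMSD over all pairs i<j, in Angstrom; no superposition."""
    x = np.asarray(coords_x, dtype=float)
    y = np.asarray(coords_y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("coordinate arrays must share an (n >= 2, 3) shape")
    dx = pdist(x)
    dy = pdist(y)
    return float(np.sqrt(np.mean((dx - dy) ** 2)))
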