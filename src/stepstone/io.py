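"""Plain-text interchange: SS strings and islands as FASTA, structures as
JSON, rate tables as TSV, fitted parameters as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import Island
from .ratefit import RateObservation, RateSurfaceParams
from .sspath import SSPath
from .structgen import Structure

__all__ = [
    "read_ss",
    "write_ss",
    "write_path_fasta",
    "write_path_manifest",
    "write_island_fasta",
    "read_structure",
    "write_structure",
    "read_rate_table",
    "write_params",
    "read_params",
    "calpha_coords_from_pdb",
]


def read_ss(path) -> str:
    """One SS string from plain text or single-record FASTA."""
    text = Path(path).read_text().strip()
    if text.startswith(">"):
        records = list(SeqIO.parse(path, "fasta"))
        if len(records) != 1:
            raise ValueError(f"{path}: expected exactly one FASTA record")
        return str(records[0].seq)
    return "".join(text.split())


def write_ss(ss: str, path, name: str = "ss") -> None:
    SeqIO.write([SeqRecord(Seq(ss), id=name, description="")], path, "fasta")


def write_path_fasta(path_obj: SSPath, out) -> None:
    """One record per step, source first."""
    records = [
        SeqRecord(Seq(s), id=f"step-{k:03d}", description="")
        for k, s in enumerate(path_obj.states)
    ]
    SeqIO.write(records, out, "fasta")


def write_path_manifest(path_obj: SSPath, out) -> None:
    rows = [{"step": 0, "move": "start", "distance_to_target": path_obj.distances[0]}]
    for k, move in enumerate(path_obj.moves):
        rows.append(
            {
                "step": k + 1,
                "move": move.describe(),
                "distance_to_target": path_obj.distances[k + 1],
            }
        )
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)


def write_island_fasta(island: Island, out) -> None:
    records = [
        SeqRecord(
            Seq(s),
            id=f"{island.structure_id}|{k}",
            description=f"E={e:.4f} T={island.temperature}",
        )
        for k, (s, e) in enumerate(zip(island.sequences, island.energies))
    ]
    SeqIO.write(records, out, "fasta")


def read_structure(path) -> Structure:
    return Structure.from_json(Path(path).read_text())


def write_structure(s: Structure, path) -> None:
    Path(path).write_text(s.to_json())


def read_rate_table(path) -> list[RateObservation]:
    df = pd.read_csv(path, sep="\t")
    return [
        RateObservation(
            de_hb=row["de_hb"],
            dn_c=row["dn_c"],
            q=row["q"],
            k_ab=row["k_ab"],
            k_ba=row["k_ba"],
            se_ab=row.get("se_ab"),
            se_ba=row.get("se_ba"),
        )
        for _, row in df.iterrows()
    ]


def write_params(params: RateSurfaceParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1))


def read_params(path) -> RateSurfaceParams:
    return RateSurfaceParams(**json.loads(Path(path).read_text()))


def calpha_coords_from_pdb(path, chain: str | None = None):
    """Calpha coordinates (Angstrom) of one chain of a standard PDB file."""
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("x", str(path))[0]
    chains = list(model.get_chains())
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"chain {chain!r} not found")
    coords = []
    for residue in chains[0]:
        if "CA" in residue:
            coords.append(residue["CA"].coord)
    return coords
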