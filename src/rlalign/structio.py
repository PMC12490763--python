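"""Reading, writing and in-memory representation of protein structures.

Only backbone atoms (N, CA, C, O) are modelled anywhere in this package;
side chains present in input files are ignored.  Residues missing any of
the four backbone atoms are dropped at parse time and logged.  Internal
residue indexing is 0-based and contiguous per chain; the original author
numbering is retained only for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"


class StructureParseError(ValueError):
    """Raised when a file cannot be parsed into a usable structure."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns or keys."""


@dataclass
class Chain:
    """One polypeptide chain: sequence plus per-residue backbone coordinates.

    `backbone` has shape (T, 4, 3) with atoms ordered N, CA, C, O (Å).
    `author_numbering` keeps the (resseq, insertion-code) labels from the
    source file, if any, for reporting.
    """

    chain_id: str
    sequence: str
    backbone: np.ndarray
    author_numbering: list[tuple[int, str]] | None = None

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, dtype=float)
        if self.backbone.ndim != 3 or self.backbone.shape[1:] != (4, 3):
            raise ValueError("backbone must have shape (T, 4, 3)")
        if len(self.sequence) != self.backbone.shape[0]:
            raise ValueError(
                f"chain {self.chain_id}: sequence length {len(self.sequence)} "
                f"!= {self.backbone.shape[0]} backbone records"
            )
        if not np.all(np.isfinite(self.backbone)):
            raise ValueError(f"chain {self.chain_id}: non-finite coordinates")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"chain {self.chain_id}: invalid residues {bad}")

    def __len__(self) -> int:
        return self.backbone.shape[0]

    @property
    def ca(self) -> np.ndarray:
        """Cα coordinates, shape (T, 3)."""
        return self.backbone[:, 1, :]


@dataclass
class ProteinStructure:
    """A multi-chain backbone structure with per-chain sequences."""

    chains: list[Chain]
    source_id: str = ""

    def __post_init__(self):
        if not self.chains:
            raise ValueError("structure must contain at least one chain")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain identifiers in {ids}")

    @property
    def total_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.source_id!r}")

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        """(chain_id, residue_index) in chain order — the global residue order."""
        return [(c.chain_id, i) for c in self.chains for i in range(len(c))]

    def all_ca(self) -> np.ndarray:
        return np.concatenate([c.ca for c in self.chains], axis=0)

    def all_backbone(self) -> np.ndarray:
        return np.concatenate([c.backbone for c in self.chains], axis=0)

    def chain_index(self) -> np.ndarray:
        """Per-residue integer chain label in the global residue order."""
        return np.concatenate(
            [np.full(len(c), i, dtype=int) for i, c in enumerate(self.chains)]
        )


@dataclass
class ScoreTable:
    """Per-candidate numeric scores keyed by (complex_id, candidate_id)."""

    frame: pd.DataFrame = field(repr=False)

    KEYS = ("complex_id", "candidate_id")

    def __post_init__(self):
        missing = [k for k in self.KEYS if k not in self.frame.columns]
        if missing:
            raise SchemaError(
                f"score table missing key columns {missing}; "
                f"expected {list(self.KEYS)} plus numeric columns"
            )
        dup = self.frame.duplicated(subset=list(self.KEYS))
        if dup.any():
            bad = self.frame.loc[dup, list(self.KEYS)].iloc[0].tolist()
            raise SchemaError(f"duplicated (complex_id, candidate_id) key: {bad}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.KEYS]


def read_pdb(path, model_index: int = 0) -> ProteinStructure:
    """Parse backbone chains from a PDB file.

    Chains are returned in first-encountered order; altloc conflicts are
    resolved by highest occupancy (ties first-seen); HETATM records are
    ignored; unknown residue names map to 'X' with a warning; residues
    missing any of N/CA/C/O are dropped and logged.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
        if n_models == 0:
            raise StructureParseError(f"no models in {path}")
        atoms = pdb.get_structure(
            model=model_index + 1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except StructureParseError:
        raise
    except Exception as exc:
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc

    atoms = atoms[~atoms.hetero]
    atoms = atoms[np.isin(atoms.atom_name, BACKBONE_ATOMS)]
    if atoms.array_length() == 0:
        raise StructureParseError(f"no backbone ATOM records in {path}")

    chains: dict[str, dict] = {}
    order: list[str] = []
    # group by (chain, resseq, icode) preserving file order
    res_starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    for lo, hi in zip(res_starts[:-1], res_starts[1:]):
        res = atoms[lo:hi]
        cid = str(res.chain_id[0])
        resname = str(res.res_name[0])
        resseq = int(res.res_id[0])
        icode = str(res.ins_code[0]) if hasattr(res, "ins_code") else ""
        coords = {}
        for i in range(res.array_length()):
            name = str(res.atom_name[i])
            if name in BACKBONE_ATOMS and name not in coords:
                coords[name] = res.coord[i]
        if set(coords) != set(BACKBONE_ATOMS):
            logger.info(
                "dropping residue %s%d%s in chain %s of %s: missing backbone "
                "atoms %s", resname, resseq, icode, cid, path,
                sorted(set(BACKBONE_ATOMS) - set(coords)),
            )
            continue
        letter = _THREE_TO_ONE.get(resname)
        if letter is None:
            warnings.warn(
                f"unknown residue name {resname} in {path}; mapped to 'X'",
                stacklevel=2,
            )
            letter = "X"
        if cid not in chains:
            chains[cid] = {"seq": [], "xyz": [], "num": []}
            order.append(cid)
        chains[cid]["seq"].append(letter)
        chains[cid]["xyz"].append(np.stack([coords[a] for a in BACKBONE_ATOMS]))
        chains[cid]["num"].append((resseq, icode))

    built = [
        Chain(
            chain_id=cid,
            sequence="".join(chains[cid]["seq"]),
            backbone=np.stack(chains[cid]["xyz"]),
            author_numbering=chains[cid]["num"],
        )
        for cid in order
        if chains[cid]["seq"]
    ]
    if not built:
        raise StructureParseError(f"no complete backbone residues in {path}")
    import os

    return ProteinStructure(chains=built, source_id=os.path.basename(str(path)))


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write fixed-width v3.3 ATOM records (backbone only, occupancy 1.00)."""
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    lines = []
    serial = 1
    for chain in structure.chains:
        for i in range(len(chain)):
            resname = _ONE_TO_THREE[chain.sequence[i]]
            if chain.author_numbering is not None:
                resseq, icode = chain.author_numbering[i]
            else:
                resseq, icode = i + 1, ""
            for a, atom in enumerate(BACKBONE_ATOMS):
                x, y, z = chain.backbone[i, a]
                name_field = f" {atom:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{resname:>3s} "
                    f"{chain.chain_id:1s}{resseq:4d}{icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {elements[atom]:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {_ONE_TO_THREE[chain.sequence[-1]]:>3s} "
                     f"{chain.chain_id:1s}{len(chain):4d}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, upper-cased sequence), order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).strip().upper().replace(" ", "")
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_score_table(path) -> ScoreTable:
    """Read a TSV/CSV score table keyed by (complex_id, candidate_id).

    Values such as "NA" become missing; duplicate keys are rejected.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else None
    frame = pd.read_csv(path, sep=sep, engine="python", na_values=["NA", "na", ""])
    for col in frame.columns:
        if col not in ScoreTable.KEYS:
            try:
                frame[col] = pd.to_numeric(frame[col])
            except (ValueError, TypeError):
                pass  # leave non-numeric columns (e.g. labels) as-is
    return ScoreTable(frame=frame)


def write_score_table(table: ScoreTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
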