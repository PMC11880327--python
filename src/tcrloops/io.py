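"""PDB and gene-table input/output for IMGT-numbered TCR structures.

Structures are read and written through :mod:`gemmi`. The residue
sequence-number field is interpreted as the IMGT position and the
insertion-code field as the IMGT insertion code, the convention of STCRDab
and of deposited TCR prediction sets. Chain identity (which file chain is
the alpha / beta domain) always comes from an explicit ``chain_map`` — it
is never inferred from sequence content.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, NamedTuple, Optional

import gemmi
import pandas as pd

from .model import (
    BACKBONE_ATOMS,
    ChainStructure,
    ImgtResidue,
    IntegrityError,
    StructureError,
    TcrRecord,
)

logger = logging.getLogger(__name__)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
_ONE_TO_THREE["X"] = "UNK"
_ATOM_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def read_structure(
    path: str | Path,
    chain_map: Mapping[str, str],
    record_id: Optional[str] = None,
    model_index: int = 0,
) -> TcrRecord:
    """Read one paired TCR variable domain from a PDB file.

    ``chain_map`` maps file chain identifiers to chain kinds and must name
    at least an ``alpha`` and a ``beta`` chain. Files with several models
    expose one model at a time via ``model_index`` (copy selection is left
    to the caller). Missing backbone atoms are recorded as absent.
    """
    path = Path(path)
    logger.info("reading structure %s", path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unparseable PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"no models in {path}")
    try:
        model = structure[model_index]
    except IndexError:
        raise LookupError(f"{path} has no model index {model_index}")

    kinds = {kind: cid for cid, kind in chain_map.items()}
    if "alpha" not in kinds or "beta" not in kinds:
        raise StructureError("chain_map must name an alpha and a beta chain")

    chains: dict[str, ChainStructure] = {}
    for file_chain_id, chain_kind in chain_map.items():
        gchain = model.find_chain(file_chain_id)
        if gchain is None:
            raise LookupError(f"chain {file_chain_id!r} not found in {path}")
        chains[chain_kind] = _convert_chain(gchain, chain_kind)

    return TcrRecord(
        record_id=record_id or path.stem,
        alpha=chains["alpha"],
        beta=chains["beta"],
        source_tag=str(path),
    )


def _convert_chain(gchain: gemmi.Chain, chain_kind: str) -> ChainStructure:
    residues: list[ImgtResidue] = []
    seen: set[tuple[int, str]] = set()
    for gres in gchain:
        icode = gres.seqid.icode.strip()
        key = (gres.seqid.num, icode)
        if key in seen:
            raise IntegrityError(
                f"duplicate residue {gres.seqid.num}{icode} in chain {gchain.name}"
            )
        seen.add(key)
        backbone = {}
        for atom_name in BACKBONE_ATOMS:
            atom = gres.find_atom(atom_name, "*")
            backbone[atom_name] = (
                None if atom is None else [atom.pos.x, atom.pos.y, atom.pos.z]
            )
        residues.append(
            ImgtResidue(
                imgt_number=gres.seqid.num,
                insertion_code=icode,
                amino_acid=_THREE_TO_ONE.get(gres.name.upper(), "X"),
                backbone=backbone,
            )
        )
    return ChainStructure(chain_kind=chain_kind, residues=residues)


def write_structure(
    record: TcrRecord,
    path: str | Path,
    chain_ids: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a record as PDB; default chain ids A (alpha) and B (beta)."""
    path = Path(path)
    chain_ids = dict(chain_ids or {"alpha": "A", "beta": "B"})
    structure = gemmi.Structure()
    structure.name = record.record_id
    model = gemmi.Model("1")
    for chain_kind in ("alpha", "beta"):
        gchain = gemmi.Chain(chain_ids[chain_kind])
        for res in record.chain(chain_kind).residues:
            gres = gemmi.Residue()
            gres.name = _ONE_TO_THREE.get(res.amino_acid, "UNK")
            gres.seqid = gemmi.SeqId(res.imgt_number, res.insertion_code or " ")
            for atom_name in BACKBONE_ATOMS:
                coord = res.backbone.get(atom_name)
                if coord is None:
                    continue
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(_ATOM_ELEMENT[atom_name])
                atom.pos = gemmi.Position(*coord)
                atom.occ = 1.0
                gres.add_atom(atom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    structure.add_model(model)
    structure.setup_entities()
    logger.info("writing structure %s", path)
    structure.write_pdb(str(path))


class GeneAnnotation(NamedTuple):
    alpha_v: Optional[str]
    alpha_j: Optional[str]
    beta_v: Optional[str]
    beta_j: Optional[str]


GENE_TABLE_COLUMNS = ("record_id", "alpha_v", "alpha_j", "beta_v", "beta_j")


def read_gene_table(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read a record-id → (TRAV, TRAJ, TRBV, TRBJ) annotation CSV.

    Missing labels are allowed and returned as ``None``; duplicate record
    ids raise :class:`IntegrityError`.
    """
    path = Path(path)
    logger.info("reading gene table %s", path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise StructureError(f"gene table {path} missing columns {missing}")
    if frame["record_id"].duplicated().any():
        dupes = frame.loc[frame["record_id"].duplicated(), "record_id"].tolist()
        raise IntegrityError(f"duplicate record ids in gene table: {dupes}")
    table: dict[str, GeneAnnotation] = {}
    for row in frame.itertuples(index=False):
        table[row.record_id] = GeneAnnotation(
            *(None if pd.isna(getattr(row, c)) else getattr(row, c)
              for c in GENE_TABLE_COLUMNS[1:])
        )
    return table


def write_gene_table(annotations: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(rid, *ann) for rid, ann in annotations.items()],
        columns=list(GENE_TABLE_COLUMNS),
    )
    frame.to_csv(path, index=False)


def apply_gene_table(records: list[TcrRecord], annotations: Mapping[str, GeneAnnotation]) -> None:
    """Attach V/J gene labels from an annotation table to records in place."""
    for record in records:
        ann = annotations.get(record.record_id)
        if ann is None:
            continue
        record.alpha.v_gene, record.alpha.j_gene = ann.alpha_v, ann.alpha_j
        record.beta.v_gene, record.beta.j_gene = ann.beta_v, ann.beta_j
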