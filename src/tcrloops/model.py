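"""Core data model for IMGT-numbered TCR variable-domain structures.

The variable domain of each TCR chain is represented as an ordered list of
residues keyed by IMGT position and insertion code. Region definitions
(anchors and loops for CDR1-3) follow the IMGT convention used by STCRDab:

====== ==================== ==============
Region Anchor positions     Loop positions
====== ==================== ==============
CDR1   22-27, 39-44         28-38
CDR2   51-56, 66-71         57-65
CDR3   100-105, 118-123     106-117
====== ==================== ==============

CDR3 length variation is absorbed by insertion codes around positions
111/112: codes ascend after 111 (111, 111A, 111B, ...) and descend before
112 (..., 112B, 112A, 112).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CHAIN_KINDS = ("alpha", "beta", "heavy", "light")
REGION_NAMES = ("CDR1", "CDR2", "CDR3")

#: IMGT positions where insertion codes sort in descending order (the
#: C-terminal half of the CDR3 gap-filling scheme).
_DESCENDING_INSERTION_POSITIONS = frozenset({112})


class StructureError(ValueError):
    """Base class for structural-model errors."""


class IntegrityError(StructureError):
    """Duplicate or inconsistent residue records."""


class EmptyRegionError(StructureError):
    """A requested region contains no residues."""


def imgt_sort_key(imgt_number: int, insertion_code: str = "") -> tuple[int, int]:
    """Canonical IMGT ordering key for a (position, insertion code) pair.

    Insertion codes ascend at every position except 112, where they descend
    so that the sequence reads ... 111, 111A, 111B, 112B, 112A, 112 ...
    """
    icode = insertion_code.strip()
    rank = 0 if not icode else ord(icode.upper()) - ord("A") + 1
    if imgt_number in _DESCENDING_INSERTION_POSITIONS:
        rank = -rank
    return (imgt_number, rank)


@dataclass
class ImgtResidue:
    """One residue with IMGT position, insertion code and backbone atoms.

    ``backbone`` maps atom names (N, CA, C, O) to 3-vectors in Angstrom;
    an absent atom is stored as ``None``, never fabricated.
    """

    imgt_number: int
    insertion_code: str = ""
    amino_acid: str = "X"
    backbone: dict[str, Optional[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.imgt_number < 1:
            raise StructureError(f"IMGT number must be >= 1, got {self.imgt_number}")
        self.insertion_code = self.insertion_code.strip()
        aa = self.amino_acid.upper()
        if aa not in CANONICAL_AA and aa != "X":
            raise StructureError(f"non-canonical amino acid {self.amino_acid!r}")
        self.amino_acid = aa
        bb: dict[str, Optional[np.ndarray]] = {}
        for name in BACKBONE_ATOMS:
            coord = self.backbone.get(name)
            if coord is not None:
                coord = np.asarray(coord, dtype=float)
                if coord.shape != (3,) or not np.all(np.isfinite(coord)):
                    raise StructureError(
                        f"bad coordinate for atom {name} at {self.key_str()}"
                    )
            bb[name] = coord
        self.backbone = bb

    @property
    def key(self) -> tuple[int, str]:
        return (self.imgt_number, self.insertion_code)

    def key_str(self) -> str:
        return f"{self.imgt_number}{self.insertion_code}"

    @property
    def sort_key(self) -> tuple[int, int]:
        return imgt_sort_key(self.imgt_number, self.insertion_code)

    def has_complete_backbone(self) -> bool:
        return all(self.backbone.get(a) is not None for a in BACKBONE_ATOMS)

    def copy(self) -> "ImgtResidue":
        return ImgtResidue(
            self.imgt_number,
            self.insertion_code,
            self.amino_acid,
            {k: (None if v is None else v.copy()) for k, v in self.backbone.items()},
        )


@dataclass
class ChainStructure:
    """An IMGT-numbered variable-domain chain.

    Residues are kept in canonical IMGT order; duplicates by
    (position, insertion code) are rejected.
    """

    chain_kind: str
    residues: list[ImgtResidue]
    v_gene: Optional[str] = None
    j_gene: Optional[str] = None
    species_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chain_kind not in CHAIN_KINDS:
            raise StructureError(f"unknown chain kind {self.chain_kind!r}")
        self.residues = sorted(self.residues, key=lambda r: r.sort_key)
        seen: set[tuple[int, str]] = set()
        for res in self.residues:
            if res.key in seen:
                raise IntegrityError(
                    f"duplicate residue {res.key_str()} in {self.chain_kind} chain"
                )
            seen.add(res.key)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def residue_map(self) -> dict[tuple[int, str], ImgtResidue]:
        return {r.key: r for r in self.residues}

    def copy(self) -> "ChainStructure":
        return ChainStructure(
            self.chain_kind,
            [r.copy() for r in self.residues],
            self.v_gene,
            self.j_gene,
            self.species_tag,
        )


@dataclass
class TcrRecord:
    """A paired alpha/beta TCR variable-domain structure."""

    record_id: str
    alpha: ChainStructure
    beta: ChainStructure
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.alpha.chain_kind != "alpha" or self.beta.chain_kind != "beta":
            raise StructureError("TcrRecord requires an alpha and a beta chain")

    def chain(self, chain_kind: str) -> ChainStructure:
        if chain_kind == "alpha":
            return self.alpha
        if chain_kind == "beta":
            return self.beta
        raise LookupError(f"record {self.record_id} has no {chain_kind!r} chain")

    def copy(self) -> "TcrRecord":
        return TcrRecord(self.record_id, self.alpha.copy(), self.beta.copy(), self.source_tag)


@dataclass(frozen=True)
class RegionDefinition:
    region_name: str
    anchor_numbers: tuple[int, ...]
    loop_range: tuple[int, int]

    def loop_numbers(self) -> tuple[int, ...]:
        lo, hi = self.loop_range
        return tuple(range(lo, hi + 1))


REGIONS: dict[str, RegionDefinition] = {
    "CDR1": RegionDefinition("CDR1", tuple(range(22, 28)) + tuple(range(39, 45)), (28, 38)),
    "CDR2": RegionDefinition("CDR2", tuple(range(51, 57)) + tuple(range(66, 72)), (57, 65)),
    "CDR3": RegionDefinition("CDR3", tuple(range(100, 106)) + tuple(range(118, 124)), (106, 117)),
}

#: all IMGT positions covered by CDR loops; the framework is the complement
CDR_LOOP_POSITIONS = frozenset(
    n for region in REGIONS.values() for n in region.loop_numbers()
)


@dataclass
class LoopStructure:
    """One extracted CDR loop with its flanking anchor residues.

    ``degraded`` is set when any anchor backbone atom is absent; distance
    computations then fall back to the atoms present in both partners.
    """

    parent_id: str
    chain_kind: str
    region_name: str
    loop_residues: list[ImgtResidue]
    anchor_residues: list[ImgtResidue]
    v_gene: Optional[str] = None
    j_gene: Optional[str] = None
    degraded: bool = False

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.loop_residues)

    @property
    def loop_length(self) -> int:
        return len(self.loop_residues)

    @property
    def loop_id(self) -> str:
        return f"{self.parent_id}/{self.chain_kind}/{self.region_name}"


def extract_region(
    record_or_chain: TcrRecord | ChainStructure,
    chain_kind: Optional[str] = None,
    region_name: str = "CDR3",
) -> LoopStructure:
    """Extract a CDR loop and its anchors from a record or a bare chain.

    Loop residues are all residues whose IMGT position lies in the region's
    inclusive loop range (insertion codes included); anchors are the
    residues at the listed anchor positions. Raises
    :class:`EmptyRegionError` when no loop residue exists; a missing anchor
    backbone atom marks the loop as ``degraded`` rather than failing.
    """
    if isinstance(record_or_chain, TcrRecord):
        if chain_kind is None:
            raise StructureError("chain_kind required when extracting from a record")
        chain = record_or_chain.chain(chain_kind)
        parent_id = record_or_chain.record_id
    else:
        chain = record_or_chain
        parent_id = "chain"
        chain_kind = chain.chain_kind
    if region_name not in REGIONS:
        raise StructureError(f"unknown region {region_name!r}")
    region = REGIONS[region_name]
    lo, hi = region.loop_range
    anchor_set = set(region.anchor_numbers)
    loop = [r for r in chain.residues if lo <= r.imgt_number <= hi]
    anchors = [r for r in chain.residues if r.imgt_number in anchor_set]
    if not loop:
        raise EmptyRegionError(
            f"{parent_id}: no residues in {region_name} loop range {lo}-{hi}"
        )
    degraded = any(not r.has_complete_backbone() for r in anchors)
    return LoopStructure(
        parent_id=parent_id,
        chain_kind=chain_kind,
        region_name=region_name,
        loop_residues=[r.copy() for r in loop],
        anchor_residues=[r.copy() for r in anchors],
        v_gene=chain.v_gene,
        j_gene=chain.j_gene,
        degraded=degraded,
    )


def imgt_loop_numbering(region_name: str, length: int) -> list[tuple[int, str]]:
    """IMGT (position, insertion code) labels for a loop of given length.

    Short loops drop central positions symmetrically (N-terminal half gets
    the extra residue on odd lengths); loops longer than the nominal span
    gain insertion codes at the two central positions, ascending after the
    first pivot and descending before the second.
    """
    if length < 1:
        raise StructureError("loop length must be >= 1")
    region = REGIONS[region_name]
    lo, hi = region.loop_range
    span = hi - lo + 1
    if length <= span:
        front = math.ceil(length / 2)
        back = length - front
        numbers = [(n, "") for n in range(lo, lo + front)]
        numbers += [(n, "") for n in range(hi - back + 1, hi + 1)]
    else:
        extra = length - span
        pivot_a = lo + span // 2 - 1  # 111 for CDR3
        pivot_b = pivot_a + 1  # 112 for CDR3
        n_a = math.ceil(extra / 2)
        n_b = extra - n_a
        numbers = [(n, "") for n in range(lo, hi + 1)]
        numbers += [(pivot_a, chr(ord("A") + k)) for k in range(n_a)]
        numbers += [(pivot_b, chr(ord("A") + k)) for k in range(n_b)]
    numbers.sort(key=lambda t: imgt_sort_key(*t))
    return numbers
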