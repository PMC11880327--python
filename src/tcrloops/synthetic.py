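"""Synthetic IMGT-numbered TCR repertoires with planted statistical structure.

The generator emits paired alpha/beta variable domains on an idealized
shared backbone scaffold: all records use the same framework and anchor
coordinates, so anchor superposition between any two records is exact and
every planted loop-to-loop distance is controlled by construction. Loops
are smooth arcs between the flanking anchor CA positions:

* a region with K >= 1 planted conformational clusters draws K centroid
  arcs with pairwise (anchor-aligned, up-sampled where lengths differ)
  distance at least ``cluster_separation``; each record's loop is its
  cluster centroid plus isotropic Gaussian coordinate noise — the regime
  of canonical CDR1/CDR2 forms;
* a region with K = 0 draws a fresh random arc per record — the diffuse,
  non-clustering regime characteristic of CDR3;
* when a VJ-coherence target is set for a chain, CDR3 conformations are
  organised per (V, J) gene pairing instead: a coherent pairing shares one
  conformation, an incoherent one is split across two well-separated
  conformations, so the fraction of single-cluster pairings converges to
  the target.

Geometry is idealized, not stereochemically valid: bond offsets are
plausible constants and no forcefield is involved; every analysis under
test is purely geometric and the ground truth stays exact.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import loop_distance
from .io import GeneAnnotation, write_gene_table, write_structure
from .model import (
    CANONICAL_AA,
    ChainStructure,
    ImgtResidue,
    LoopStructure,
    REGIONS,
    REGION_NAMES,
    StructureError,
    TcrRecord,
    extract_region,
    imgt_loop_numbering,
)

logger = logging.getLogger(__name__)


class GeneratorError(StructureError):
    pass


# fixed backbone offsets (Angstrom) around each CA; plausible bond-length
# magnitudes, shared by every generated residue
_ATOM_OFFSETS = {
    "N": np.array([-1.20, -0.80, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.80, 0.00]),
    "O": np.array([1.60, -0.35, 0.30]),
}
_CA_SPACING = 2.2  # x-advance per IMGT position in the scaffold
_CHAIN_Y_OFFSET = {"alpha": 0.0, "beta": 40.0}
_FRAMEWORK_SEED = 1337  # the scaffold is a fixed constant shared by all records


def _default_length_distribution() -> dict[str, dict[int, float]]:
    return {
        "CDR1": {6: 0.6, 7: 0.4},
        "CDR2": {5: 0.5, 6: 0.5},
        "CDR3": {10: 0.15, 11: 0.20, 12: 0.30, 13: 0.20, 14: 0.10, 15: 0.05},
    }


def _default_clusters() -> dict[str, dict[str, int]]:
    # canonical CDR1/CDR2 forms; diffuse CDR3 on both chains
    return {
        "alpha": {"CDR1": 6, "CDR2": 4, "CDR3": 0},
        "beta": {"CDR1": 6, "CDR2": 4, "CDR3": 0},
    }


def _default_vj_vocab() -> dict[str, tuple[list[str], list[str]]]:
    return {
        "alpha": ([f"TRAV{i}" for i in range(1, 7)], [f"TRAJ{i}" for i in range(1, 5)]),
        "beta": ([f"TRBV{i}" for i in range(1, 7)], [f"TRBJ{i}" for i in range(1, 5)]),
    }


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic repertoire.

    ``noise_radius`` is the RMS per-atom displacement within a cluster
    (Angstrom); two members of the same cluster then sit ~ sqrt(2) x
    noise_radius apart in RMSD. ``cluster_separation`` is the minimum
    centroid-to-centroid distance and must exceed twice the noise radius
    whenever K >= 2. ``vj_coherence`` per chain is the target proportion of
    (V, J) pairings mapping onto a single 2 Angstrom CDR3 cluster
    (``None`` leaves CDR3 in the diffuse regime).
    """

    n_records: int = 100
    loop_length_distribution: dict[str, dict[int, float]] = field(
        default_factory=_default_length_distribution
    )
    clusters_per_region: dict[str, dict[str, int]] = field(default_factory=_default_clusters)
    noise_radius: float = 0.3
    cluster_separation: float = 4.0
    vj_vocab: dict[str, tuple[list[str], list[str]]] = field(default_factory=_default_vj_vocab)
    vj_coherence: dict[str, Optional[float]] = field(
        default_factory=lambda: {"alpha": None, "beta": None}
    )
    seq_mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise GeneratorError("n_records must be positive")
        if self.noise_radius < 0:
            raise GeneratorError("noise_radius must be non-negative")
        any_multi = any(
            k >= 2 for per_chain in self.clusters_per_region.values() for k in per_chain.values()
        )
        if any_multi and not self.cluster_separation > 2 * self.noise_radius:
            raise GeneratorError("cluster_separation must exceed 2 * noise_radius")
        for region, dist in self.loop_length_distribution.items():
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise GeneratorError(f"{region} length probabilities sum to {total}")
        for chain, coh in self.vj_coherence.items():
            if coh is not None and not 0.0 <= coh <= 1.0:
                raise GeneratorError(f"vj_coherence[{chain}] must be in [0, 1]")

    @classmethod
    def antibody_like(cls, **overrides) -> "GeneratorConfig":
        """Preset mirroring the antibody contrast: a light-like chain whose
        CDR3 clusters into a few canonical forms (alpha slot) against a
        heavy-like diffuse CDR3 (beta slot)."""
        clusters = _default_clusters()
        clusters["alpha"]["CDR3"] = 3
        clusters["beta"]["CDR3"] = 0
        overrides.setdefault("clusters_per_region", clusters)
        return cls(**overrides)


@dataclass
class GroundTruth:
    """Planted structure of a generated repertoire.

    ``labels[chain][region]`` holds one conformation label per record
    (-1 in the diffuse regime). ``vj_expected_clusters[chain]`` maps each
    realised (V, J) pairing to its intended CDR3 cluster count.
    """

    record_ids: list[str]
    labels: dict[str, dict[str, list[int]]]
    vj_expected_clusters: dict[str, dict[tuple[str, str], int]]
    consensus_sequences: dict[str, dict[str, dict[int, str]]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "record_ids": self.record_ids,
            "labels": self.labels,
            "vj_expected_clusters": {
                chain: {f"{v}|{j}": k for (v, j), k in pairs.items()}
                for chain, pairs in self.vj_expected_clusters.items()
            },
            "consensus_sequences": self.consensus_sequences,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _framework_positions() -> list[int]:
    loop_positions = {n for r in REGIONS.values() for n in r.loop_numbers()}
    return [n for n in range(1, 129) if n not in loop_positions]


class _Scaffold:
    """Fixed framework geometry and sequence for one chain kind."""

    def __init__(self, chain_kind: str):
        rng = np.random.default_rng(_FRAMEWORK_SEED + (0 if chain_kind == "alpha" else 1))
        y0 = _CHAIN_Y_OFFSET[chain_kind]
        self.chain_kind = chain_kind
        self.framework: list[ImgtResidue] = []
        self._ca: dict[int, np.ndarray] = {}
        aa_pool = list(CANONICAL_AA)
        for n in _framework_positions():
            ca = np.array([_CA_SPACING * n, y0, 0.0])
            self._ca[n] = ca
            self.framework.append(
                ImgtResidue(
                    imgt_number=n,
                    amino_acid=aa_pool[int(rng.integers(len(aa_pool)))],
                    backbone={a: ca + off for a, off in _ATOM_OFFSETS.items()},
                )
            )

    def loop_endpoints(self, region_name: str) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = REGIONS[region_name].loop_range
        return self._ca[lo - 1], self._ca[hi + 1]

    def framework_copy(self) -> list[ImgtResidue]:
        return [r.copy() for r in self.framework]


_SCAFFOLDS = {kind: _Scaffold(kind) for kind in ("alpha", "beta")}


def _arc_loop(
    scaffold: _Scaffold, region_name: str, length: int, bulge: np.ndarray
) -> list[ImgtResidue]:
    """Loop residues on a smooth sine-bump arc between the anchor endpoints."""
    start, end = scaffold.loop_endpoints(region_name)
    numbering = imgt_loop_numbering(region_name, length)
    residues = []
    for i, (num, icode) in enumerate(numbering):
        t = (i + 1) / (length + 1)
        ca = (1 - t) * start + t * end + math.sin(math.pi * t) * bulge
        residues.append(
            ImgtResidue(
                imgt_number=num,
                insertion_code=icode,
                backbone={a: ca + off for a, off in _ATOM_OFFSETS.items()},
            )
        )
    return residues


def _as_loop_structure(
    scaffold: _Scaffold, region_name: str, loop_residues: list[ImgtResidue]
) -> LoopStructure:
    anchor_set = set(REGIONS[region_name].anchor_numbers)
    anchors = [r for r in scaffold.framework if r.imgt_number in anchor_set]
    return LoopStructure(
        parent_id="centroid",
        chain_kind=scaffold.chain_kind,
        region_name=region_name,
        loop_residues=loop_residues,
        anchor_residues=anchors,
    )


def _sample_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


@dataclass
class _Conformation:
    region_name: str
    length: int
    residues: list[ImgtResidue]
    consensus: str


def _sample_conformations(
    rng: np.random.Generator,
    scaffold: _Scaffold,
    region_name: str,
    k: int,
    length_dist: dict[int, float],
    separation: float,
    max_tries: int = 400,
) -> list[_Conformation]:
    """K centroid arcs with pairwise distance >= separation."""
    confs: list[_Conformation] = []
    structures: list[LoopStructure] = []
    for _ in range(k):
        length = _sample_length(rng, length_dist)
        for attempt in range(max_tries):
            magnitude = (2.5 + 5.0 * rng.random()) * (1.0 + attempt / 100.0)
            candidate = _arc_loop(scaffold, region_name, length, magnitude * _unit_vector(rng))
            cand_ls = _as_loop_structure(scaffold, region_name, candidate)
            if all(
                loop_distance(cand_ls, prev).value >= separation for prev in structures
            ):
                break
        else:
            raise GeneratorError(
                f"cannot place {k} conformations for {region_name} at "
                f"separation {separation} (geometry infeasible)"
            )
        consensus = "".join(
            CANONICAL_AA[int(i)] for i in rng.integers(len(CANONICAL_AA), size=length)
        )
        confs.append(_Conformation(region_name, length, candidate, consensus))
        structures.append(cand_ls)
    return confs


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = []
    for ch in consensus:
        if rng.random() < rate:
            choices = CANONICAL_AA.replace(ch, "")
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(ch)
    return "".join(out)


def _noisy_copy(
    rng: np.random.Generator, conf: _Conformation, noise_radius: float, sequence: str
) -> list[ImgtResidue]:
    sigma = noise_radius / math.sqrt(3.0)
    out = []
    for res, aa in zip(conf.residues, sequence):
        backbone = {
            a: res.backbone[a] + rng.normal(scale=sigma, size=3) if sigma > 0
            else res.backbone[a].copy()
            for a in res.backbone
        }
        out.append(ImgtResidue(res.imgt_number, res.insertion_code, aa, backbone))
    return out


def generate_repertoire(config: GeneratorConfig) -> tuple[list[TcrRecord], GroundTruth]:
    """Generate a repertoire of paired TCR records plus its ground truth.

    Fully reproducible: identical config and seed give bit-identical
    coordinates, sequences and gene labels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    record_ids = [f"synth{r:04d}" for r in range(n)]

    labels: dict[str, dict[str, list[int]]] = {c: {} for c in ("alpha", "beta")}
    consensus: dict[str, dict[str, dict[int, str]]] = {c: {} for c in ("alpha", "beta")}
    vj_expected: dict[str, dict[tuple[str, str], int]] = {c: {} for c in ("alpha", "beta")}
    # per chain/region: per-record list of residue lists
    loop_pool: dict[str, dict[str, list[list[ImgtResidue]]]] = {
        c: {} for c in ("alpha", "beta")
    }
    gene_labels: dict[str, list[tuple[str, str]]] = {}

    for chain in ("alpha", "beta"):
        scaffold = _SCAFFOLDS[chain]
        v_vocab, j_vocab = config.vj_vocab[chain]
        coherence = config.vj_coherence.get(chain)

        # gene labels: round-robin over the V x J product when a coherence
        # target is set (balanced group sizes), random draw otherwise
        pairs = list(product(v_vocab, j_vocab))
        if coherence is not None:
            assigned = [pairs[r % len(pairs)] for r in range(n)]
        else:
            assigned = [
                (v_vocab[int(rng.integers(len(v_vocab)))],
                 j_vocab[int(rng.integers(len(j_vocab)))])
                for _ in range(n)
            ]
        gene_labels[chain] = assigned

        for region in REGION_NAMES:
            k = config.clusters_per_region[chain][region]
            length_dist = config.loop_length_distribution[region]
            if region == "CDR3" and coherence is not None:
                loops, region_labels, region_consensus = _coherent_cdr3(
                    rng, scaffold, config, assigned, vj_expected[chain]
                )
            elif k >= 1:
                confs = _sample_conformations(
                    rng, scaffold, region, k, length_dist, config.cluster_separation
                )
                # balanced shuffled assignment: every planted cluster is
                # realised whenever n_records >= K, keeping census == K exact
                region_labels = [int(x) for x in rng.permutation(np.arange(n) % k)]
                loops = []
                for lab in region_labels:
                    conf = confs[lab]
                    seq = _mutate(rng, conf.consensus, config.seq_mutation_rate)
                    loops.append(_noisy_copy(rng, conf, config.noise_radius, seq))
                region_consensus = {i: c.consensus for i, c in enumerate(confs)}
            else:  # diffuse: fresh arc per record
                region_labels = [-1] * n
                loops = []
                for _ in range(n):
                    length = _sample_length(rng, length_dist)
                    magnitude = 1.0 + 6.0 * rng.random()
                    residues = _arc_loop(
                        scaffold, region, length, magnitude * _unit_vector(rng)
                    )
                    seq = "".join(
                        CANONICAL_AA[int(i)]
                        for i in rng.integers(len(CANONICAL_AA), size=length)
                    )
                    conf = _Conformation(region, length, residues, seq)
                    loops.append(_noisy_copy(rng, conf, config.noise_radius, seq))
                region_consensus = {}
            labels[chain][region] = region_labels
            consensus[chain][region] = region_consensus
            loop_pool[chain][region] = loops

    records = []
    for r, rid in enumerate(record_ids):
        chains = {}
        for chain in ("alpha", "beta"):
            residues = _SCAFFOLDS[chain].framework_copy()
            for region in REGION_NAMES:
                residues.extend(loop_pool[chain][region][r])
            v, j = gene_labels[chain][r]
            chains[chain] = ChainStructure(
                chain_kind=chain, residues=residues, v_gene=v, j_gene=j
            )
        records.append(
            TcrRecord(record_id=rid, alpha=chains["alpha"], beta=chains["beta"],
                      source_tag="synthetic")
        )

    truth = GroundTruth(
        record_ids=record_ids,
        labels=labels,
        vj_expected_clusters=vj_expected,
        consensus_sequences=consensus,
    )
    return records, truth


def _coherent_cdr3(
    rng: np.random.Generator,
    scaffold: _Scaffold,
    config: GeneratorConfig,
    assigned_pairs: list[tuple[str, str]],
    vj_expected: dict[tuple[str, str], int],
) -> tuple[list[list[ImgtResidue]], list[int], dict[int, str]]:
    """CDR3 loops organised per VJ pairing to realise the coherence target.

    A pairing is coherent (one conformation) with probability equal to the
    chain's target; an incoherent pairing splits its members evenly across
    two conformations separated by at least ``cluster_separation``.
    """
    chain = scaffold.chain_kind
    coherence = config.vj_coherence[chain]
    length_dist = config.loop_length_distribution["CDR3"]
    realised = sorted(set(assigned_pairs))
    conf_store: list[_Conformation] = []
    pair_confs: dict[tuple[str, str], list[int]] = {}
    for pair in realised:
        k_intended = 1 if rng.random() < coherence else 2
        confs = _sample_conformations(
            rng, scaffold, "CDR3", k_intended, length_dist, config.cluster_separation
        )
        indices = []
        for conf in confs:
            indices.append(len(conf_store))
            conf_store.append(conf)
        pair_confs[pair] = indices
        vj_expected[pair] = k_intended

    loops: list[list[ImgtResidue]] = []
    region_labels: list[int] = []
    seen_count: dict[tuple[str, str], int] = {}
    for pair in assigned_pairs:
        rank = seen_count.get(pair, 0)
        seen_count[pair] = rank + 1
        indices = pair_confs[pair]
        conf = conf_store[indices[rank % len(indices)]]
        seq = _mutate(rng, conf.consensus, config.seq_mutation_rate)
        loops.append(_noisy_copy(rng, conf, config.noise_radius, seq))
        region_labels.append(indices[rank % len(indices)])
    region_consensus = {i: c.consensus for i, c in enumerate(conf_store)}
    return loops, region_labels, region_consensus


def extract_loops(
    records: Sequence[TcrRecord], chain_kind: str, region_name: str
) -> list[LoopStructure]:
    """Convenience: extract one region from every record."""
    return [extract_region(rec, chain_kind, region_name) for rec in records]


def generate_identity_rmsd_pairs(
    n_pairs: int,
    target_pcc: float = -0.41,
    seed: int = 0,
    identity_range: tuple[float, float] = (0.20, 0.95),
    rmsd_intercept: float = 4.5,
    rmsd_total_sd: float = 1.0,
) -> np.ndarray:
    """Joint (sequence identity, RMSD) draws with a planted correlation.

    Identity is uniform on ``identity_range``; RMSD is a linear response
    plus independent uniform noise, with slope and noise width solved so
    that the *population* Pearson correlation equals ``target_pcc``
    exactly and both marginals stay bounded (identity in [0, 1],
    RMSD >= 0). The empirical PCC then converges to the target at the
    usual ~(1 - rho^2)/sqrt(n) rate; n = 2 is degenerate (PCC is +-1).
    """
    if not -1.0 < target_pcc <= 0.0:
        raise GeneratorError("target_pcc must be in (-1, 0]")
    lo, hi = identity_range
    if not 0.0 <= lo < hi <= 1.0:
        raise GeneratorError("identity_range must be inside [0, 1]")
    rng = np.random.default_rng(seed)
    identity = rng.uniform(lo, hi, size=n_pairs)
    sd_identity = (hi - lo) / math.sqrt(12.0)
    slope = target_pcc * rmsd_total_sd / sd_identity
    noise_sd = rmsd_total_sd * math.sqrt(1.0 - target_pcc**2)
    half_width = noise_sd * math.sqrt(3.0)
    noise = rng.uniform(-half_width, half_width, size=n_pairs)
    rmsd = rmsd_intercept + slope * identity + noise
    if np.any(rmsd < 0):
        raise GeneratorError("rmsd_intercept too small for the requested correlation")
    return np.column_stack([identity, rmsd])


def perturb_record(
    record: TcrRecord,
    chain_kind: str,
    region_name: str,
    displacement: float,
    seed: int = 0,
    direction: Optional[np.ndarray] = None,
) -> TcrRecord:
    """Copy a record with one loop rigidly translated by ``displacement``.

    Anchors are untouched, so the anchor superposition against the
    original is the identity and the loop's anchor-aligned RMSD to the
    original equals ``displacement`` exactly. The translation direction is
    drawn from ``seed`` unless given.
    """
    if displacement < 0:
        raise GeneratorError("displacement must be non-negative")
    lo, hi = REGIONS[region_name].loop_range
    out = record.copy()
    chain = out.chain(chain_kind)
    if not any(lo <= r.imgt_number <= hi for r in chain.residues):
        raise StructureError(f"{record.record_id}: no {region_name} loop on {chain_kind}")
    if direction is None:
        direction = _unit_vector(np.random.default_rng(seed))
    else:
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
    shift = displacement * direction
    for res in chain.residues:
        if lo <= res.imgt_number <= hi:
            for atom, coord in res.backbone.items():
                if coord is not None:
                    res.backbone[atom] = coord + shift
    return out


def write_repertoire(
    records: Sequence[TcrRecord],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write PDB files, a gene-annotation CSV and the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = {}
    for record in records:
        write_structure(record, outdir / f"{record.record_id}.pdb")
        annotations[record.record_id] = GeneAnnotation(
            record.alpha.v_gene, record.alpha.j_gene,
            record.beta.v_gene, record.beta.j_gene,
        )
    write_gene_table(annotations, outdir / "genes.csv")
    truth.to_json(outdir / "ground_truth.json")
    logger.info("wrote %d records to %s", len(records), outdir)
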