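"""Shared fixtures: toy loop builders and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from tcrloops.model import (
    REGIONS,
    ImgtResidue,
    LoopStructure,
    imgt_loop_numbering,
)

# fixed backbone offsets around each CA for toy residues
ATOM_OFFSETS = {
    "N": np.array([-1.2, -0.8, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.8, 0.0]),
    "O": np.array([1.6, -0.35, 0.3]),
}


def make_residue(num: int, icode: str = "", ca=(0.0, 0.0, 0.0), aa: str = "A") -> ImgtResidue:
    ca = np.asarray(ca, float)
    return ImgtResidue(num, icode, aa, {k: ca + v for k, v in ATOM_OFFSETS.items()})


def default_anchor_ca(region: str) -> dict[int, np.ndarray]:
    return {n: np.array([2.2 * n, 0.0, 0.0]) for n in REGIONS[region].anchor_numbers}


def make_loop(
    ca_positions,
    region: str = "CDR3",
    parent: str = "toy",
    chain: str = "alpha",
    anchor_ca: dict | None = None,
    sequence: str | None = None,
) -> LoopStructure:
    """Loop with CA atoms at the given positions, IMGT-numbered for its
    length, on a shared straight-line anchor scaffold."""
    ca_positions = [np.asarray(p, float) for p in ca_positions]
    numbering = imgt_loop_numbering(region, len(ca_positions))
    if sequence is None:
        sequence = "A" * len(ca_positions)
    loop = [
        make_residue(n, ic, ca, aa)
        for (n, ic), ca, aa in zip(numbering, ca_positions, sequence)
    ]
    if anchor_ca is None:
        anchor_ca = default_anchor_ca(region)
    anchors = [make_residue(n, "", ca) for n, ca in sorted(anchor_ca.items())]
    return LoopStructure(parent, chain, region, loop, anchors)


def random_loop(rng: np.random.Generator, length: int, region: str = "CDR3",
                scale: float = 3.0, **kwargs) -> LoopStructure:
    lo, hi = REGIONS[region].loop_range
    start = np.array([2.2 * (lo - 1), 0.0, 0.0])
    end = np.array([2.2 * (hi + 1), 0.0, 0.0])
    t = (np.arange(length) + 1) / (length + 1)
    base = start + np.outer(t, end - start)
    ca = base + rng.normal(scale=scale, size=(length, 3))
    return make_loop(ca, region=region, **kwargs)


def smooth_loop(rng: np.random.Generator, length: int, region: str = "CDR3",
                amplitudes=None, **kwargs) -> LoopStructure:
    """Loop whose 4L-atom backbone trace lies on one smooth curve (a chord
    plus low-frequency sine modes), so spline resampling converges fast."""
    lo, hi = REGIONS[region].loop_range
    start = np.array([2.2 * (lo - 1), 0.0, 0.0])
    end = np.array([2.2 * (hi + 1), 0.0, 0.0])
    if amplitudes is None:
        amplitudes = rng.normal(scale=2.0, size=(2, 3))
    n_atoms = 4 * length
    t = np.linspace(0.05, 0.95, n_atoms)
    trace = start + np.outer(t, end - start)
    for mode, amp in enumerate(amplitudes, start=1):
        trace = trace + np.outer(np.sin(np.pi * mode * t), amp)
    numbering = imgt_loop_numbering(region, length)
    loop = []
    for i, (n, ic) in enumerate(numbering):
        atoms = trace[4 * i: 4 * i + 4]
        backbone = dict(zip(("N", "CA", "C", "O"), atoms))
        loop.append(ImgtResidue(n, ic, "A", backbone))
    anchor_ca = default_anchor_ca(region)
    anchors = [make_residue(n, "", ca) for n, ca in sorted(anchor_ca.items())]
    return LoopStructure(kwargs.get("parent", "smooth"), kwargs.get("chain", "alpha"),
                         region, loop, anchors)


def greedy_cluster_transcription(D: np.ndarray, tau: float) -> list[list[int]]:
    """Literal transcription of the published greedy-clustering pseudocode
    (1-indexed loops translated to 0-indexed lists); the independent oracle
    for the vectorised implementation."""
    n = D.shape[0]
    clusters: dict[int, list[int]] = {}
    clustered_indices: list[int] = []
    count = 0
    for i in range(n):
        if i not in clustered_indices:
            clusters[count] = [i]
            clustered_indices.append(i)
            for j in range(i + 1, n):
                if j not in clustered_indices and D[i, j] < tau:
                    clusters[count].append(j)
                    clustered_indices.append(j)
            count += 1
    return [clusters[k] for k in range(count)]


def lcs_recursive(a: str, b: str, _memo=None) -> int:
    """Memoised recursive LCS, independent of the DP implementation."""
    if _memo is None:
        _memo = {}
    key = (a, b)
    if key in _memo:
        return _memo[key]
    if not a or not b:
        result = 0
    elif a[-1] == b[-1]:
        result = lcs_recursive(a[:-1], b[:-1], _memo) + 1
    else:
        result = max(lcs_recursive(a[:-1], b, _memo), lcs_recursive(a, b[:-1], _memo))
    _memo[key] = result
    return result


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_repertoire():
    """A small default-condition synthetic repertoire shared across tests."""
    from tcrloops.synthetic import GeneratorConfig, generate_repertoire

    return generate_repertoire(GeneratorConfig(n_records=25, seed=7))
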