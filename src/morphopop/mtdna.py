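"""Mitochondrial COI barcoding checks: p-distances, haplotypes, segregating
sites, neighbor-joining trees and minimum-spanning haplotype networks.

Sequences are pre-aligned nucleotide strings (A/C/G/T/N/-).  Distances are
uncorrected p-distances in percent with pairwise deletion of ambiguous or
gapped positions — the scale on which intraspecific (~1%) and interspecific
(>10%) divergence separate cleanly in insect COI barcoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "HaplotypeSet",
    "pdistance_matrix",
    "collapse_haplotypes",
    "segregating_sites",
    "nj_tree",
    "mst_network",
]

_VALID = set(b"ACGT")


def _to_array(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = list(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) > 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lens)}")
    arr = np.frombuffer("".join(seqs[i].upper() for i in ids).encode(),
                        dtype="S1").reshape(len(ids), -1)
    return ids, arr


@dataclass
class HaplotypeSet:
    """Unique sequences with frequencies, composition, and their p-distances."""

    haplotypes: dict[str, str]               # haplotype id -> sequence
    frequency: dict[str, int]
    members: dict[str, list[str]]            # haplotype id -> input sequence ids
    composition: dict[str, dict[str, int]]   # haplotype id -> population -> count
    distance_matrix: pd.DataFrame            # percent p-distances between haplotypes

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total(self) -> int:
        return sum(self.frequency.values())


def pdistance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Pairwise uncorrected p-distances in percent, pairwise-deleting any
    position where either sequence is N or a gap."""
    ids, arr = _to_array(seqs)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                diff = int((arr[i][both] != arr[j][both]).sum())
                out[i, j] = out[j, i] = 100.0 * diff / m
    return pd.DataFrame(out, index=ids, columns=ids)


def collapse_haplotypes(
    seqs: dict[str, str],
    populations: dict[str, str] | None = None,
) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes (strict string equality;
    sequences differing only at N/gap positions are kept distinct).

    Haplotype IDs are assigned in order of first occurrence.
    """
    ids, _ = _to_array(seqs)
    hap_of: dict[str, str] = {}
    haps: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for sid in ids:
        s = seqs[sid].upper()
        if s not in hap_of:
            hid = f"Hap{len(haps) + 1:02d}"
            hap_of[s] = hid
            haps[hid] = s
            members[hid] = []
        members[hap_of[s]].append(sid)
    freq = {h: len(m) for h, m in members.items()}
    comp: dict[str, dict[str, int]] = {}
    for h, m in members.items():
        comp[h] = {}
        for sid in m:
            pop = populations.get(sid, "?") if populations else "?"
            comp[h][pop] = comp[h].get(pop, 0) + 1
    dist = pdistance_matrix(haps)
    return HaplotypeSet(haplotypes=haps, frequency=freq, members=members,
                        composition=comp, distance_matrix=dist)


def segregating_sites(seqs: dict[str, str]) -> int:
    """Number of alignment columns with >= 2 distinct resolved (ACGT) states."""
    _, arr = _to_array(seqs)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    count = 0
    for j in range(arr.shape[1]):
        states = set(arr[valid[:, j], j].tobytes())
        if len(states) >= 2:
            count += 1
    return count


def nj_tree(dist: pd.DataFrame, outgroup: str | None = None) -> str:
    """Saitou–Nei neighbor joining on a distance matrix; returns Newick.

    Negative branch lengths are clamped to zero (difference moved to the
    adjacent branch).  With ``outgroup`` the tree is rooted on that taxon's
    branch.
    """
    mat = np.asarray(dist, dtype=float)
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains NaN entries")
    if mat.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = DistanceMatrix(mat, ids=list(dist.index))
    tree = nj(dm)
    if outgroup is not None:
        node = tree.find(outgroup)
        tree = tree.root_at(node.parent)
    return str(tree).strip()


def mst_network(h: HaplotypeSet) -> dict:
    """Minimum spanning network of haplotypes on raw mismatch counts.

    Kruskal MST over absolute Hamming distances (mutational steps); every
    non-tree edge whose weight ties the maximum weight on the tree path
    between its endpoints is reported as a co-minimal alternative.
    """
    if h.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    ids = list(h.haplotypes)
    _, arr = _to_array(h.haplotypes)
    gfull = nx.Graph()
    for i, a in enumerate(ids):
        for b, j in zip(ids[i + 1:], range(i + 1, len(ids))):
            steps = int((arr[i] != arr[j]).sum())
            gfull.add_edge(a, b, weight=steps)
    mst = nx.minimum_spanning_tree(gfull, algorithm="kruskal")
    edges = [(a, b, gfull[a][b]["weight"]) for a, b in mst.edges]

    alternatives = []
    for a, b, d in gfull.edges(data=True):
        if mst.has_edge(a, b):
            continue
        path = nx.shortest_path(mst, a, b)
        path_max = max(mst[u][v]["weight"] for u, v in zip(path, path[1:]))
        if d["weight"] <= path_max:
            alternatives.append((a, b, d["weight"]))
    return {"edges": sorted(edges), "alternatives": sorted(alternatives)}
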