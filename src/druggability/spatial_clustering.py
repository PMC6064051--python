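"""Recursive 3D proximity clustering of mutated residues.

Mutated residues on a protein structure are paired when their 3D distance is
both below 5 Angstroms and empirically rare: the pair p-value is the
proportion of ALL residue-pair distances on that structure that are less
than or equal to the pair's distance, and only pairs with p < 0.05 survive.
Single-link agglomeration (connected components of the significant-pair
graph) forms initial clusters.  Each initial cluster is focused around a
centroid — the most recurrent mutation, ties broken toward the member
closest (recurrence-weighted, along graph shortest paths) to the rest —
keeping members within a 5 Angstrom graph radius; members left outside are
re-clustered recursively until no significant pair remains.

Residues that co-cluster with knowledgebase drug-sensitive mutations but are
not themselves catalogued become putative sensitive calls; resistant
clusters yield putative resistant calls only when they share no member with
any sensitive-containing cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_P_THRESHOLD = 0.05
PAIR_DISTANCE_LIMIT = 5.0  # Angstroms
RADIUS_LIMIT = 5.0  # graph-radius limit from the centroid, Angstroms

LABEL_KNOWN_SENSITIVE = "known_sensitive"
LABEL_KNOWN_RESISTANT = "known_resistant"
LABEL_PUTATIVE = "putative"


@dataclass
class ResidueDistanceSet:
    """Pairwise residue distances for one structure/gene.

    ``distances`` maps unordered residue pairs (stored with i < j) to their
    distance; the full set of values is the background distribution for the
    empirical pair p-value.
    """

    structure_id: str
    gene: str
    distances: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (i, j), d in self.distances.items():
            if d < 0:
                raise ValueError(f"negative distance for pair ({i},{j})")
            if i >= j:
                raise ValueError("distance keys must satisfy i < j")

    def distance(self, i: int, j: int) -> float | None:
        if i == j:
            return 0.0
        return self.distances.get((min(i, j), max(i, j)))

    @property
    def background(self) -> np.ndarray:
        return np.fromiter(self.distances.values(), dtype=float)


def distance_set_from_coordinates(
    structure_id: str, gene: str, coords: dict[int, np.ndarray]
) -> ResidueDistanceSet:
    """Build a distance set from per-residue point coordinates."""
    residues = sorted(coords)
    dist = {}
    for a, i in enumerate(residues):
        for j in residues[a + 1 :]:
            dist[(i, j)] = float(np.linalg.norm(np.asarray(coords[i]) - np.asarray(coords[j])))
    return ResidueDistanceSet(structure_id, gene, dist)


def distance_set_from_pdb(path, gene: str, chain_id: str = "A") -> ResidueDistanceSet:
    """Residue-residue distances from a PDB chain.

    The residue pair distance is the minimum inter-atomic distance between
    the two residues.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(gene, str(path))
    chain = structure[0][chain_id]
    residues = [r for r in chain if r.id[0] == " "]
    coords = {
        r.id[1]: np.array([atom.coord for atom in r], dtype=float) for r in residues
    }
    numbers = sorted(coords)
    dist = {}
    for a, i in enumerate(numbers):
        for j in numbers[a + 1 :]:
            diff = coords[i][:, None, :] - coords[j][None, :, :]
            dist[(i, j)] = float(np.sqrt((diff**2).sum(axis=2)).min())
    return ResidueDistanceSet(str(getattr(path, "stem", path)), gene, dist)


def read_distance_tsv(path) -> dict[tuple[str, str], ResidueDistanceSet]:
    """Load precomputed distances: structure_id, gene, res_i, res_j, distance_A."""
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[str, str], ResidueDistanceSet] = {}
    for (sid, gene), grp in df.groupby(["structure_id", "gene"]):
        dist = {}
        for row in grp.itertuples(index=False):
            i, j = int(row.res_i), int(row.res_j)
            if i == j:
                continue
            dist[(min(i, j), max(i, j))] = float(row.distance_A)
        out[(sid, gene)] = ResidueDistanceSet(sid, gene, dist)
    return out


@dataclass(frozen=True)
class ProximalPair:
    residues: tuple[int, int]
    distance: float
    p_value: float


@dataclass
class MutationCluster:
    cluster_id: str
    gene: str
    structure_id: str
    members: list[int]  # residue positions
    centroid: int
    generation: int
    labels: dict[int, str] = field(default_factory=dict)
    recurrence: dict[int, int] = field(default_factory=dict)
    graph: nx.Graph = field(default_factory=nx.Graph)


def pair_pvalue(d: float, background: np.ndarray) -> float:
    """Proportion of all structure pair distances <= d."""
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("empty background distribution")
    return float(np.count_nonzero(background <= d) / background.size)


def significant_pairs(
    mutated_residues: list[int],
    dset: ResidueDistanceSet,
    p_threshold: float = PAIR_P_THRESHOLD,
    distance_limit: float = PAIR_DISTANCE_LIMIT,
) -> list[ProximalPair]:
    """Pairs of mutated residues with p < 0.05 and distance < 5 A (both strict)."""
    background = dset.background
    residues = sorted(set(mutated_residues))
    pairs = []
    for a, i in enumerate(residues):
        for j in residues[a + 1 :]:
            d = dset.distance(i, j)
            if d is None or d >= distance_limit:
                continue
            p = pair_pvalue(d, background)
            if p < p_threshold:
                pairs.append(ProximalPair((i, j), d, p))
    return pairs


def single_link_cluster(pairs: list[ProximalPair]) -> list[set[int]]:
    """Initial clusters = connected components of the significant-pair graph."""
    g = nx.Graph()
    for p in pairs:
        g.add_edge(*p.residues, weight=p.distance)
    return [set(c) for c in nx.connected_components(g)]


def choose_centroid(
    members: set[int], recurrence: dict[int, int], graph: nx.Graph
) -> int:
    """The most recurrent member; ties resolved toward the member with the
    smallest recurrence-weighted sum of shortest-path distances to all other
    members, then toward the smallest residue number."""
    max_rec = max(recurrence.get(m, 0) for m in members)
    candidates = sorted(m for m in members if recurrence.get(m, 0) == max_rec)
    if len(candidates) == 1:
        return candidates[0]

    def weighted_distance_sum(m: int) -> float:
        lengths = nx.single_source_dijkstra_path_length(graph, m, weight="weight")
        return sum(
            recurrence.get(o, 0) * lengths.get(o, np.inf) for o in members if o != m
        )

    return min(candidates, key=lambda m: (weighted_distance_sum(m), m))


def focus_and_recurse(
    initial_members: set[int],
    pairs: list[ProximalPair],
    recurrence: dict[int, int],
    radius_limit: float = RADIUS_LIMIT,
) -> list[tuple[set[int], int, int, nx.Graph]]:
    """Focus an initial cluster by graph radius and recurse on the remainder.

    Returns (members, centroid, generation, subgraph) tuples.  Generation 0
    is the focused cluster around the first centroid; members beyond the
    radius re-enter single-link clustering restricted to pairs among
    themselves, and the process repeats until no significant pair remains.
    Singleton leftovers are discarded (no pair, no cluster).
    """
    out: list[tuple[set[int], int, int, nx.Graph]] = []
    remaining = set(initial_members)
    live_pairs = [p for p in pairs if set(p.residues) <= remaining]
    generation = 0
    while True:
        components = single_link_cluster(live_pairs)
        if not components:
            break
        next_remaining: set[int] = set()
        for comp in sorted(components, key=min):
            g = nx.Graph()
            for p in live_pairs:
                if set(p.residues) <= comp:
                    g.add_edge(*p.residues, weight=p.distance)
            centroid = choose_centroid(comp, recurrence, g)
            lengths = nx.single_source_dijkstra_path_length(g, centroid, weight="weight")
            inside = {m for m in comp if lengths.get(m, np.inf) <= radius_limit}
            out.append((inside, centroid, generation, g.subgraph(inside).copy()))
            next_remaining |= comp - inside
        if not next_remaining:
            break
        remaining = next_remaining
        live_pairs = [p for p in live_pairs if set(p.residues) <= remaining]
        if not live_pairs:
            break
        generation += 1
    return out


def cluster_structure(
    dset: ResidueDistanceSet,
    mutated_residues: list[int],
    recurrence: dict[int, int],
    kb_labels: dict[int, str] | None = None,
    p_threshold: float = PAIR_P_THRESHOLD,
    distance_limit: float = PAIR_DISTANCE_LIMIT,
    radius_limit: float = RADIUS_LIMIT,
) -> list[MutationCluster]:
    """Full clustering of one structure: pairs -> components -> focus/recurse."""
    kb_labels = kb_labels or {}
    pairs = significant_pairs(mutated_residues, dset, p_threshold, distance_limit)
    clusters: list[MutationCluster] = []
    for comp in sorted(single_link_cluster(pairs), key=min):
        comp_pairs = [p for p in pairs if set(p.residues) <= comp]
        for members, centroid, gen, graph in focus_and_recurse(
            comp, comp_pairs, recurrence, radius_limit
        ):
            cid = f"{dset.gene}:{dset.structure_id}:{min(members)}g{gen}"
            clusters.append(
                MutationCluster(
                    cluster_id=cid,
                    gene=dset.gene,
                    structure_id=dset.structure_id,
                    members=sorted(members),
                    centroid=centroid,
                    generation=gen,
                    labels={
                        m: kb_labels.get(m, LABEL_PUTATIVE) for m in members
                    },
                    recurrence={m: recurrence.get(m, 0) for m in members},
                    graph=graph,
                )
            )
    return clusters


def putative_residue_sets(
    clusters: list[MutationCluster],
) -> tuple[set[tuple[str, int]], set[tuple[str, int]]]:
    """(gene, residue) sets eligible for putative sensitive/resistant calls.

    Every member residue of a cluster holding a known sensitive mutation is
    sensitive-eligible; members of resistant-containing clusters are
    resistant-eligible only when the cluster shares no member with any
    sensitive-containing cluster.  Uncatalogued mutations at these residues
    (including at residues that also host a known mutation) become putative
    calls.
    """
    sensitive: set[tuple[str, int]] = set()
    for c in clusters:
        if LABEL_KNOWN_SENSITIVE in c.labels.values():
            sensitive.update((c.gene, m) for m in c.members)
    resistant: set[tuple[str, int]] = set()
    for c in clusters:
        if LABEL_KNOWN_SENSITIVE in c.labels.values():
            continue
        if LABEL_KNOWN_RESISTANT not in c.labels.values():
            continue
        if any((c.gene, m) in sensitive for m in c.members):
            continue
        resistant.update((c.gene, m) for m in c.members)
    return sensitive, resistant


def propagate_labels(clusters: list[MutationCluster]) -> pd.DataFrame:
    """Derive putative sensitive/resistant residues from cluster membership.

    Columns: cluster_id, gene, structure_id, generation, residue, label,
    putative_call, recurrence, centroid_flag.  Putative resistant calls are
    suppressed for resistant clusters overlapping any sensitive-containing
    cluster.
    """
    sensitive_members: set[tuple[str, int]] = set()
    for c in clusters:
        if any(l == LABEL_KNOWN_SENSITIVE for l in c.labels.values()):
            sensitive_members.update((c.gene, m) for m in c.members)

    rows = []
    for c in clusters:
        has_sensitive = any(l == LABEL_KNOWN_SENSITIVE for l in c.labels.values())
        has_resistant = any(l == LABEL_KNOWN_RESISTANT for l in c.labels.values())
        if has_sensitive and has_resistant:
            logger.warning(
                "cluster %s holds both sensitive and resistant known mutations; "
                "members labelled putative_sensitive",
                c.cluster_id,
            )
        overlaps_sensitive = any((c.gene, m) in sensitive_members for m in c.members)
        for m in c.members:
            label = c.labels[m]
            putative_call = ""
            if label == LABEL_PUTATIVE:
                if has_sensitive:
                    putative_call = "putative_sensitive"
                elif has_resistant and not overlaps_sensitive:
                    putative_call = "putative_resistant"
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "gene": c.gene,
                    "structure_id": c.structure_id,
                    "generation": c.generation,
                    "residue": m,
                    "label": label,
                    "putative_call": putative_call,
                    "recurrence": c.recurrence.get(m, 0),
                    "centroid_flag": m == c.centroid,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "gene",
            "structure_id",
            "generation",
            "residue",
            "label",
            "putative_call",
            "recurrence",
            "centroid_flag",
        ],
    )
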