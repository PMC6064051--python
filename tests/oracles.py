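"""Independent reference implementations used to cross-check the package.

Everything here is deliberately brute-force and literal — exhaustive scans,
explicit enumeration, Floyd-Warshall shortest paths — and shares no code
path with the implementation under test.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass


# --------------------------------------------------------------------------
# knowledgebase matching / call resolution
# --------------------------------------------------------------------------

_EVIDENCE = {"preclinical": 1, "case_report": 2, "clinical_trial": 3, "fda_approved": 4}


@dataclass(frozen=True)
class OracleEntry:
    entry_id: int
    gene: str
    variant_class: str
    variant_spec: str
    tumor_type: str
    effect: str
    evidence_level: str
    drug: str


@dataclass(frozen=True)
class OracleRecord:
    sample_id: str
    cancer_type: str
    gene: str
    protein_change: str
    mutation_class: str


def _parse_change(change: str, mclass: str):
    """(ref, pos, alt) of a protein change, or None."""
    if mclass == "missense":
        m = re.match(r"^([A-Z])(\d+)([A-Z])$", change)
        return (m.group(1), int(m.group(2)), m.group(3)) if m else None
    if mclass == "nonsense":
        m = re.match(r"^([A-Z])(\d+)\*$", change)
        return (m.group(1), int(m.group(2)), "*") if m else None
    if mclass == "frameshift":
        m = re.match(r"^([A-Z])(\d+)[A-Za-z]*fs", change)
        return (m.group(1), int(m.group(2)), None) if m else None
    if mclass in ("inframe_del", "inframe_ins"):
        m = re.match(r"^([A-Z])(\d+)", change)
        return (m.group(1), int(m.group(2)), None) if m else None
    return None


def brute_force_match(record: OracleRecord, entries: list[OracleEntry]) -> list[int]:
    """Exhaustive scan over entries applying the three matching rules plus
    loose frameshift/nonsense categories; returns sorted entry ids."""
    hits = set()
    parsed = _parse_change(record.protein_change, record.mutation_class)
    for e in entries:
        if e.gene != record.gene:
            continue
        vc = e.variant_class
        if vc in ("missense_exact", "inframe_indel_exact"):
            if e.variant_spec == record.protein_change:
                hits.add(e.entry_id)
        elif vc == "missense_position":
            if record.mutation_class == "missense" and parsed is not None:
                m = re.match(r"^([A-Z])(\d+)$", e.variant_spec)
                if m and parsed[0] == m.group(1) and parsed[1] == int(m.group(2)):
                    hits.add(e.entry_id)
        elif vc in ("aa_range", "inframe_indel_range"):
            if parsed is None:
                continue
            m = re.match(r"^(\d+)-(\d+)(?::([a-z_]+))?$", e.variant_spec)
            if not m:
                continue
            start, end, sub = int(m.group(1)), int(m.group(2)), m.group(3)
            if vc == "aa_range" and sub is None:
                ok = record.mutation_class in ("missense", "inframe_del", "inframe_ins")
            else:
                ok = record.mutation_class == sub
            if ok and start <= parsed[1] <= end:
                hits.add(e.entry_id)
        elif vc in ("frameshift", "nonsense"):
            if record.mutation_class != vc or parsed is None:
                continue
            if e.variant_spec == "*" or e.variant_spec == str(parsed[1]):
                hits.add(e.entry_id)
    return sorted(hits)


def brute_force_resolve(
    record: OracleRecord, entries: list[OracleEntry], match_ids: list[int]
) -> dict | None:
    """Literal re-statement of the resolution rules on matched entries."""
    matched = [e for e in entries if e.entry_id in set(match_ids)]
    if not matched:
        return None
    effect = "sensitive" if any(e.effect == "sensitive" for e in matched) else "resistant"
    consistent = [e for e in matched if e.effect == effect]
    top = max(_EVIDENCE[e.evidence_level] for e in consistent)
    at_top = [e for e in consistent if _EVIDENCE[e.evidence_level] == top]
    specific = any(e.tumor_type == record.cancer_type for e in at_top)
    return {
        "effect": effect,
        "evidence": top,
        "chosen_drug": min(e.drug for e in at_top),
        "specificity": "cancer_type_specific" if specific else "non_specific",
        "all_matches": tuple(sorted(match_ids)),
    }


# --------------------------------------------------------------------------
# proximity clustering
# --------------------------------------------------------------------------


def reference_cluster(
    distances: dict[tuple[int, int], float],
    mutated: list[int],
    recurrence: dict[int, int],
    p_threshold: float = 0.05,
    distance_limit: float = 5.0,
    radius_limit: float = 5.0,
) -> list[tuple[frozenset, int, int]]:
    """Literal recursion: explicit pair p-values, DFS components,
    Floyd-Warshall shortest paths, and the stated centroid rule.

    Returns (member set, centroid, generation) tuples.
    """
    background = list(distances.values())
    n_bg = len(background)

    def lookup(i: int, j: int) -> float | None:
        return distances.get((min(i, j), max(i, j)))

    sig = []
    muts = sorted(set(mutated))
    for i, j in itertools.combinations(muts, 2):
        d = lookup(i, j)
        if d is None or d >= distance_limit:
            continue
        p = sum(1 for b in background if b <= d) / n_bg
        if p < p_threshold:
            sig.append((i, j, d))

    results: list[tuple[frozenset, int, int]] = []
    pairs = sig
    generation = 0
    while pairs:
        nodes = sorted({v for i, j, _ in pairs for v in (i, j)})
        adj: dict[int, set[int]] = {v: set() for v in nodes}
        for i, j, _ in pairs:
            adj[i].add(j)
            adj[j].add(i)
        seen: set[int] = set()
        components = []
        for v in nodes:
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            components.append(comp)

        leftover: set[int] = set()
        for comp in sorted(components, key=min):
            members = sorted(comp)
            idx = {m: k for k, m in enumerate(members)}
            n = len(members)
            dist = [[math.inf] * n for _ in range(n)]
            for k in range(n):
                dist[k][k] = 0.0
            for i, j, d in pairs:
                if i in comp and j in comp:
                    a, b = idx[i], idx[j]
                    dist[a][b] = min(dist[a][b], d)
                    dist[b][a] = min(dist[b][a], d)
            for k in range(n):
                for a in range(n):
                    for b in range(n):
                        if dist[a][k] + dist[k][b] < dist[a][b]:
                            dist[a][b] = dist[a][k] + dist[k][b]
            max_rec = max(recurrence.get(m, 0) for m in members)
            candidates = [m for m in members if recurrence.get(m, 0) == max_rec]
            if len(candidates) > 1:
                def weighted(m: int) -> float:
                    return sum(
                        recurrence.get(o, 0) * dist[idx[m]][idx[o]]
                        for o in members
                        if o != m
                    )
                candidates.sort(key=lambda m: (weighted(m), m))
            centroid = candidates[0]
            inside = frozenset(
                m for m in members if dist[idx[centroid]][idx[m]] <= radius_limit
            )
            results.append((inside, centroid, generation))
            leftover |= comp - inside
        pairs = [(i, j, d) for i, j, d in pairs if i in leftover and j in leftover]
        generation += 1
    return results


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------


def exact_mannwhitney_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free data)."""
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "enumeration oracle needs tie-free data"
    m = len(x)

    def u_of(xs: set[int]) -> int:
        # U = number of (x, y) pairs with x > y, over rank positions
        return sum(sum(1 for q in range(len(combined)) if q not in xs and q < p) for p in xs)

    positions = {combined.index(v) for v in x}
    u_obs = u_of(positions)
    total = 0
    cdf = 0
    sf = 0
    for subset in itertools.combinations(range(len(combined)), m):
        u = u_of(set(subset))
        total += 1
        if u <= u_obs:
            cdf += 1
        if u >= u_obs:
            sf += 1
    return min(1.0, 2 * min(cdf / total, sf / total))


def fisher_exact_p(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p by hypergeometric-sum enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def log_comb(n_: int, k_: int) -> float:
        return (
            math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)
        )

    def pmf(k: int) -> float:
        return math.exp(
            log_comb(col1, k) + log_comb(n - col1, row1 - k) - log_comb(n, row1)
        )

    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9)))


def bh_qvalues(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, literal definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvalues[i] * m / rank_from_end)
        q[i] = val
        prev = val
    return q


def ols_slope_intercept(x: list[float], y: list[float]) -> tuple[float, float]:
    """Closed-form normal equations."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    return slope, my - slope * mx
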