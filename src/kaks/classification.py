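"""Evolutionary-rate gene classes and the cross-species shared-gene network.

Genes are sorted by Ka (NA treated as 0, since undefined estimates almost
always come from identical pairs) and the lowest, middle and highest 10%
labelled slow-, intermediately- and fast-evolving.  Between species, the
fraction of shared genes that fall in the same class gives a normalized
association coefficient, from which a species network is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

__all__ = [
    "classify_by_ka",
    "shared_class_counts",
    "build_species_network",
    "NetworkEdge",
]


def classify_by_ka(genes, cutoff: float = 0.10, species_id: str | None = None) -> pd.DataFrame:
    """Label genes slow/intermediate/fast by Ka rank.

    ``genes`` is an iterable of (gene_id, ka) with NaN/None marking NA,
    which is mapped to 0 before sorting.  With k = floor(cutoff * n):
    slow = ranks 1..k, fast = the top k ranks, intermediate = the k genes
    centered on the median rank; everything else is unclassified.
    """
    items = [(g, 0.0 if ka is None or (isinstance(ka, float) and math.isnan(ka)) else float(ka))
             for g, ka in genes]
    n = len(items)
    ids = [g for g, _ in items]
    if len(set(ids)) != n:
        raise ValueError("duplicate gene_ids")
    k = int(math.floor(cutoff * n))
    if k < 1:
        raise ValueError(f"cutoff {cutoff} selects zero genes from n={n}")
    if n < 3 * k:
        raise ValueError(f"n={n} too small for three disjoint classes of size k={k}")
    items.sort(key=lambda x: (x[1], x[0]))
    mid_start = math.ceil((n - k) / 2)  # 0-based start of the centered window
    rows = []
    for rank0, (gene, ka) in enumerate(items):
        rank = rank0 + 1
        if rank <= k:
            cls = "slow"
        elif rank > n - k:
            cls = "fast"
        elif mid_start < rank <= mid_start + k:
            cls = "intermediate"
        else:
            cls = "unclassified"
        row = {"gene_id": gene, "ka": ka, "rank": rank, "class": cls}
        if species_id is not None:
            row = {"species_id": species_id, **row}
        rows.append(row)
    return pd.DataFrame(rows)


def _class_set(table: pd.DataFrame, cls: str) -> set:
    return set(table.loc[table["class"] == cls, "gene_id"])


def shared_class_counts(tables: dict, cls: str, species_subset=None) -> int:
    """Number of genes carrying class ``cls`` in every listed species."""
    if species_subset is None:
        species_subset = list(tables)
    unknown = [s for s in species_subset if s not in tables]
    if unknown:
        raise ValueError(f"unknown species {unknown}")
    sets = [_class_set(tables[s], cls) for s in species_subset]
    return len(set.intersection(*sets)) if sets else 0


@dataclass(frozen=True)
class NetworkEdge:
    species_a: str
    species_b: str
    cls: str  # fast | slow | both
    coefficient: float
    retained: bool


def build_species_network(tables: dict, retention: str = "per_species_top2") -> list[NetworkEdge]:
    """Species network from shared fast/slow-evolving genes.

    For each unordered species pair, the coefficient of a class is the
    number of shared genes in that class in both species divided by the
    total number of shared genes; the 'both' coefficient is the fast and
    slow coefficients summed.  Retention modes:

    - ``per_species_top2``: for each class, each species marks its two
      largest incident coefficients, and an edge is retained if either
      endpoint marked it.
    - ``per_pair_top_class``: each pair retains only its largest-class
      edge.

    Pairs sharing no genes contribute no edges.
    """
    if len(tables) < 3:
        raise ValueError("need at least three species")
    if retention not in ("per_species_top2", "per_pair_top_class"):
        raise ValueError(f"unknown retention mode {retention!r}")
    genes = {s: set(t["gene_id"]) for s, t in tables.items()}
    fast = {s: _class_set(t, "fast") for s, t in tables.items()}
    slow = {s: _class_set(t, "slow") for s, t in tables.items()}

    raw: list[dict] = []
    for a, b in combinations(sorted(tables), 2):
        shared = genes[a] & genes[b]
        if not shared:
            continue
        cf = len(fast[a] & fast[b] & shared) / len(shared)
        cs = len(slow[a] & slow[b] & shared) / len(shared)
        for cls, coef in (("fast", cf), ("slow", cs), ("both", cf + cs)):
            raw.append({"a": a, "b": b, "cls": cls, "coef": coef})

    retained_keys = set()
    if retention == "per_species_top2":
        for cls in ("fast", "slow", "both"):
            incident: dict[str, list] = {}
            for e in raw:
                if e["cls"] != cls:
                    continue
                for sp in (e["a"], e["b"]):
                    incident.setdefault(sp, []).append(e)
            for sp, edges in incident.items():
                edges.sort(key=lambda e: (-e["coef"], e["a"], e["b"]))
                for e in edges[:2]:
                    retained_keys.add((e["a"], e["b"], e["cls"]))
    else:
        pairs: dict[tuple, list] = {}
        for e in raw:
            if e["cls"] == "both":
                continue
            pairs.setdefault((e["a"], e["b"]), []).append(e)
        for (a, b), edges in pairs.items():
            best = max(edges, key=lambda e: (e["coef"], e["cls"]))
            retained_keys.add((a, b, best["cls"]))

    return [
        NetworkEdge(e["a"], e["b"], e["cls"], e["coef"], (e["a"], e["b"], e["cls"]) in retained_keys)
        for e in raw
    ]


def edges_to_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_a": e.species_a,
                "species_b": e.species_b,
                "class": e.cls,
                "coefficient": e.coefficient,
                "retained": e.retained,
            }
            for e in edges
        ]
    )


def to_networkx(edges, retained_only: bool = True):
    """Export retained edges as a networkx Graph (edge attrs: class,
    coefficient) for downstream viewers."""
    import networkx as nx

    g = nx.MultiGraph()
    for e in edges:
        if retained_only and not e.retained:
            continue
        g.add_edge(e.species_a, e.species_b, cls=e.cls, coefficient=e.coefficient)
    return g
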