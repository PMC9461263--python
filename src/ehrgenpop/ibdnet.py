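"""IBD sharing networks and fine-scale community detection.

Pairwise segments are summed into one weighted edge per pair of
individuals (total genome-wide cM), close relatives are removed using the
kinship table, and communities are found with InfoMap (the map-equation
flow algorithm) on the weighted undirected graph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .genoqc import DEGREE3_CUTOFF


def total_pairwise_ibd(segments: pd.DataFrame) -> pd.DataFrame:
    """Sum segment cM per unordered pair -> edge list (id1, id2, total_cm).

    Pairs with no segments are simply absent. Zero or negative segment
    lengths are rejected.
    """
    if len(segments) == 0:
        return pd.DataFrame(columns=["id1", "id2", "total_cm"])
    if (segments["cm"] <= 0).any():
        raise ValueError("segment lengths must be positive cM")
    a = segments["id1"].astype(str)
    b = segments["id2"].astype(str)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    if (lo == hi).any():
        raise ValueError("self-segments (id1 == id2) are not allowed")
    totals = (
        pd.DataFrame({"id1": lo, "id2": hi, "cm": segments["cm"].to_numpy()})
        .groupby(["id1", "id2"], as_index=False)["cm"]
        .sum()
        .rename(columns={"cm": "total_cm"})
    )
    return totals


def filter_relatives(
    edges: pd.DataFrame,
    kin: pd.DataFrame,
    phi_cutoff: float = DEGREE3_CUTOFF,
) -> pd.DataFrame:
    """Drop edges between pairs related at phi >= cutoff (default: third
    degree or closer). Output is a subset of the input rows."""
    related = kin[kin["phi"] >= phi_cutoff]
    bad = {
        tuple(sorted(p)) for p in zip(related["id1"].astype(str), related["id2"].astype(str))
    }
    keys = [tuple(sorted(p)) for p in zip(edges["id1"], edges["id2"])]
    keep = [k not in bad for k in keys]
    return edges[keep].reset_index(drop=True)


@dataclass
class CommunityAssignment:
    membership: pd.Series  # node id -> community id
    sizes: pd.Series  # community id -> node count
    codelength: float  # map-equation score of the partition


def detect_communities(edges: pd.DataFrame, seed: int = 0) -> CommunityAssignment:
    """InfoMap communities on the weighted undirected sharing graph."""
    if len(edges) == 0:
        raise ValueError("empty graph: no edges to cluster")
    nodes = sorted(set(edges["id1"]) | set(edges["id2"]))
    index = {n: i for i, n in enumerate(nodes)}
    graph = ig.Graph(
        n=len(nodes),
        edges=[(index[a], index[b]) for a, b in zip(edges["id1"], edges["id2"])],
        edge_attrs={"weight": edges["total_cm"].astype(float).tolist()},
    )
    ig.set_random_number_generator(random.Random(seed))
    clustering = graph.community_infomap(edge_weights="weight")
    ig.set_random_number_generator(random)
    membership = pd.Series(clustering.membership, index=nodes, name="community_id")
    sizes = membership.value_counts().sort_index()
    return CommunityAssignment(
        membership=membership, sizes=sizes, codelength=float(clustering.codelength)
    )


def summarize_communities(
    assign: CommunityAssignment,
    edges: pd.DataFrame,
    min_size: int = 100,
    min_degree: int = 30,
    strict_size: bool = True,
    strict_degree: bool = False,
) -> pd.DataFrame:
    """Reporting view: keep communities with size > ``min_size`` (strict by
    default) and nodes with degree >= ``min_degree`` on the filtered graph
    (``strict_degree=True`` switches to strict >). The assignment itself is
    unchanged. Degree is computed on the post-relative-filter edge list."""
    degree = pd.concat(
        [edges.groupby("id1").size(), edges.groupby("id2").size()], axis=1
    ).fillna(0).sum(axis=1)
    out = assign.membership.rename("community_id").to_frame()
    out["degree"] = degree.reindex(out.index).fillna(0).astype(int)
    size_ok = (
        assign.sizes > min_size if strict_size else assign.sizes >= min_size
    )
    kept_comms = set(size_ok[size_ok].index)
    deg_ok = out["degree"] > min_degree if strict_degree else out["degree"] >= min_degree
    keep = out["community_id"].isin(kept_comms) & deg_ok
    report = out[keep].reset_index(names="sample_id")
    return report
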