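"""Clustering, ranking and type-specificity calls for DAN upstream neurons.

USNs are grouped into clusters (by annotation type, or by morphology for
SEZ-associated neurons), the cluster x DAN percentage-dendritic-input
matrix is assembled, clusters are ranked by combined input strength to a
named DAN type selection, a display threshold is selected by a silhouette
scan over binarised connectivity profiles, and cluster-to-DAN-type
connections are classified as exclusive to one compartment (beta'2, gamma4
or gamma5) or shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .connectome import (
    COMPARTMENT_GROUPS,
    DAN_TYPE_INFO,
    FLAG_TYPE,
    DanTypeCatalog,
)

# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UsnCluster:
    cluster_id: str
    member_ids: tuple[int, ...]
    origin: str  # "by_type" | "by_morphology"

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"cluster {self.cluster_id} has no members")


def cluster_by_type(usns: pd.DataFrame) -> list[UsnCluster]:
    """One cluster per distinct type label among non-SEZ USNs.

    USNs with an empty type label form singleton clusters. SEZ-associated
    neurons are not clustered here; route them to
    :func:`cluster_by_morphology`.
    """
    sez = usns.get("sez_associated")
    body = usns if sez is None else usns.loc[~sez.astype(bool)]
    clusters: list[UsnCluster] = []
    labels = body["type_label"].fillna("").astype(str)
    for label, grp in body.groupby(labels):
        ids = tuple(sorted(grp["neuron_id"].astype(int)))
        if label == "":
            clusters.extend(
                UsnCluster(f"usn_{i}", (i,), "by_type") for i in ids
            )
        else:
            clusters.append(UsnCluster(str(label), ids, "by_type"))
    return sorted(clusters, key=lambda c: c.cluster_id)


def cluster_by_morphology(
    features: pd.DataFrame,
    cut: float,
    *,
    hemisphere: pd.Series | None = None,
    mirror_axis: str | int | None = None,
    max_cluster_size: int | None = 34,
) -> list[UsnCluster]:
    """Agglomerative clustering of morphology feature vectors.

    Manhattan (L1) distance with the average linkage criterion, cut at the
    given dendrogram height. Left-hemisphere vectors are mirrored onto the
    right by sign-flipping the designated mediolateral axis column before
    distances are computed. Deterministic for fixed input.

    When ``max_cluster_size`` is set and the cut produces a larger cluster,
    the cut height is halved until every cluster fits (the fine-granularity
    fallback); pass ``None`` to disable.
    """
    X = features.to_numpy(dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D table of equal-length vectors")
    ids = list(features.index.astype(int))
    if hemisphere is not None and mirror_axis is not None:
        col = (
            list(features.columns).index(mirror_axis)
            if isinstance(mirror_axis, str)
            else int(mirror_axis)
        )
        X = X.copy()
        left = (hemisphere.reindex(features.index).astype(str) == "left").to_numpy()
        X[left, col] *= -1.0
    if len(ids) == 1:
        return [UsnCluster("morph_1", (ids[0],), "by_morphology")]
    Z = linkage(pdist(X, metric="cityblock"), method="average")
    height = float(cut)
    while True:
        assign = fcluster(Z, t=height, criterion="distance")
        sizes = np.bincount(assign)
        if max_cluster_size is None or sizes.max() <= max_cluster_size or height <= 0:
            break
        height /= 2.0
    clusters = []
    for k in np.unique(assign):
        members = tuple(sorted(i for i, a in zip(ids, assign) if a == k))
        clusters.append(UsnCluster(f"morph_{k}", members, "by_morphology"))
    return sorted(clusters, key=lambda c: c.cluster_id)


# ---------------------------------------------------------------------------
# Cluster x DAN input matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterInputMatrix:
    """Summed percentage dendritic input per (USN cluster, individual DAN).

    ``values``: DataFrame indexed by cluster_id with one column per DAN id.
    ``dan_types``: Series mapping DAN id (column) -> type code.
    ``members``: cluster_id -> member USN ids.
    """

    values: pd.DataFrame
    dan_types: pd.Series
    members: Mapping[str, tuple[int, ...]]


def build_matrix(
    fractions: pd.DataFrame,
    clusters: Sequence[UsnCluster],
    catalog: DanTypeCatalog,
) -> ClusterInputMatrix:
    """Sum member percentages into a cluster x DAN matrix.

    Every USN appearing in the fraction table must belong to exactly one
    cluster. Columns are the catalog DANs; column sums equal 100 for any
    DAN with nonzero included input.
    """
    assign: dict[int, str] = {}
    for c in clusters:
        for m in c.member_ids:
            if m in assign:
                raise ValueError(f"USN {m} belongs to multiple clusters")
            assign[m] = c.cluster_id
    missing = set(fractions["usn_id"].astype(int)) - set(assign)
    if missing:
        raise ValueError(f"USN {min(missing)} is absent from every cluster")

    f = fractions.assign(cluster_id=fractions["usn_id"].map(assign))
    mat = f.pivot_table(
        index="cluster_id", columns="dan_id", values="percent", aggfunc="sum", fill_value=0.0
    )
    dan_ids = sorted(catalog.dan_ids)
    mat = mat.reindex(index=sorted(c.cluster_id for c in clusters), columns=dan_ids, fill_value=0.0)
    type_of = catalog.type_of()
    dan_types = pd.Series({d: type_of[d] for d in dan_ids}, name="dan_type")
    return ClusterInputMatrix(
        values=mat.astype(float),
        dan_types=dan_types,
        members={c.cluster_id: c.member_ids for c in clusters},
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedClusters:
    """Clusters ordered by combined input strength to a DAN type selection."""

    table: pd.DataFrame  # columns: cluster_id, strength (non-increasing)
    selection: tuple[str, ...]
    n: int
    members: Mapping[str, tuple[int, ...]]

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.table["cluster_id"])

    @property
    def usn_ids(self) -> set[int]:
        return {m for c in self.cluster_ids for m in self.members[c]}


def rank_top(
    matrix: ClusterInputMatrix, selection: Iterable[str], n: int
) -> RankedClusters:
    """Rank clusters by summed input to all DANs of the selected types.

    Descending by strength; ties broken by ascending cluster id. Returns
    the top ``min(n, n_clusters)`` entries.
    """
    sel = tuple(selection)
    if not sel:
        raise ValueError("selection must be non-empty")
    if n <= 0:
        raise ValueError("n must be positive")
    cols = [d for d in matrix.values.columns if matrix.dan_types[d] in sel]
    strength = matrix.values[cols].sum(axis=1)
    tab = (
        strength.rename("strength")
        .rename_axis("cluster_id")
        .reset_index()
        .sort_values(["strength", "cluster_id"], ascending=[False, True], ignore_index=True)
        .head(n)
    )
    members = {c: matrix.members[c] for c in tab["cluster_id"]}
    return RankedClusters(table=tab, selection=sel, n=n, members=members)


def compare_topsets(a: RankedClusters, b: RankedClusters) -> dict:
    """Overlap report between two top-N cluster rankings.

    Counts shared and side-unique clusters, and the USNs contained in each
    category (union of member lists).
    """
    sa, sb = set(a.cluster_ids), set(b.cluster_ids)
    shared = sa & sb
    only_a, only_b = sa - sb, sb - sa

    def usns(ranked: RankedClusters, ids: set[str]) -> set[int]:
        return {m for c in ids for m in ranked.members[c]}

    return {
        "shared_clusters": len(shared),
        "shared_usns": len(usns(a, shared)),
        "unique_clusters_a": len(only_a),
        "unique_usns_a": len(usns(a, only_a)),
        "unique_clusters_b": len(only_b),
        "unique_usns_b": len(usns(b, only_b)),
    }


# ---------------------------------------------------------------------------
# Thresholding and type-specificity calls
# ---------------------------------------------------------------------------


def apply_edge_threshold(matrix: ClusterInputMatrix, tau: float) -> pd.DataFrame:
    """Cluster-to-DAN edges at or above ``tau`` percent (inclusive).

    Returns a long table (cluster_id, dan_id, dan_type, percent); zero
    entries are never emitted, so ``tau=0`` keeps all nonzero edges.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    long = (
        matrix.values.rename_axis(index="cluster_id", columns="dan_id")
        .stack()
        .rename("percent")
        .reset_index()
    )
    long = long.loc[(long["percent"] >= tau) & (long["percent"] > 0)]
    long["dan_type"] = long["dan_id"].map(matrix.dan_types)
    return long.sort_values(["cluster_id", "dan_id"], ignore_index=True)


def classify_type_connectivity(
    edges: pd.DataFrame,
    catalog: DanTypeCatalog,
    coverage: float = 0.2,
    *,
    groups: Mapping[str, tuple[str, ...]] = COMPARTMENT_GROUPS,
    flag_type: str = FLAG_TYPE,
) -> pd.DataFrame:
    """Call cluster-to-DAN-type connections from thresholded edges.

    A cluster is connected to a DAN type when its surviving edges reach at
    least ``coverage`` (default 20%, inclusive) of the neurons constituting
    that type. Exclusivity is evaluated over the beta'2 / gamma4 / gamma5
    compartment groups; connectivity to the gamma4<gamma1gamma2 type is
    recorded as a separate flag.

    Returns one row per cluster: per-group booleans, ``exclusive_to`` (the
    single connected group, else None), ``exclusivity`` in
    {"exclusive_to_one_type", "shared", "none"} and the flag-type boolean.
    """
    known = set(catalog.type_codes)
    seen = set(edges["dan_type"].unique()) if len(edges) else set()
    if seen - known:
        raise ValueError(f"unknown DAN type in edge list: {sorted(seen - known)}")

    covered = (
        edges.groupby(["cluster_id", "dan_type"])["dan_id"].nunique()
        if len(edges)
        else pd.Series(dtype=int)
    )
    rows = []
    for cluster_id in sorted(edges["cluster_id"].unique()) if len(edges) else []:
        conn_types = set()
        for t in known:
            n_cov = int(covered.get((cluster_id, t), 0))
            if catalog.member_count(t) and n_cov / catalog.member_count(t) >= coverage:
                conn_types.add(t)
        conn_groups = {g for g, ts in groups.items() if conn_types & set(ts)}
        row = {"cluster_id": cluster_id}
        for g in groups:
            row[g] = g in conn_groups
        row["exclusive_to"] = next(iter(conn_groups)) if len(conn_groups) == 1 else None
        row["exclusivity"] = (
            "exclusive_to_one_type"
            if len(conn_groups) == 1
            else ("shared" if conn_groups else "none")
        )
        row["gamma4g1g2_flag"] = flag_type in conn_types
        row["connected_types"] = ",".join(sorted(conn_types))
        rows.append(row)
    cols = ["cluster_id", *groups, "exclusive_to", "exclusivity", "gamma4g1g2_flag", "connected_types"]
    return pd.DataFrame(rows, columns=cols)


def specificity_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Tally the connectivity-pattern classes used in the network map."""
    if not len(calls):
        return {}
    out = {
        "exclusive_bp2": int((calls["exclusive_to"] == "bp2").sum()),
        "exclusive_g4": int((calls["exclusive_to"] == "g4").sum()),
        "exclusive_g5": int((calls["exclusive_to"] == "g5").sum()),
        "shared_bp2_g4": int((calls["bp2"] & calls["g4"]).sum()),
        "shared_bp2_g4_g5": int((calls["bp2"] & calls["g4"] & calls["g5"]).sum()),
    }
    return out


# ---------------------------------------------------------------------------
# Silhouette threshold scan
# ---------------------------------------------------------------------------

DEFAULT_GRID = np.round(np.arange(0.1, 5.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class ThresholdScanResult:
    table: pd.DataFrame  # columns: tau, score, flagged
    selected_threshold: float


def silhouette_threshold_scan(
    matrix: ClusterInputMatrix,
    grid: np.ndarray | None = None,
    *,
    profile: str = "binary",
    metric: str = "manhattan",
) -> ThresholdScanResult:
    """Select the connection threshold that best reproduces known DAN types.

    For each candidate threshold the matrix is binarised (or masked, with
    ``profile="continuous"``) and each DAN is represented by its upstream
    connectivity profile over clusters. The mean silhouette coefficient of
    the known DAN type labels under Manhattan distance scores how well the
    types are reproduced; the selected threshold is the smallest grid value
    attaining the maximum score.

    Thresholds at which some DAN has an all-zero profile are scored but
    flagged; if every threshold is flagged the scan fails.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    labels = matrix.dan_types.reindex(matrix.values.columns).to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("silhouette scan needs at least two DAN type labels")
    V = matrix.values.to_numpy(dtype=float)  # clusters x dans
    rows = []
    for tau in grid:
        mask = V >= tau
        X = (mask.T.astype(float) if profile == "binary" else np.where(mask, V, 0.0).T)
        flagged = bool((X.sum(axis=1) == 0).any())
        score = float(silhouette_score(X, labels, metric=metric))
        if not np.isfinite(score):  # degenerate: all profiles identical
            score, flagged = -1.0, True
        rows.append({"tau": float(tau), "score": score, "flagged": flagged})
    tab = pd.DataFrame(rows)
    if tab["flagged"].all():
        raise ValueError("every threshold leaves some DAN with an all-zero profile")
    best = tab["score"].max()
    selected = float(tab.loc[tab["score"] == best, "tau"].iloc[0])
    return ThresholdScanResult(table=tab, selected_threshold=selected)


# ---------------------------------------------------------------------------
# Heat-map specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeatmapSpec:
    values: pd.DataFrame        # row-normalised, rows in dendrogram leaf order
    row_order: tuple[str, ...]
    col_order: tuple[int, ...]  # DANs sorted by type
    linkage: np.ndarray
    flagged_rows: tuple[str, ...]


def heatmap_spec(matrix: ClusterInputMatrix, *, row_norm: str = "sum") -> HeatmapSpec:
    """Row-normalised heat map of cluster inputs, no thresholds applied.

    Rows are divided by their total (or maximum, with ``row_norm="max"``)
    and ordered by the leaf order of a Ward dendrogram on Manhattan
    distances; all-zero rows are left unnormalised and flagged. Columns are
    DANs sorted by type then id. The linkage record is returned so the
    ordering can be reproduced.
    """
    V = matrix.values.copy()
    totals = V.sum(axis=1) if row_norm == "sum" else V.max(axis=1)
    flagged = tuple(totals.index[totals == 0])
    nz = totals != 0
    V.loc[nz] = V.loc[nz].div(totals[nz], axis=0)
    if len(V) > 1:
        Z = linkage(pdist(V.to_numpy(), metric="cityblock"), method="ward")
        order = [V.index[i] for i in leaves_list(Z)]
    else:
        Z = np.empty((0, 4))
        order = list(V.index)
    type_order = {t: k for k, t in enumerate(DAN_TYPE_INFO)}
    cols = sorted(V.columns, key=lambda d: (type_order[matrix.dan_types[d]], d))
    return HeatmapSpec(
        values=V.loc[order, cols],
        row_order=tuple(order),
        col_order=tuple(cols),
        linkage=Z,
        flagged_rows=flagged,
    )


# ---------------------------------------------------------------------------
# Edge styling and network export
# ---------------------------------------------------------------------------

TRANSPARENCY_MIN = 49.0
TRANSPARENCY_MAX = 149.0
PERCENT_AT_MIN = 0.1
PERCENT_AT_MAX = 12.17


def edge_style(percent):
    """Map percentage input to display attributes.

    Transparency is an affine map from percent onto pixel values, anchored
    at 49 for 0.1% and 149 for 12.17%, clamped to that range; edge weight
    is the percent passed through unchanged.
    """
    p = np.asarray(percent, dtype=float)
    t = TRANSPARENCY_MIN + (TRANSPARENCY_MAX - TRANSPARENCY_MIN) * (
        (p - PERCENT_AT_MIN) / (PERCENT_AT_MAX - PERCENT_AT_MIN)
    )
    t = np.clip(t, TRANSPARENCY_MIN, TRANSPARENCY_MAX)
    if np.isscalar(percent) or np.ndim(percent) == 0:
        return {"percent": float(p), "weight": float(p), "transparency": float(t)}
    return pd.DataFrame({"percent": p, "weight": p, "transparency": t})


def export_network(
    edges: pd.DataFrame,
    catalog: DanTypeCatalog,
    path,
    *,
    calls: pd.DataFrame | None = None,
) -> None:
    """Write the thresholded cluster-to-DAN network as GraphML.

    DAN nodes carry their type and compartment subtype; cluster nodes carry
    their connectivity class and gamma4<gamma1gamma2 flag when calls are
    supplied. Edges carry percent, weight and transparency. Output is
    byte-stable for fixed input (nodes and edges are added in sorted
    order).
    """
    import networkx as nx

    G = nx.DiGraph()
    type_of = catalog.type_of()
    info = {t: DAN_TYPE_INFO.get(t, ("", None, 0)) for t in catalog.type_codes}
    for d in sorted(catalog.dan_ids):
        t = type_of[d]
        subtype, group, _ = info[t]
        G.add_node(
            f"dan_{d}", kind="dan", dan_type=t, subtype=subtype, group=group or FLAG_TYPE
        )
    call_ix = calls.set_index("cluster_id") if calls is not None and len(calls) else None
    for c in sorted(set(edges["cluster_id"])) if len(edges) else []:
        attrs = {"kind": "cluster"}
        if call_ix is not None and c in call_ix.index:
            attrs["connectivity_class"] = str(call_ix.loc[c, "exclusivity"])
            attrs["exclusive_to"] = str(call_ix.loc[c, "exclusive_to"])
            attrs["gamma4g1g2_flag"] = bool(call_ix.loc[c, "gamma4g1g2_flag"])
        G.add_node(f"cluster_{c}", **attrs)
    if len(edges):
        styled = edges.sort_values(["cluster_id", "dan_id"])
        for _, r in styled.iterrows():
            s = edge_style(r["percent"])
            G.add_edge(
                f"cluster_{r['cluster_id']}",
                f"dan_{int(r['dan_id'])}",
                percent=float(r["percent"]),
                weight=float(s["weight"]),
                transparency=float(s["transparency"]),
            )
    nx.write_graphml(G, path)
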