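"""Signaling pathways from chronologically ordered excitation clusters.

Excited residues are grouped into clusters — by contiguity in sequence, or
by a user-supplied secondary-structure annotation (residues on the same
beta strand, loop or helix form one cluster).  Each cluster's excitation
time is the earliest excitation time among its members, and ordering the
clusters by that time traces the route the perturbation energy takes
through the protein.  Anisotropy of the transport is quantified by relating
each residue's peak response to its hop distance (Dijkstra on the contact
graph) and Euclidean distance from the source, with the equilibrium
normalized cross-correlation to the source as the comparison observable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import dijkstra
from scipy.stats import spearmanr

from gnmflow.errors import DisconnectedNetworkError, InputError
from gnmflow.gnm import KirchhoffModel, ModeBasis, cross_correlation
from gnmflow.propagation import ExcitationTable
from gnmflow.structures import StructureModel

__all__ = [
    "ResidueCluster",
    "PathwayReport",
    "AnisotropyProfile",
    "cluster_excited",
    "order_pathway",
    "anisotropy_profile",
    "top_correlated",
]


@dataclass
class ResidueCluster:
    """A group of excited residues acting as one pathway node.

    ``excitation_time`` is the earliest member excitation time ("the time
    when any residue in the cluster was first excited"); the central residue
    is the member with the largest peak response metric.
    """

    members: List[int]
    central_residue: int
    excitation_time: float
    label: Optional[str] = None

    def __post_init__(self):
        if not self.members:
            raise InputError("cluster must have at least one member")
        if self.central_residue not in self.members:
            raise InputError("central residue must be a cluster member")


@dataclass
class PathwayReport:
    """Clusters in chronological order plus the directed earlier-to-later edges."""

    source_residue: int
    clusters: List[ResidueCluster]
    edges: List[tuple]            # (cluster_index_a, cluster_index_b)
    parameters: Dict

    def to_dict(self) -> Dict:
        return {
            "source_residue": self.source_residue,
            "clusters": [
                {
                    "members": list(map(int, c.members)),
                    "central_residue": int(c.central_residue),
                    "excitation_time": float(c.excitation_time),
                    "label": c.label,
                }
                for c in self.clusters
            ],
            "edges": [[int(a), int(b)] for a, b in self.edges],
            "parameters": self.parameters,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def edge_table(self) -> pd.DataFrame:
        """Flat TSV-ready edge list."""
        rows = []
        for a, b in self.edges:
            rows.append(
                {
                    "from_central": self.clusters[a].central_residue,
                    "to_central": self.clusters[b].central_residue,
                    "from_time": self.clusters[a].excitation_time,
                    "to_time": self.clusters[b].excitation_time,
                }
            )
        return pd.DataFrame(rows,
                            columns=["from_central", "to_central",
                                     "from_time", "to_time"])


@dataclass
class AnisotropyProfile:
    """Per-residue distances from the source and the associated observables."""

    source_residue: int
    shortest_path_length: np.ndarray   # (N,) integer hops on the contact graph
    euclidean_distance: np.ndarray     # (N,) Angstrom
    peak_metric: np.ndarray            # (N,) from the excitation table
    cross_correlation_to_source: np.ndarray  # (N,) normalized, in [-1, 1]
    rank_correlations: Dict            # Spearman rho of peak metric vs distances

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "serial": np.arange(len(self.shortest_path_length)),
                "shortest_path_length": self.shortest_path_length,
                "euclidean_distance": self.euclidean_distance,
                "peak_metric": self.peak_metric,
                "cross_correlation_to_source": self.cross_correlation_to_source,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")


def cluster_excited(table: ExcitationTable, gap_tolerance: int = 2,
                    annotations: Optional[Sequence[Optional[str]]] = None,
                    structure: Optional[StructureModel] = None
                    ) -> List[ResidueCluster]:
    """Group excited residues into clusters.

    Default mode: maximal runs of excited residues whose consecutive members
    are within ``gap_tolerance`` in sequence position (same chain); short
    unexcited interior gaps therefore do not split a secondary-structure
    element.  Annotation mode (``annotations`` given, one label per residue):
    excited residues sharing a label form one cluster, mirroring grouping by
    beta strand / loop / helix; unlabeled excited residues fall back to the
    run-based rule among themselves.

    Each cluster's central residue is the member with the largest peak
    metric (ties to the lowest serial).  Returns an empty list when nothing
    is excited.
    """
    if gap_tolerance < 1:
        raise InputError(f"gap_tolerance must be >= 1, got {gap_tolerance}")
    excited = list(np.flatnonzero(table.excited))
    if not excited:
        import warnings

        warnings.warn("no residues excited; empty cluster list", stacklevel=2)
        return []

    if structure is not None:
        chain_of = {i: structure.nodes[i].chain_id for i in excited}
        seqpos_of = {i: structure.nodes[i].residue_number for i in excited}
    else:
        chain_of = {i: "A" for i in excited}
        seqpos_of = {i: i for i in excited}

    def make_cluster(members: List[int], label: Optional[str]) -> ResidueCluster:
        peak = table.peak_metric[members]
        central = members[int(np.argmax(peak))]  # argmax ties -> lowest serial
        t_min = float(np.nanmin(table.excitation_time[members]))
        return ResidueCluster(members=sorted(members), central_residue=central,
                              excitation_time=t_min, label=label)

    def runs(serials: List[int]) -> List[List[int]]:
        groups: List[List[int]] = []
        for s in sorted(serials, key=lambda i: (chain_of[i], seqpos_of[i])):
            if (groups
                    and chain_of[groups[-1][-1]] == chain_of[s]
                    and seqpos_of[s] - seqpos_of[groups[-1][-1]] <= gap_tolerance):
                groups[-1].append(s)
            else:
                groups.append([s])
        return groups

    clusters: List[ResidueCluster] = []
    if annotations is not None:
        labeled: Dict[str, List[int]] = {}
        unlabeled: List[int] = []
        for s in excited:
            lab = annotations[s]
            if lab is None or lab == "":
                unlabeled.append(s)
            else:
                labeled.setdefault(str(lab), []).append(s)
        for lab in sorted(labeled, key=lambda l: min(labeled[l])):
            clusters.append(make_cluster(labeled[lab], lab))
        for group in runs(unlabeled):
            clusters.append(make_cluster(group, None))
    else:
        for group in runs(excited):
            clusters.append(make_cluster(group, None))
    return sorted(clusters, key=lambda c: min(c.members))


def order_pathway(clusters: List[ResidueCluster], source: int,
                  structure: Optional[StructureModel] = None,
                  branches: Optional[List[List[int]]] = None,
                  parameters: Optional[Dict] = None) -> PathwayReport:
    """Order clusters chronologically into a signaling pathway.

    Clusters are sorted ascending by excitation time; ties are broken by the
    Euclidean distance of the central residue to the source (nearer first,
    requires ``structure``), then by central serial.  Directed edges connect
    consecutive clusters.  ``branches`` optionally partitions cluster
    indices (into the input list) into independently ordered arms — the
    branch split itself is a structural judgement supplied by the user, not
    computed here.
    """
    if structure is not None:
        src_pos = structure.nodes[source].position

        def dist(c: ResidueCluster) -> float:
            return float(np.linalg.norm(
                structure.nodes[c.central_residue].position - src_pos))
    else:
        def dist(c: ResidueCluster) -> float:
            return float(abs(c.central_residue - source))

    def sort_key(idx: int):
        c = clusters[idx]
        return (c.excitation_time, dist(c), c.central_residue)

    if branches is None:
        branch_list = [list(range(len(clusters)))]
    else:
        flat = [i for br in branches for i in br]
        if sorted(flat) != sorted(set(flat)) or any(
                not 0 <= i < len(clusters) for i in flat):
            raise InputError("branches must contain valid, non-repeating "
                             "cluster indices")
        branch_list = [list(br) for br in branches]

    order: List[int] = []
    edges: List[tuple] = []
    for br in branch_list:
        br_sorted = sorted(br, key=sort_key)
        order.extend(br_sorted)
        edges.extend(zip(br_sorted[:-1], br_sorted[1:]))

    # re-index clusters in the report's chronological order
    position = {old: new for new, old in enumerate(order)}
    return PathwayReport(
        source_residue=source,
        clusters=[clusters[i] for i in order],
        edges=[(position[a], position[b]) for a, b in edges],
        parameters=dict(parameters or {}),
    )


def shortest_path_lengths(kirchhoff: KirchhoffModel, source: int) -> np.ndarray:
    """Hop count from the source to every residue (Dijkstra, unit weights)."""
    adj = scipy.sparse.csr_matrix(kirchhoff.adjacency.astype(float))
    lengths = dijkstra(adj, directed=False, indices=source, unweighted=False)
    if np.any(np.isinf(lengths)):
        raise DisconnectedNetworkError(
            "some residues are unreachable from the source"
        )
    return lengths.astype(int)


def anisotropy_profile(kirchhoff: KirchhoffModel, structure: StructureModel,
                       table: ExcitationTable, modes: ModeBasis,
                       source: int) -> AnisotropyProfile:
    """Distance dependence of the response versus equilibrium correlations.

    For each residue: shortest path length to the source on the unweighted
    contact graph (Dijkstra), Euclidean C-alpha distance, the peak response
    metric and the normalized cross-correlation to the source.  Spearman
    rank correlations of the peak metric (and cross-correlation) with both
    distance measures summarize how isotropically the response decays.
    """
    if not 0 <= source < kirchhoff.n_residues:
        raise InputError(f"source {source} out of range")
    hops = shortest_path_lengths(kirchhoff, source)
    coords = structure.coords
    eucl = np.linalg.norm(coords - coords[source], axis=1)
    corr = cross_correlation(modes, normalized=True)[source]

    others = np.arange(kirchhoff.n_residues) != source
    rank = {
        "peak_vs_hops": float(spearmanr(table.peak_metric[others],
                                        hops[others]).statistic),
        "peak_vs_euclidean": float(spearmanr(table.peak_metric[others],
                                             eucl[others]).statistic),
        "correlation_vs_hops": float(spearmanr(corr[others],
                                               hops[others]).statistic),
        "correlation_vs_euclidean": float(spearmanr(corr[others],
                                                    eucl[others]).statistic),
    }
    return AnisotropyProfile(
        source_residue=source,
        shortest_path_length=hops,
        euclidean_distance=eucl,
        peak_metric=table.peak_metric.copy(),
        cross_correlation_to_source=corr,
        rank_correlations=rank,
    )


def top_correlated(modes: ModeBasis, source: int, fraction: float = 0.1,
                   ranking: str = "signed") -> List[int]:
    """Residues most dynamically coupled to the source at equilibrium.

    Selects the ``ceil(fraction * (N - 1))`` residues (source excluded) with
    the highest normalized cross-correlation to the source.  ``ranking``
    is ``signed`` (default) or ``absolute``; ties break to the lower serial.
    """
    if not 0 < fraction <= 1:
        raise InputError(f"fraction must be in (0, 1], got {fraction}")
    n = modes.n_residues
    if not 0 <= source < n:
        raise InputError(f"source {source} out of range")
    corr = cross_correlation(modes, normalized=True)[source]
    if ranking == "signed":
        score = corr
    elif ranking == "absolute":
        score = np.abs(corr)
    else:
        raise InputError(f"unknown ranking {ranking!r}")
    others = [i for i in range(n) if i != source]
    k = math.ceil(fraction * (n - 1))
    ranked = sorted(others, key=lambda i: (-score[i], i))
    return sorted(ranked[:k])
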