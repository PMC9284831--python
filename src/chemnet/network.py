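"""Chemical-protein interaction networks, biological distances and
hierarchical clustering of chemicals.

The per-chemical network profile is a score-weighted protein vector with
one-step propagation along protein-protein edges; the biological distance
between two chemicals is the cosine distance of their profiles. Profiles are
a concrete, testable surrogate for network-topology distance methods whose
exact formulas live elsewhere; the distance is swappable behind
:func:`build_profiles` / :func:`compute_distance_matrix`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ClusterLookupError,
    ConfigurationError,
    FormatError,
    InputError,
)

logger = logging.getLogger(__name__)

MAX_SCORE = 1000
LINKAGE_METHODS = ("single", "complete", "average")

CP_COLUMNS = ("chemical", "protein", "combined_score")
PP_COLUMNS = ("protein1", "protein2", "combined_score")


@dataclass
class InteractionGraph:
    """Scored chemical-protein and (undirected) protein-protein edges.

    Scores are integers in [0, 1000]. Protein pairs are stored with
    normalized ordering and no self-loops; duplicates collapse to the
    maximum score.
    """

    chem_protein: dict[tuple[str, str], int] = field(default_factory=dict)
    protein_protein: dict[tuple[str, str], int] = field(default_factory=dict)

    def add_chem_protein(self, chemical: str, protein: str, score: int) -> None:
        self._check_score(score)
        key = (chemical, protein)
        self.chem_protein[key] = max(score, self.chem_protein.get(key, 0))

    def add_protein_protein(self, p1: str, p2: str, score: int) -> None:
        self._check_score(score)
        if p1 == p2:
            return
        key = (p1, p2) if p1 < p2 else (p2, p1)
        self.protein_protein[key] = max(score, self.protein_protein.get(key, 0))

    @staticmethod
    def _check_score(score: int) -> None:
        if not (0 <= score <= MAX_SCORE):
            raise FormatError(f"score {score} outside [0, {MAX_SCORE}]")

    @property
    def chemicals(self) -> list[str]:
        return sorted({c for c, _ in self.chem_protein})

    @property
    def proteins(self) -> list[str]:
        out = {p for _, p in self.chem_protein}
        for a, b in self.protein_protein:
            out.add(a)
            out.add(b)
        return sorted(out)

    def chemical_edges(self, chemical: str) -> dict[str, int]:
        return {
            p: s for (c, p), s in self.chem_protein.items() if c == chemical
        }


def _read_edge_table(path, columns: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    score = frame[columns[-1]]
    if not pd.api.types.is_integer_dtype(score):
        raise FormatError(f"{path}: combined_score must be integer")
    return frame


def read_interactions(cp_path, pp_path, quality_cutoff: int = 150) -> InteractionGraph:
    """Read STITCH-style and STRING-style TSV edge tables.

    Edges below *quality_cutoff* are dropped; duplicate edges collapse to
    their maximum score.
    """
    cp = _read_edge_table(cp_path, CP_COLUMNS)
    pp = _read_edge_table(pp_path, PP_COLUMNS)
    graph = InteractionGraph()
    for row in cp.itertuples(index=False):
        score = int(getattr(row, "combined_score"))
        if score >= quality_cutoff:
            graph.add_chem_protein(str(row.chemical), str(row.protein), score)
    for row in pp.itertuples(index=False):
        score = int(getattr(row, "combined_score"))
        if score >= quality_cutoff:
            graph.add_protein_protein(str(row.protein1), str(row.protein2), score)
    return graph


def write_interactions(graph: InteractionGraph, cp_path, pp_path) -> None:
    """Write the graph back to STITCH/STRING-style TSV (sorted, diff-stable)."""
    cp = pd.DataFrame(
        [(c, p, s) for (c, p), s in sorted(graph.chem_protein.items())],
        columns=list(CP_COLUMNS),
    )
    pp = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(graph.protein_protein.items())],
        columns=list(PP_COLUMNS),
    )
    cp.to_csv(cp_path, sep="\t", index=False)
    pp.to_csv(pp_path, sep="\t", index=False)


@dataclass
class ChemicalProfile:
    """Sparse protein-weight vector for one chemical, L2-normalized."""

    chemical: str
    weights: dict[str, float]


def build_profiles(
    graph: InteractionGraph, propagation_weight: float = 0.5
) -> list[ChemicalProfile]:
    """Score-weighted protein profiles with one-step PPI propagation.

    profile(c)[p] = direct_score(c,p)/1000
                    + w * sum_q direct_score(c,q) * ppi_score(q,p) / 1000^2

    summed over one-step protein neighbours q of p, then L2-normalized.
    Chemicals with no qualifying edges are omitted with a warning.
    """
    if not (0.0 <= propagation_weight <= 1.0):
        raise ConfigurationError("propagation_weight must be in [0, 1]")
    ppi: dict[str, dict[str, int]] = {}
    for (a, b), s in graph.protein_protein.items():
        ppi.setdefault(a, {})[b] = s
        ppi.setdefault(b, {})[a] = s

    by_chemical: dict[str, dict[str, int]] = {}
    for (c, p), s in graph.chem_protein.items():
        by_chemical.setdefault(c, {})[p] = s

    profiles: list[ChemicalProfile] = []
    for chemical in sorted(by_chemical):
        direct = by_chemical[chemical]
        weights: dict[str, float] = {}
        for p, s in direct.items():
            weights[p] = weights.get(p, 0.0) + s / MAX_SCORE
        if propagation_weight > 0:
            for q, s in direct.items():
                for p, t in ppi.get(q, {}).items():
                    weights[p] = weights.get(p, 0.0) + (
                        propagation_weight * s * t / MAX_SCORE**2
                    )
        norm = float(np.sqrt(sum(v * v for v in weights.values())))
        if norm == 0:
            logger.warning("chemical %s has no qualifying edges; omitted", chemical)
            continue
        profiles.append(
            ChemicalProfile(chemical, {p: v / norm for p, v in weights.items()})
        )
    return profiles


@dataclass
class DistanceMatrix:
    """Symmetric chemical-chemical distances in [0, 1] with zero diagonal."""

    chemicals: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        n = len(self.chemicals)
        if self.matrix.shape != (n, n):
            raise InputError("distance matrix shape does not match chemical list")

    def index(self, chemical: str) -> int:
        return self.chemicals.index(chemical)


def compute_distance_matrix(profiles: list[ChemicalProfile]) -> DistanceMatrix:
    """Cosine distance (1 - cosine similarity) between all profile pairs."""
    if len(profiles) < 2:
        raise InputError("need at least 2 profiles for a distance matrix")
    profiles = sorted(profiles, key=lambda p: p.chemical)
    proteins = sorted({p for prof in profiles for p in prof.weights})
    index = {p: i for i, p in enumerate(proteins)}
    dense = np.zeros((len(profiles), len(proteins)), dtype=np.float64)
    for i, prof in enumerate(profiles):
        for p, v in prof.weights.items():
            dense[i, index[p]] = v
    condensed = pdist(dense, metric="cosine")
    matrix = squareform(np.clip(condensed, 0.0, 1.0))
    np.fill_diagonal(matrix, 0.0)
    return DistanceMatrix([p.chemical for p in profiles], matrix)


@dataclass
class Clustering:
    """Flat clusters cut from a linkage tree at one distance threshold.

    The linkage and leaf ordering are retained so cophenetic distances
    between clusters remain queryable after support filtering. Cluster ids
    are assigned by smallest member id, making outputs diff-stable.
    """

    threshold: float
    assignment: dict[str, int]
    linkage_matrix: np.ndarray
    leaves: list[str]
    discarded: list[str] = field(default_factory=list)

    @property
    def support(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for cid in self.assignment.values():
            counts[cid] = counts.get(cid, 0) + 1
        return counts

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignment.values()))

    def members(self, cluster_id: int) -> list[str]:
        out = [c for c, cid in self.assignment.items() if cid == cluster_id]
        if not out:
            raise ClusterLookupError(f"unknown cluster id {cluster_id}")
        return sorted(out)

    def linkage_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "leaves": self.leaves,
                "linkage": self.linkage_matrix.tolist(),
            }
        )


def hierarchical_cluster(
    dist: DistanceMatrix, threshold: float, linkage_method: str = "average"
) -> Clustering:
    """Average/single/complete-linkage clustering cut at *threshold*."""
    if linkage_method not in LINKAGE_METHODS:
        raise ConfigurationError(
            f"unknown linkage {linkage_method!r}; choose from {LINKAGE_METHODS}"
        )
    if not (0 < threshold):
        raise ConfigurationError("threshold must be positive")
    condensed = squareform(dist.matrix, checks=False)
    Z = linkage(condensed, method=linkage_method)
    raw = fcluster(Z, t=threshold, criterion="distance")
    # Stable ids: clusters ordered by their smallest member id.
    groups: dict[int, list[str]] = {}
    for chem, lab in zip(dist.chemicals, raw):
        groups.setdefault(int(lab), []).append(chem)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    assignment = {
        chem: cid for cid, members in enumerate(ordered) for chem in members
    }
    return Clustering(
        threshold=float(threshold),
        assignment=assignment,
        linkage_matrix=Z,
        leaves=list(dist.chemicals),
    )


def filter_by_support(clustering: Clustering, min_support: int) -> Clustering:
    """Keep clusters with support strictly greater than *min_support*.

    Chemicals from removed clusters are reported on ``discarded``.
    """
    support = clustering.support
    keep = {cid for cid, n in support.items() if n > min_support}
    assignment = {
        c: cid for c, cid in clustering.assignment.items() if cid in keep
    }
    discarded = sorted(
        c for c, cid in clustering.assignment.items() if cid not in keep
    )
    return Clustering(
        threshold=clustering.threshold,
        assignment=assignment,
        linkage_matrix=clustering.linkage_matrix,
        leaves=clustering.leaves,
        discarded=discarded,
    )


@dataclass
class ClusterAnnotation:
    """Protein sets assigned to clusters at one score cutoff."""

    proteins: dict[int, frozenset]
    cutoff_used: int


def annotate_cluster(
    clustering: Clustering, graph: InteractionGraph, score_cutoff: int
) -> ClusterAnnotation:
    """Union, over each cluster's members, of proteins bound with edge score
    >= *score_cutoff*. Lowering the cutoff never shrinks any protein set."""
    by_chemical: dict[str, dict[str, int]] = {}
    for (c, p), s in graph.chem_protein.items():
        by_chemical.setdefault(c, {})[p] = s
    out: dict[int, set] = {cid: set() for cid in clustering.cluster_ids}
    for chem, cid in clustering.assignment.items():
        edges = by_chemical.get(chem)
        if edges is None:
            logger.warning("chemical %s missing from graph; skipped", chem)
            continue
        out[cid].update(p for p, s in edges.items() if s >= score_cutoff)
    return ClusterAnnotation(
        proteins={cid: frozenset(ps) for cid, ps in out.items()},
        cutoff_used=score_cutoff,
    )


def cluster_distance(clustering: Clustering, cid_a: int, cid_b: int) -> float:
    """Cophenetic distance between two flat clusters on the retained tree.

    All member pairs across two flat clusters join at the same tree node, so
    one representative pair suffices.
    """
    if cid_a == cid_b:
        # validate existence
        clustering.members(cid_a)
        return 0.0
    a = clustering.members(cid_a)[0]
    b = clustering.members(cid_b)[0]
    coph = squareform(cophenet(clustering.linkage_matrix))
    ia = clustering.leaves.index(a)
    ib = clustering.leaves.index(b)
    return float(coph[ia, ib])
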