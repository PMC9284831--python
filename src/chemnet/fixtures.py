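"""Synthetic interaction networks and SMILES libraries with planted structure.

Planted-partition protein communities, cluster-specific chemical attachment
and motif-bearing molecule libraries make every downstream stage testable
without any database download. All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigurationError, SmilesParseError
from .network import InteractionGraph, write_interactions

logger = logging.getLogger(__name__)

#: Small substituents attached at random valence-legal positions.
SUBSTITUENT_ALPHABET = ("F", "Cl", "OC", "N", "CC")

DEFAULT_MOTIFS = (
    "c1ccccc1",          # benzene
    "C1CCNCC1",          # piperidine
    "c1ccsc1",           # thiophene
    "C1CCOC1",           # tetrahydrofuran
)


@dataclass
class FixtureSpec:
    """Parameters of the planted network + library generator."""

    n_proteins: int = 60
    n_communities: int = 4
    n_clusters: int = 4
    chemicals_per_cluster: tuple = (30, 30, 30, 30)
    intra_community_edge_prob: float = 0.3
    inter_community_edge_prob: float = 0.01
    chem_attach_count: int = 5
    noise_attach_count: int = 1
    score_range_high: tuple = (700, 1000)
    score_range_low: tuple = (150, 400)
    motif_per_cluster: tuple = DEFAULT_MOTIFS
    seed: int = 0

    def __post_init__(self):
        for name in ("n_proteins", "n_communities", "n_clusters", "chem_attach_count"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("intra_community_edge_prob", "inter_community_edge_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name}={p} is not a probability")
        if self.intra_community_edge_prob <= self.inter_community_edge_prob:
            raise ConfigurationError(
                "intra_community_edge_prob must exceed inter_community_edge_prob"
            )
        if len(self.chemicals_per_cluster) != self.n_clusters:
            raise ConfigurationError(
                "chemicals_per_cluster length must equal n_clusters"
            )
        if len(self.motif_per_cluster) != self.n_clusters:
            raise ConfigurationError("motif_per_cluster length must equal n_clusters")
        if any(n <= 0 for n in self.chemicals_per_cluster):
            raise ConfigurationError("chemicals_per_cluster entries must be positive")
        if self.n_clusters > self.n_communities:
            raise ConfigurationError("n_clusters must not exceed n_communities")
        for lo, hi in (self.score_range_high, self.score_range_low):
            if not (0 <= lo <= hi <= 1000):
                raise ConfigurationError("score ranges must satisfy 0 <= lo <= hi <= 1000")


@dataclass
class GroundTruth:
    """Planted labels: chemical -> cluster, protein -> community."""

    chemical_cluster: dict[str, int] = field(default_factory=dict)
    protein_community: dict[str, int] = field(default_factory=dict)

    @property
    def chemicals(self) -> list[str]:
        return sorted(self.chemical_cluster)


def _community_blocks(spec: FixtureSpec) -> list[list[str]]:
    names = [f"P{i:04d}" for i in range(spec.n_proteins)]
    blocks: list[list[str]] = [[] for _ in range(spec.n_communities)]
    for i, name in enumerate(names):
        blocks[i % spec.n_communities].append(name)
    return blocks


def generate_network(spec: FixtureSpec) -> tuple[InteractionGraph, GroundTruth]:
    """Planted-partition protein network plus cluster-specific chemical
    attachment.

    Protein pairs inside a community are linked with
    ``intra_community_edge_prob`` (scores from the high range), pairs across
    communities with ``inter_community_edge_prob`` (low range). Each
    chemical of cluster k binds ``chem_attach_count`` proteins of community
    k with high scores plus ``noise_attach_count`` off-community proteins
    with low scores. Deterministic per spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = _community_blocks(spec)
    truth = GroundTruth()
    for com, block in enumerate(blocks):
        for protein in block:
            truth.protein_community[protein] = com

    graph = InteractionGraph()
    proteins = sorted(truth.protein_community)
    lo_h, hi_h = spec.score_range_high
    lo_l, hi_l = spec.score_range_low
    for i, p1 in enumerate(proteins):
        for p2 in proteins[i + 1:]:
            same = truth.protein_community[p1] == truth.protein_community[p2]
            prob = (
                spec.intra_community_edge_prob
                if same
                else spec.inter_community_edge_prob
            )
            if rng.random() < prob:
                lo, hi = (lo_h, hi_h) if same else (lo_l, hi_l)
                graph.add_protein_protein(p1, p2, int(rng.integers(lo, hi + 1)))

    chem_counter = 0
    for cluster, count in enumerate(spec.chemicals_per_cluster):
        block = blocks[cluster]
        off_block = [p for p in proteins if truth.protein_community[p] != cluster]
        if spec.chem_attach_count > len(block):
            raise ConfigurationError(
                "chem_attach_count exceeds community size; shrink it or add proteins"
            )
        for _ in range(count):
            chemical = f"C{chem_counter:05d}"
            chem_counter += 1
            truth.chemical_cluster[chemical] = cluster
            targets = rng.choice(len(block), size=spec.chem_attach_count, replace=False)
            for t in targets:
                graph.add_chem_protein(
                    chemical, block[t], int(rng.integers(lo_h, hi_h + 1))
                )
            if spec.noise_attach_count > 0 and off_block:
                noise = rng.choice(
                    len(off_block),
                    size=min(spec.noise_attach_count, len(off_block)),
                    replace=False,
                )
                for t in noise:
                    graph.add_chem_protein(
                        chemical, off_block[t], int(rng.integers(lo_l, hi_l + 1))
                    )
    return graph, truth


def _attach_substituent(mol: Chem.Mol, sub_smiles: str, atom_idx: int) -> Chem.Mol | None:
    sub = Chem.MolFromSmiles(sub_smiles)
    combined = Chem.RWMol(Chem.CombineMols(mol, sub))
    combined.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:  # valence violation: caller retries elsewhere
        return None


def generate_smiles_library(
    ground_truth: GroundTruth,
    motifs,
    seed: int = 0,
    max_substituents: int = 3,
) -> dict[str, str]:
    """Chemically valid SMILES per chemical, each containing its cluster's
    motif as substructure, decorated with 0-3 random small substituents.
    Deterministic per seed."""
    motif_mols = []
    for m in motifs:
        mol = Chem.MolFromSmiles(m)
        if mol is None:
            raise ConfigurationError(f"invalid motif fragment: {m!r}")
        motif_mols.append(mol)

    rng = np.random.default_rng(seed)
    library: dict[str, str] = {}
    for chemical in ground_truth.chemicals:
        cluster = ground_truth.chemical_cluster[chemical]
        mol = Chem.Mol(motif_mols[cluster])
        n_subs = int(rng.integers(0, max_substituents + 1))
        for _ in range(n_subs):
            candidates = [
                a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0
            ]
            if not candidates:
                break
            atom_idx = int(candidates[rng.integers(len(candidates))])
            sub = SUBSTITUENT_ALPHABET[rng.integers(len(SUBSTITUENT_ALPHABET))]
            attached = _attach_substituent(mol, sub, atom_idx)
            if attached is not None:
                mol = attached
        smiles = Chem.MolToSmiles(mol)
        if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover
            raise SmilesParseError(smiles, "generated invalid SMILES")
        library[chemical] = smiles
    return library


def write_fixture_dir(
    out_dir,
    graph: InteractionGraph,
    truth: GroundTruth,
    library: dict[str, str],
) -> dict[str, Path]:
    """Write STITCH/STRING-style TSVs, a .smi library and a labels CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chem_protein": out / "chemical_protein.tsv",
        "protein_protein": out / "protein_protein.tsv",
        "library": out / "library.smi",
        "labels": out / "labels.csv",
    }
    write_interactions(graph, paths["chem_protein"], paths["protein_protein"])
    with open(paths["library"], "w") as fh:
        for chem in sorted(library):
            fh.write(f"{library[chem]}\t{chem}\n")
    labels = pd.DataFrame(
        sorted(truth.chemical_cluster.items()), columns=["id", "cluster"]
    )
    labels.to_csv(paths["labels"], index=False)
    return paths


def make_default_fixture(seed: int = 0, spec: FixtureSpec | None = None):
    """Convenience: default 4-cluster network plus motif library."""
    spec = spec or FixtureSpec(seed=seed)
    graph, truth = generate_network(spec)
    library = generate_smiles_library(truth, spec.motif_per_cluster, seed=spec.seed + 1)
    return spec, graph, truth, library
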