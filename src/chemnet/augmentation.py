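"""Equivalent-SMILES enumeration and class-wise augmentation.

One molecule admits many grammar-valid SMILES strings; sequence encoders see
these as distinct inputs while the molecule is unchanged, so enumeration is
usable as label-preserving augmentation. Class-wise augmentation grows the
smaller classes toward a balanced target.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .encoding import canonicalize
from .errors import ConfigurationError, SmilesParseError

logger = logging.getLogger(__name__)

#: Above this many depth-first traversals, exhaustive enumeration falls back
#: to random sampling.
DEFAULT_EXHAUSTIVE_LIMIT = 10_000


def _dfs_preorders(mol: Chem.Mol, limit: int) -> list[tuple[int, ...]] | None:
    """All depth-first atom visit orders (every root atom, every branch
    order). Returns None once more than *limit* orders exist."""
    n = mol.GetNumAtoms()
    adj = {
        a.GetIdx(): sorted(b.GetIdx() for b in a.GetNeighbors())
        for a in mol.GetAtoms()
    }
    orders: list[tuple[int, ...]] = []

    def rec(stack: list[int], visited: set[int], order: list[int]) -> bool:
        if len(order) == n:
            orders.append(tuple(order))
            return len(orders) <= limit
        node = stack[-1]
        pending = [x for x in adj[node] if x not in visited]
        if not pending:
            return rec(stack[:-1], visited, order)
        for nxt in pending:
            if not rec(stack + [nxt], visited | {nxt}, order + [nxt]):
                return False
        return True

    for root in range(n):
        if not rec([root], {root}, [root]):
            return None
    return orders


def _smiles_for_order(mol: Chem.Mol, order: tuple[int, ...]) -> str:
    # Renumbering atoms to the traversal preorder makes the non-canonical
    # writer emit exactly that traversal.
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, list(order)), canonical=False)


def enumerate_smiles(
    smiles: str,
    max_variants: int | None = None,
    seed: int = 0,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> list[str]:
    """Distinct grammar-valid SMILES strings equivalent to *smiles*.

    Exhaustive mode (``max_variants=None``): generate every string reachable
    by varying the root atom and branch traversal order, deduplicated.
    Sampled mode: a uniform draw without replacement of ``max_variants``
    strings from that set, deterministic per *seed*. For molecules whose
    traversal count exceeds *exhaustive_limit*, random-order generation is
    used instead and uniformity is approximate.

    Every returned string canonicalizes to ``canonicalize(smiles)``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    rng = np.random.default_rng(seed)
    orders = _dfs_preorders(mol, exhaustive_limit)
    if orders is not None:
        variants = sorted({_smiles_for_order(mol, o) for o in orders})
        if max_variants is None or max_variants >= len(variants):
            return variants
        picked = rng.choice(len(variants), size=max_variants, replace=False)
        return [variants[i] for i in sorted(picked)]
    # Too many traversals: sample random renumberings instead.
    logger.info(
        "traversal count for %s exceeds %d; sampling", smiles, exhaustive_limit
    )
    target = max_variants if max_variants is not None else exhaustive_limit
    n = mol.GetNumAtoms()
    seen: set[str] = set()
    stall = 0
    while len(seen) < target and stall < 100:
        perm = rng.permutation(n).tolist()
        s = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        if s in seen:
            stall += 1
        else:
            seen.add(s)
            stall = 0
    return sorted(seen)


@dataclass
class AugmentedDataset:
    """Labeled SMILES records after class-wise augmentation.

    ``frame`` columns: id, smiles, cluster, is_augmented, source_id. All
    original records are retained; every variant canonicalizes to the same
    molecule as its source.
    """

    frame: pd.DataFrame
    shortfalls: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def class_sizes(self) -> dict:
        return self.frame["cluster"].value_counts().to_dict()


def _as_frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        frame = dataset.copy()
    else:
        frame = pd.DataFrame(dataset, columns=["id", "smiles", "cluster"])
    missing = {"id", "smiles", "cluster"} - set(frame.columns)
    if missing:
        raise ConfigurationError(f"dataset missing columns: {sorted(missing)}")
    return frame


def classwise_augment(dataset, k: int, seed: int = 0) -> AugmentedDataset:
    """Grow every class toward ``k x (largest class size)`` records by adding
    enumerated SMILES variants of its members, round-robin, never duplicating
    a string already present in the class.

    ``k=0`` returns the input unchanged (originals only). Classes whose
    members lack enough distinct variants stop early; the shortfall is
    logged and reported.
    """
    if k < 0:
        raise ConfigurationError(f"augmentation k must be >= 0, got {k}")
    frame = _as_frame(dataset)
    frame["is_augmented"] = False
    frame["source_id"] = frame["id"]
    if k == 0 or frame.empty:
        return AugmentedDataset(frame.reset_index(drop=True))

    n_max = int(frame["cluster"].value_counts().max())
    target = k * n_max
    out_records: list[pd.DataFrame] = [frame]
    shortfalls: dict = {}

    for cluster, members in frame.groupby("cluster", sort=True):
        members = members.sort_values("id")
        present = set(members["smiles"])
        need = target - len(members)
        if need <= 0:
            continue
        # Per-member variant iterators, visited round-robin.
        iters = []
        for pos, row in enumerate(members.itertuples(index=False)):
            stable = zlib.crc32(str(row.id).encode()) % 2**31
            member_seed = np.random.default_rng([seed, stable]).integers(2**31)
            variants = enumerate_smiles(
                row.smiles, max_variants=None, seed=int(member_seed)
            )
            rng = np.random.default_rng(int(member_seed))
            shuffled = [variants[i] for i in rng.permutation(len(variants))]
            iters.append((row.id, row.smiles, iter(shuffled)))
        added: list[dict] = []
        active = list(range(len(iters)))
        counters = [0] * len(iters)
        while need > 0 and active:
            still_active = []
            for i in active:
                if need <= 0:
                    break
                source_id, _, it = iters[i]
                for variant in it:
                    if variant not in present:
                        present.add(variant)
                        counters[i] += 1
                        added.append(
                            {
                                "id": f"{source_id}#aug{counters[i]}",
                                "smiles": variant,
                                "cluster": cluster,
                                "is_augmented": True,
                                "source_id": source_id,
                            }
                        )
                        need -= 1
                        still_active.append(i)
                        break
            active = still_active
        if need > 0:
            shortfalls[cluster] = need
            logger.warning(
                "class %s short of augmentation target by %d records", cluster, need
            )
        if added:
            out_records.append(pd.DataFrame(added))

    result = pd.concat(out_records, ignore_index=True)
    return AugmentedDataset(result, shortfalls=shortfalls)


def assert_identity_preserved(augmented: AugmentedDataset) -> None:
    """Raise if any variant does not canonicalize to its source molecule."""
    frame = augmented.frame
    canon_by_id = {
        row.id: canonicalize(row.smiles)
        for row in frame[~frame["is_augmented"]].itertuples(index=False)
    }
    for row in frame[frame["is_augmented"]].itertuples(index=False):
        if canonicalize(row.smiles) != canon_by_id[row.source_id]:
            raise AssertionError(
                f"variant {row.id} does not canonicalize to its source"
            )
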