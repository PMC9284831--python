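"""Study-design orchestration: cluster subset selection, splits and
cross-validation, F1 scoring, fold-wise randomization tests for model
comparison, and the prediction + annotation report for novel compounds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import classwise_augment
from .encoding import encode_dataset
from .errors import InputError
from .network import Clustering, ClusterAnnotation, cluster_distance
from .models import ModelConfig, TrainedClassifier, train_classifier

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class SplitSpec:
    """Dataset partition: optional holdout/validation/test id lists plus
    fold assignments for k-fold CV on the remainder."""

    train_ids: list = field(default_factory=list)
    val_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    folds: dict = field(default_factory=dict)  # fold index -> id list
    seed: int = 0
    stratified: bool = True

    def all_ids(self) -> set:
        out = set(self.train_ids) | set(self.val_ids) | set(self.test_ids)
        for ids in self.folds.values():
            out.update(ids)
        return out


def _stratified_order(frame: pd.DataFrame, rng: np.random.Generator) -> list:
    """Ids grouped by class (classes sorted), shuffled within class."""
    order: list = []
    for _, group in frame.groupby("cluster", sort=True):
        ids = list(group["id"])
        rng.shuffle(ids)
        order.extend(ids)
    return order


def _largest_remainder(counts: np.ndarray, fraction: float, total_target: int):
    """Per-class allocation summing exactly to total_target."""
    raw = counts * fraction
    base = np.floor(raw).astype(int)
    remainder = raw - base
    short = total_target - base.sum()
    for i in np.argsort(-remainder)[:short]:
        base[i] += 1
    return base


def make_splits(
    dataset: pd.DataFrame,
    holdout_fraction: float = 0.1,
    k_folds: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> SplitSpec:
    """Hold out ``holdout_fraction`` of the data for final testing and
    assign the remainder to *k_folds* CV folds.

    Stratification preserves class proportions within one sample per class;
    classes smaller than the fold count fall back to plain dealing with a
    warning. Fold sizes differ by at most one.
    """
    frame = dataset[["id", "cluster"]].copy()
    if len(frame) < k_folds:
        raise InputError("dataset smaller than the number of folds")
    rng = np.random.default_rng(seed)

    if stratified:
        classes = sorted(frame["cluster"].unique())
        counts = frame["cluster"].value_counts().reindex(classes).to_numpy()
        small = [c for c, n in zip(classes, counts) if n < k_folds]
        if small:
            logger.warning(
                "classes %s have fewer members than folds; stratification is "
                "approximate for them", small,
            )
        n_hold = int(round(holdout_fraction * len(frame)))
        per_class_hold = _largest_remainder(counts, holdout_fraction, n_hold)
        holdout: list = []
        rest_order: list = []
        for cls, take in zip(classes, per_class_hold):
            ids = list(frame.loc[frame["cluster"] == cls, "id"])
            rng.shuffle(ids)
            holdout.extend(ids[:take])
            rest_order.extend(ids[take:])
    else:
        ids = list(frame["id"])
        rng.shuffle(ids)
        n_hold = int(round(holdout_fraction * len(ids)))
        holdout = ids[:n_hold]
        rest_order = ids[n_hold:]

    folds: dict = {f: [] for f in range(k_folds)}
    for i, sample in enumerate(rest_order):
        folds[i % k_folds].append(sample)
    return SplitSpec(
        test_ids=sorted(holdout),
        folds={f: sorted(ids) for f, ids in folds.items()},
        seed=seed,
        stratified=stratified,
    )


def make_tvt(
    dataset: pd.DataFrame,
    fractions: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = True,
) -> SplitSpec:
    """Train/validation/test split (default 80/10/10), stratified."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    frame = dataset[["id", "cluster"]].copy()
    rng = np.random.default_rng(seed)
    n = len(frame)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))

    if stratified:
        classes = sorted(frame["cluster"].unique())
        counts = frame["cluster"].value_counts().reindex(classes).to_numpy()
        val_take = _largest_remainder(counts, fractions[1], n_val)
        test_take = _largest_remainder(counts, fractions[2], n_test)
        train, val, test = [], [], []
        for cls, nv, nt in zip(classes, val_take, test_take):
            ids = list(frame.loc[frame["cluster"] == cls, "id"])
            rng.shuffle(ids)
            val.extend(ids[:nv])
            test.extend(ids[nv: nv + nt])
            train.extend(ids[nv + nt:])
    else:
        ids = list(frame["id"])
        rng.shuffle(ids)
        val = ids[:n_val]
        test = ids[n_val: n_val + n_test]
        train = ids[n_val + n_test:]
    return SplitSpec(
        train_ids=sorted(train), val_ids=sorted(val), test_ids=sorted(test),
        seed=seed, stratified=stratified,
    )


def assert_no_leakage(train_frame: pd.DataFrame, eval_ids) -> None:
    """Fail if any training record (original or augmented) stems from a
    compound in the evaluation split."""
    sources = set(train_frame.get("source_id", train_frame["id"]))
    overlap = sources & set(eval_ids)
    if overlap:
        raise AssertionError(f"augmentation leakage for sources: {sorted(overlap)}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def f1_scores(y_true, y_pred):
    """(macro F1, micro F1, per-class F1).

    Per-class F1 = 2PR/(P+R), 0 when P+R = 0; macro averages over classes
    present in the true labels; micro pools counts.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise InputError("label vectors differ in length")
    if len(y_true) == 0:
        raise InputError("empty label vectors")
    classes = sorted(set(y_true.tolist()))
    per_class: dict = {}
    tp_total = 0
    for cls in classes:
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        tp_total += tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_class[cls] = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
    macro = float(np.mean(list(per_class.values())))
    # single-label multiclass: pooled FP == pooled FN, so micro F1 == accuracy
    micro = tp_total / len(y_true)
    return macro, micro, per_class


def randomization_test(
    scores_a,
    scores_b,
    n_permutations: int = 10_000,
    seed: int = 0,
    exhaustive_below: int = 12,
) -> float:
    """Two-sided paired sign-flip permutation test on the mean fold-score
    difference. Exhaustive over all 2^n sign patterns when n <=
    *exhaustive_below*, otherwise Monte-Carlo with add-one smoothing.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired score lists differ in length")
    d = a - b
    n = len(d)
    if n == 0:
        raise InputError("empty score lists")
    obs = abs(d.mean())
    eps = 1e-12
    if n <= exhaustive_below:
        # all 2^n sign patterns at once
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        signs = np.where(bits & 1, -1.0, 1.0)
        perm = np.abs(signs @ d) / n
        return float(np.sum(perm >= obs - eps)) / 2**n
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    perm = np.abs(signs @ d) / n
    count = int(np.sum(perm >= obs - eps))
    return (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# Cluster subset selection
# ---------------------------------------------------------------------------


def select_cluster_subset(
    clustering: Clustering, n_clusters: int, seed: int = 0
) -> list[int]:
    """Choose a cluster subset containing both closely related and distant
    clusters: half as globally nearest pairs in cophenetic distance, the
    rest by max-min (farthest point) spread. Deterministic per seed."""
    ids = clustering.cluster_ids
    if len(ids) < n_clusters:
        raise InputError(
            f"asked for {n_clusters} clusters but only {len(ids)} exist"
        )
    if len(ids) == n_clusters:
        return list(ids)
    dist = {
        (a, b): cluster_distance(clustering, a, b)
        for a, b in itertools.combinations(ids, 2)
    }
    chosen: list[int] = []
    near_target = n_clusters // 2
    pairs = sorted(dist.items(), key=lambda kv: (kv[1], kv[0]))
    for (a, b), _ in pairs:
        if len(chosen) >= near_target:
            break
        if a not in chosen and b not in chosen:
            chosen.extend([a, b])
    chosen = chosen[: max(near_target, 2)] if near_target else chosen
    rng = np.random.default_rng(seed)
    remaining = [c for c in ids if c not in chosen]
    if not chosen and remaining:
        chosen.append(remaining.pop(int(rng.integers(len(remaining)))))
    while len(chosen) < n_clusters and remaining:
        # farthest-point: maximize the minimum distance to chosen clusters
        best = max(
            remaining,
            key=lambda c: (min(dist[tuple(sorted((c, x)))] for x in chosen), -c),
        )
        chosen.append(best)
        remaining.remove(best)
    return sorted(chosen[:n_clusters])


# ---------------------------------------------------------------------------
# Architecture comparison
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Fold-wise F1 scores, pairwise randomization-test p-values, and the
    per-compound prediction fragment."""

    per_fold: dict = field(default_factory=dict)  # name -> list of macro F1
    per_fold_micro: dict = field(default_factory=dict)
    means: dict = field(default_factory=dict)
    stds: dict = field(default_factory=dict)
    pairwise_p: dict = field(default_factory=dict)  # (name_a, name_b) -> p
    failed_folds: dict = field(default_factory=dict)
    predictions: list = field(default_factory=list)
    cluster_distance_table: pd.DataFrame | None = None


def _encode_for_config(frame: pd.DataFrame, config: ModelConfig,
                       vocab=None, merges=None, max_len=None, classes=None):
    scheme = {
        "dnn": "fingerprint",
        "cnn": "matrix",
        "rnn_seq2seq": config.tokenizer_scheme or "atomwise",
        "lm_finetune": config.tokenizer_scheme or "atomwise",
    }[config.architecture]
    canonical = scheme in ("fingerprint", "matrix")
    labels = list(frame["cluster"])
    if classes is not None:
        # keep a fixed class ordering across folds
        assert set(labels) <= set(classes)
    return encode_dataset(
        list(frame["id"]), list(frame["smiles"]), labels, scheme,
        vocab=vocab, merges=merges, max_len=max_len, canonical=canonical,
    )


def evaluate_architectures(
    dataset: pd.DataFrame,
    architectures: list[tuple[str, ModelConfig]],
    splits: SplitSpec,
    augment_k: int = 0,
    seed: int = 0,
) -> EvaluationReport:
    """Cross-validated comparison of architectures.

    For each fold, each architecture trains on the other folds (with
    class-wise augmentation of the training portion only, when
    ``augment_k>0``) and is scored on the fold. Pairwise fold-score
    randomization tests are reported over the folds both models completed.
    """
    report = EvaluationReport()
    frame = dataset.set_index("id", drop=False)
    fold_ids = sorted(splits.folds)
    for name, config in architectures:
        scores: list[float] = []
        micro_scores: list[float] = []
        failed: list[int] = []
        for fold in fold_ids:
            val_ids = splits.folds[fold]
            train_ids = [
                i for f in fold_ids if f != fold for i in splits.folds[f]
            ]
            train_frame = frame.loc[train_ids].reset_index(drop=True)
            val_frame = frame.loc[val_ids].reset_index(drop=True)
            try:
                needs_tokens = config.architecture in ("rnn_seq2seq", "lm_finetune")
                if augment_k > 0 and needs_tokens:
                    train_frame = classwise_augment(
                        train_frame[["id", "smiles", "cluster"]], augment_k,
                        seed=seed + fold,
                    ).frame
                    assert_no_leakage(train_frame, val_ids)
                enc_train = _encode_for_config(train_frame, config)
                enc_val = _encode_for_config(
                    val_frame, config, vocab=enc_train.vocab,
                    merges=enc_train.merges, max_len=enc_train.max_len,
                )
                model = train_classifier(enc_train, config)
                probs = model.predict_proba(enc_val.X)
                predicted = [model.classes[i] for i in probs.argmax(axis=1)]
                truth = [enc_val.classes[i] for i in enc_val.y]
                macro, micro, _ = f1_scores(truth, predicted)
                scores.append(macro)
                micro_scores.append(micro)
            except Exception:
                logger.exception("architecture %s failed on fold %d", name, fold)
                failed.append(fold)
                scores.append(float("nan"))
                micro_scores.append(float("nan"))
        report.per_fold[name] = scores
        report.per_fold_micro[name] = micro_scores
        valid = [s for s in scores if not np.isnan(s)]
        report.means[name] = float(np.mean(valid)) if valid else float("nan")
        report.stds[name] = float(np.std(valid)) if valid else float("nan")
        report.failed_folds[name] = failed
    names = [name for name, _ in architectures]
    for a, b in itertools.combinations(names, 2):
        sa = np.asarray(report.per_fold[a])
        sb = np.asarray(report.per_fold[b])
        ok = ~(np.isnan(sa) | np.isnan(sb))
        if ok.sum() == 0:
            continue
        report.pairwise_p[(a, b)] = randomization_test(sa[ok], sb[ok], seed=seed)
    return report


# ---------------------------------------------------------------------------
# Prediction + annotation for novel compounds
# ---------------------------------------------------------------------------


def predict_and_annotate(
    model: TrainedClassifier,
    compounds: list[str],
    clustering: Clustering,
    annotations: tuple[ClusterAnnotation, ClusterAnnotation],
    top_k: int = 3,
    encode_fn=None,
) -> EvaluationReport:
    """Top-k cluster predictions with probabilities, protein annotations at
    both cutoffs, and the pairwise predicted-cluster cophenetic distance
    table. Unparseable compounds produce per-compound error entries without
    aborting the batch."""
    q_annot, l_annot = annotations
    report = EvaluationReport()
    predicted_clusters: list = []
    ok_compounds: list[str] = []
    for smiles in compounds:
        try:
            X = _encode_single(model, smiles) if encode_fn is None else encode_fn(smiles)
            probs = model.predict_proba(X)[0]
            order = np.argsort(-probs)[:top_k]
            top = [(model.classes[i], float(probs[i])) for i in order]
            entry = {
                "smiles": smiles,
                "ok": True,
                "top": top,
                "annotations": {
                    cluster: {
                        "Q": sorted(q_annot.proteins.get(cluster, frozenset())),
                        "L": sorted(l_annot.proteins.get(cluster, frozenset())),
                    }
                    for cluster, _ in top
                },
            }
            predicted_clusters.append(top[0][0])
            ok_compounds.append(smiles)
        except Exception as exc:
            entry = {"smiles": smiles, "ok": False, "error": str(exc)}
        report.predictions.append(entry)
    if ok_compounds:
        n = len(ok_compounds)
        table = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = cluster_distance(
                    clustering, predicted_clusters[i], predicted_clusters[j]
                )
                table[i, j] = table[j, i] = d
        report.cluster_distance_table = pd.DataFrame(
            table, index=ok_compounds, columns=ok_compounds
        )
    return report


def _encode_single(model: TrainedClassifier, smiles: str) -> np.ndarray:
    """Encode one SMILES according to the model's stored encoder metadata."""
    from . import encoding as enc

    meta = model.encoder_meta
    scheme = meta["scheme"]
    if scheme == "fingerprint":
        return enc.morgan_fingerprint(
            smiles, n_bits=meta["n_features"]
        ).astype(np.float64)[None, :]
    if scheme == "matrix":
        return enc.feature_matrix(enc.canonicalize(smiles), meta["max_len"])[None, :, :]
    vocab = enc.TokenVocabulary.from_json(meta["vocab_json"])
    canon = enc.canonicalize(smiles)
    if scheme == "spe":
        merges = enc.MergeTable.from_json(meta["merges_json"])
        tokens = enc.tokenize_spe(canon, merges)
    else:
        tokens = enc.tokenize_atomwise(canon)
    return enc.encode_tokens(tokens, vocab, meta["max_len"])[None, :]
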