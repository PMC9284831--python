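"""SMILES encoders: canonical form, Morgan fingerprints, per-character feature
matrices, and token sequences (atom-wise and learned pair-encoding).

Three model input representations are produced here:

* fingerprint bit vectors (order-invariant, no augmentation possible),
* 42-row character feature matrices over canonical SMILES,
* token-id sequences under atom-wise or pair-encoding (SPE) tokenization.
"""

from __future__ import annotations

import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import (
    InputError,
    LengthError,
    SmilesParseError,
    TokenizationError,
)

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# Canonical form and fingerprints
# ---------------------------------------------------------------------------


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES for *smiles*.

    Idempotent: all equivalent orderings of one molecule map to a single
    string. Raises :class:`SmilesParseError` on unparseable input.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


DEFAULT_FP_RADIUS = 2
DEFAULT_FP_BITS = 1024


def morgan_fingerprint(
    smiles: str, radius: int = DEFAULT_FP_RADIUS, n_bits: int = DEFAULT_FP_BITS
) -> np.ndarray:
    """Morgan (circular/ECFP-style) fingerprint as a 0/1 vector of length
    *n_bits*. Identical molecules give identical vectors regardless of the
    SMILES ordering used, so augmentation has no effect on this encoding.
    """
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Bracket atoms as single tokens, two-letter halogens, %NN ring closures,
# otherwise single characters.
_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|Br|Cl|%\d{2}|.")

# Single characters that open an (organic-subset) atom.
_ORGANIC_ATOM_CHARS = frozenset("BCNOPSFIbcnops*")


def tokenize_atomwise(smiles: str) -> list[str]:
    """Split a SMILES string into atom-wise tokens.

    Tokens: ``[...]`` bracket atoms, ``Cl``/``Br``, ``%NN`` ring closures,
    and single characters otherwise. The concatenation of the returned
    tokens reproduces the input exactly.
    """
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise TokenizationError(f"tokenization did not cover input: {smiles!r}")
    for tok in tokens:
        if tok in ("[", "]"):
            raise TokenizationError(f"unmatched bracket in {smiles!r}")
    return tokens


def is_atom_token(token: str) -> bool:
    """True when *token* begins an atom (bracket atom, halogen or organic
    subset symbol)."""
    if token.startswith("["):
        return True
    if token in ("Cl", "Br"):
        return True
    return len(token) == 1 and token in _ORGANIC_ATOM_CHARS


# ---------------------------------------------------------------------------
# Character feature matrices
# ---------------------------------------------------------------------------

FEATURE_DIM = 42

# Atom block (first 21 rows): 13-way atom-type one-hot, then scalar
# descriptors, then 2 reserved rows. Symbol block (last 21 rows): one-hot
# over 20 structural characters plus an "other" slot. The split is kept in
# one place so alternative layouts summing to FEATURE_DIM are drop-in.
_ATOM_TYPES = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se"]
_ATOM_BLOCK = 21
_SYMBOL_CHARS = list("0123456789()=#/\\@+-%")
assert len(_SYMBOL_CHARS) == 20
_SYMBOL_INDEX = {c: i for i, c in enumerate(_SYMBOL_CHARS)}
_SYMBOL_OTHER = len(_SYMBOL_CHARS)  # 21st slot


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    feats = np.zeros(_ATOM_BLOCK, dtype=np.float64)
    sym = atom.GetSymbol()
    idx = _ATOM_TYPES.index(sym) if sym in _ATOM_TYPES else len(_ATOM_TYPES)
    feats[idx] = 1.0  # slots 0..12
    feats[13] = atom.GetDegree() / 3.0
    feats[14] = 1.0 if atom.GetIsAromatic() else 0.0
    feats[15] = 1.0 if atom.IsInRing() else 0.0
    feats[16] = atom.GetFormalCharge() / 4.0
    feats[17] = 0.0 if atom.GetChiralTag() == Chem.ChiralType.CHI_UNSPECIFIED else 1.0
    feats[18] = atom.GetTotalNumHs() / 4.0
    # slots 19, 20 reserved (zero)
    return feats


def _symbol_column(char: str) -> np.ndarray:
    col = np.zeros(FEATURE_DIM, dtype=np.float64)
    slot = _SYMBOL_INDEX.get(char, _SYMBOL_OTHER)
    col[_ATOM_BLOCK + slot] = 1.0
    return col


def feature_matrix(smiles: str, max_len: int) -> np.ndarray:
    """Encode a canonical SMILES as a ``(42, max_len)`` matrix.

    Each character of the string yields one 42-entry column: the atom block
    is filled for the character that begins an atom, the symbol one-hot
    block for every other character. Columns past the string length are
    zero padding.

    Raises :class:`LengthError` when the string is longer than *max_len*.
    """
    if len(smiles) > max_len:
        raise LengthError(
            f"SMILES of length {len(smiles)} exceeds max_len={max_len}"
        )
    mol = _mol_from_smiles(smiles)
    tokens = tokenize_atomwise(smiles)
    mat = np.zeros((FEATURE_DIM, max_len), dtype=np.float64)
    pos = 0
    atom_idx = 0
    for tok in tokens:
        if is_atom_token(tok):
            # RDKit atom indices follow SMILES appearance order.
            mat[:_ATOM_BLOCK, pos] = _atom_features(mol.GetAtomWithIdx(atom_idx))
            atom_idx += 1
            pos += 1
            for ch in tok[1:]:
                mat[:, pos] = _symbol_column(ch)
                pos += 1
        else:
            for ch in tok:
                mat[:, pos] = _symbol_column(ch)
                pos += 1
    return mat


# ---------------------------------------------------------------------------
# Pair encoding (SPE)
# ---------------------------------------------------------------------------


@dataclass
class MergeTable:
    """Learned pair-encoding merge rules, in application order, with the
    training frequency at which each rule was adopted."""

    rules: list[tuple[str, str]] = field(default_factory=list)
    frequencies: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"rules": [list(r) for r in self.rules], "frequencies": self.frequencies}
        )

    @classmethod
    def from_json(cls, text: str) -> "MergeTable":
        obj = json.loads(text)
        return cls(
            rules=[tuple(r) for r in obj["rules"]],
            frequencies=list(obj["frequencies"]),
        )


def _merge_once(seq: list[str], pair: tuple[str, str]) -> list[str]:
    """Apply one merge rule leftmost-first, non-overlapping."""
    merged = pair[0] + pair[1]
    out: list[str] = []
    i = 0
    while i < len(seq):
        if i + 1 < len(seq) and seq[i] == pair[0] and seq[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(seq[i])
            i += 1
    return out


def learn_spe(
    corpus: Iterable[str], min_frequency: int = 2, max_merges: int = 500
) -> MergeTable:
    """Learn pair-encoding merges from a SMILES corpus.

    Repeatedly merges the most frequent adjacent token pair (ties broken
    lexicographically) until *max_merges* rules exist or no pair reaches
    *min_frequency*. Deterministic.
    """
    sequences = [tokenize_atomwise(s) for s in corpus]
    if not sequences:
        raise InputError("empty corpus for pair-encoding learning")
    table = MergeTable()
    for _ in range(max_merges):
        counts: Counter[tuple[str, str]] = Counter()
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                counts[(a, b)] += 1
        if not counts:
            break
        best_freq = max(counts.values())
        if best_freq < min_frequency:
            break
        best = min(p for p, c in counts.items() if c == best_freq)
        table.rules.append(best)
        table.frequencies.append(best_freq)
        sequences = [_merge_once(seq, best) for seq in sequences]
    return table


def tokenize_spe(smiles: str, merges: MergeTable) -> list[str]:
    """Tokenize with atom-wise splitting then apply merge rules in learned
    order (leftmost-first). Concatenation reproduces the input."""
    seq = tokenize_atomwise(smiles)
    for rule in merges.rules:
        seq = _merge_once(seq, rule)
    return seq


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<bos>", "<eos>"
SPECIALS = (PAD, UNK, BOS, EOS)


@dataclass
class TokenVocabulary:
    """Token to contiguous-id map with reserved PAD/UNK/BOS/EOS ids 0..3."""

    token_to_id: dict[str, int]

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def bos_id(self) -> int:
        return self.token_to_id[BOS]

    @property
    def eos_id(self) -> int:
        return self.token_to_id[EOS]

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def id_to_token(self) -> list[str]:
        inv = [""] * len(self.token_to_id)
        for tok, i in self.token_to_id.items():
            inv[i] = tok
        return inv

    def content_hash(self) -> str:
        payload = json.dumps(self.token_to_id, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(self.token_to_id)

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        return cls(token_to_id=json.loads(text))


def build_vocab(sequences: Iterable[Sequence[str]]) -> TokenVocabulary:
    """Vocabulary over observed tokens, sorted by frequency then
    lexicographically, after the four reserved specials."""
    counts: Counter[str] = Counter()
    n = 0
    for seq in sequences:
        n += 1
        counts.update(seq)
    if n == 0:
        raise InputError("no sequences given to build_vocab")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    token_to_id = {tok: i for i, tok in enumerate(SPECIALS)}
    for tok, _ in ordered:
        token_to_id[tok] = len(token_to_id)
    return TokenVocabulary(token_to_id)


def encode_tokens(
    tokens: Sequence[str], vocab: TokenVocabulary, max_len: int
) -> np.ndarray:
    """Map tokens to ids with BOS/EOS framing, truncating or padding to
    *max_len*. Unseen tokens map to UNK."""
    ids = [vocab.bos_id]
    for tok in tokens:
        ids.append(vocab.token_to_id.get(tok, vocab.unk_id))
    ids.append(vocab.eos_id)
    if len(ids) > max_len:
        ids = ids[: max_len - 1] + [vocab.eos_id]
    ids.extend([vocab.pad_id] * (max_len - len(ids)))
    return np.asarray(ids, dtype=np.int64)


def decode_tokens(ids: Sequence[int], vocab: TokenVocabulary) -> list[str]:
    """Inverse of :func:`encode_tokens` up to truncation: strips specials."""
    inv = vocab.id_to_token
    special_ids = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    return [inv[i] for i in ids if i not in special_ids]


# ---------------------------------------------------------------------------
# Encoded datasets
# ---------------------------------------------------------------------------


@dataclass
class EncodedDataset:
    """Molecules rendered for one model family, with labels.

    ``scheme`` is one of ``fingerprint``, ``matrix``, ``atomwise``, ``spe``.
    ``X`` is ``(n, n_bits)`` for fingerprints, ``(n, 42, max_len)`` for
    matrices and ``(n, max_len)`` integer ids for token schemes.
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    scheme: str
    classes: list
    vocab: TokenVocabulary | None = None
    merges: MergeTable | None = None
    max_len: int | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.X) or len(self.X) != len(self.y):
            raise InputError("ids, X and y must have equal length")


def encode_dataset(
    ids: Sequence[str],
    smiles: Sequence[str],
    labels: Sequence,
    scheme: str,
    *,
    radius: int = DEFAULT_FP_RADIUS,
    n_bits: int = DEFAULT_FP_BITS,
    max_len: int | None = None,
    vocab: TokenVocabulary | None = None,
    merges: MergeTable | None = None,
    canonical: bool = True,
) -> EncodedDataset:
    """Encode a labeled SMILES collection under one scheme.

    For token schemes a vocabulary (and merge table for ``spe``) may be
    passed; otherwise they are learned from this collection. Fingerprint and
    matrix schemes canonicalize first (those encodings are order-invariant
    by construction); token schemes keep the given string when
    ``canonical=False`` so augmented variants stay distinct.
    """
    classes = sorted(set(labels))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[l] for l in labels], dtype=np.int64)

    if scheme == "fingerprint":
        X = np.stack([morgan_fingerprint(s, radius, n_bits) for s in smiles])
        return EncodedDataset(list(ids), X.astype(np.float64), y, scheme, classes)

    if scheme == "matrix":
        canon = [canonicalize(s) for s in smiles]
        if max_len is None:
            max_len = max(len(s) for s in canon)
        X = np.stack([feature_matrix(s, max_len) for s in canon])
        return EncodedDataset(list(ids), X, y, scheme, classes, max_len=max_len)

    if scheme in ("atomwise", "spe"):
        strings = [canonicalize(s) if canonical else s for s in smiles]
        if scheme == "spe":
            if merges is None:
                merges = learn_spe(strings)
            token_seqs = [tokenize_spe(s, merges) for s in strings]
        else:
            token_seqs = [tokenize_atomwise(s) for s in strings]
        if vocab is None:
            vocab = build_vocab(token_seqs)
        if max_len is None:
            max_len = max(len(t) for t in token_seqs) + 2
        X = np.stack([encode_tokens(t, vocab, max_len) for t in token_seqs])
        return EncodedDataset(
            list(ids), X, y, scheme, classes, vocab=vocab, merges=merges,
            max_len=max_len,
        )

    raise InputError(f"unknown encoding scheme: {scheme!r}")
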