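"""k-mer tokenization and strand-permutation augmentation.

Each strand is decomposed into overlapping k-mers (k = 3 by default); the
strands of a construct are concatenated with an explicit SEP token between
them (windows never span strand boundaries), right-padded with PAD to a
fixed length.  Because the physical connectivity of the strands is not
represented in a flat token stream, the training set is expanded with
systematic strand permutations so models learn order-insensitive features.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import NANPDataset, NANPRecord, NanpError

PAD, SEP, UNK = "PAD", "SEP", "UNK"
SPECIALS = (PAD, SEP, UNK)

DEFAULT_K = 3
#: full factorial through the 6-strand constructs of the panel (6! = 720)
DEFAULT_PERMUTATION_CAP = 720


class TooShortError(NanpError):
    """Sequence shorter than the k-mer window."""


class TooLongError(NanpError):
    """Encoded variant exceeds max_len and truncation is disabled."""


class EmptyCorpusError(NanpError):
    """No sequences to build a vocabulary from."""


def kmerize(sequence: str, k: int = DEFAULT_K) -> list[str]:
    """All overlapping length-k windows of ``sequence``, in order.

    A sequence of length L yields exactly L - k + 1 tokens.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(sequence) < k:
        raise TooShortError(
            f"sequence of length {len(sequence)} shorter than k={k}"
        )
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@dataclass
class Vocabulary:
    """k-mer token inventory with PAD/SEP/UNK specials.

    PAD is always index 0; k-mer entries are lexicographically ordered
    after the specials, so vocabulary construction is deterministic.
    ``max_len`` is the encoding length fixed at build time and shipped
    with trained models.
    """

    token_to_index: dict[str, int]
    k: int
    max_len: int | None = None

    def __post_init__(self) -> None:
        if self.token_to_index.get(PAD) != 0:
            raise ValueError("PAD must have index 0")
        indices = sorted(self.token_to_index.values())
        if indices != list(range(len(indices))):
            raise ValueError("token indices must be contiguous from 0")
        for tok in self.token_to_index:
            if tok not in SPECIALS and len(tok) != self.k:
                raise ValueError(f"k-mer {tok!r} does not have length k={self.k}")

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def pad_index(self) -> int:
        return self.token_to_index[PAD]

    @property
    def sep_index(self) -> int:
        return self.token_to_index[SEP]

    @property
    def unk_index(self) -> int:
        return self.token_to_index[UNK]

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, self.token_to_index[UNK])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "token_to_index": self.token_to_index,
                    "k": self.k,
                    "max_len": self.max_len,
                },
                indent=0,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            token_to_index=dict(payload["token_to_index"]),
            k=int(payload["k"]),
            max_len=payload.get("max_len"),
        )


def encoded_length(record: NANPRecord, k: int) -> int:
    """Token count of an encoded record: per-strand windows + SEPs.

    Independent of strand order, so it bounds every permutation variant.
    """
    return sum(len(s) - k + 1 for s in record.strands) + record.strand_count - 1


def build_vocabulary(
    datasets: NANPDataset | Iterable[NANPDataset],
    k: int = DEFAULT_K,
    max_len: int | None = None,
) -> Vocabulary:
    """Vocabulary over every k-mer observed in the corpus.

    ``max_len`` defaults to the longest encoded variant in the corpus,
    rounded up to a multiple of 8.
    """
    if isinstance(datasets, NANPDataset):
        datasets = [datasets]
    kmers: set[str] = set()
    longest = 0
    n_records = 0
    for ds in datasets:
        for rec in ds:
            n_records += 1
            for strand in rec.strands:
                kmers.update(kmerize(strand.sequence, k))
            longest = max(longest, encoded_length(rec, k))
    if n_records == 0:
        raise EmptyCorpusError("cannot build a vocabulary from an empty corpus")
    token_to_index = {tok: i for i, tok in enumerate(SPECIALS)}
    for i, kmer in enumerate(sorted(kmers), start=len(SPECIALS)):
        token_to_index[kmer] = i
    if max_len is None:
        max_len = 8 * math.ceil(longest / 8)
    return Vocabulary(token_to_index=token_to_index, k=k, max_len=max_len)


@dataclass(frozen=True)
class TokenSequence:
    """An encoded (and possibly permuted) variant of one NANP."""

    token_indices: tuple[int, ...]
    group_id: str
    permutation_index: int

    def __len__(self) -> int:
        return len(self.token_indices)


def encode_record(
    record: NANPRecord,
    strand_order: Sequence[int],
    vocab: Vocabulary,
    max_len: int | None = None,
    permutation_index: int = 0,
    truncate: bool = False,
) -> TokenSequence:
    """Encode a record under a given strand ordering.

    ``strand_order`` is a permutation of 0..n_strands-1.  Strands are
    k-merized independently and joined with SEP; the stream is right-padded
    with PAD to ``max_len`` (default: the vocabulary's).  Unseen k-mers map
    to UNK.  Overlong streams raise :class:`TooLongError` unless
    ``truncate`` is set.
    """
    n = record.strand_count
    if sorted(strand_order) != list(range(n)):
        raise ValueError(
            f"strand_order must be a permutation of 0..{n - 1}, got {strand_order}"
        )
    if max_len is None:
        max_len = vocab.max_len
    if max_len is None:
        raise ValueError("max_len not set on vocabulary nor passed explicitly")
    indices: list[int] = []
    for pos, strand_idx in enumerate(strand_order):
        if pos:
            indices.append(vocab.sep_index)
        seq = record.strands[strand_idx].sequence
        indices.extend(vocab.index(t) for t in kmerize(seq, vocab.k))
    if len(indices) > max_len:
        if not truncate:
            raise TooLongError(
                f"{record.nanp_id}: encoded length {len(indices)} exceeds "
                f"max_len {max_len}"
            )
        indices = indices[:max_len]
    indices.extend([vocab.pad_index] * (max_len - len(indices)))
    return TokenSequence(tuple(indices), record.nanp_id, permutation_index)


def permute_strands(
    record: NANPRecord,
    cap: int = DEFAULT_PERMUTATION_CAP,
    seed: int = 0,
) -> list[tuple[int, ...]]:
    """Strand orderings for augmentation, identity first.

    Returns all n! orderings when n! <= cap; otherwise the identity plus
    cap - 1 distinct orderings sampled uniformly without replacement.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    n = record.strand_count
    total = math.factorial(n)
    if total <= cap:
        return [tuple(p) for p in itertools.permutations(range(n))]
    rng = np.random.default_rng(seed)
    identity = tuple(range(n))
    chosen: list[tuple[int, ...]] = [identity]
    seen = {identity}
    while len(chosen) < cap:
        perm = tuple(int(x) for x in rng.permutation(n))
        if perm not in seen:
            seen.add(perm)
            chosen.append(perm)
    return chosen


@dataclass
class AugmentedDataset:
    """Permutation variants of a dataset, grouped by parent record.

    Every variant of a record carries that record's targets; ``groups``
    maps nanp_id to the variant positions, which is what keeps whole
    groups inside one cross-validation fold.
    """

    variants: list[tuple[TokenSequence, Mapping[str, float]]]
    groups: dict[str, list[int]] = field(default_factory=dict)
    max_len: int | None = None

    def __len__(self) -> int:
        return len(self.variants)

    def token_matrix(self) -> np.ndarray:
        return np.array(
            [ts.token_indices for ts, _ in self.variants], dtype=np.int32
        )

    def target_vector(self, endpoint: str) -> np.ndarray:
        return np.array(
            [targets[endpoint] for _, targets in self.variants], dtype=np.float64
        )

    def group_ids(self) -> list[str]:
        return [ts.group_id for ts, _ in self.variants]


def augment_dataset(
    dataset: NANPDataset,
    vocab: Vocabulary,
    cap: int = DEFAULT_PERMUTATION_CAP,
    seed: int = 0,
    max_len: int | None = None,
) -> AugmentedDataset:
    """Expand a dataset into min(n_strands!, cap) permutation variants
    per record.

    ``cap=1`` keeps only the identity ordering — the no-augmentation
    regime used as a comparator.  Records must carry endpoints (assumed
    already log10-transformed by the pipeline).
    """
    variants: list[tuple[TokenSequence, Mapping[str, float]]] = []
    groups: dict[str, list[int]] = {}
    rng = np.random.default_rng(seed)
    for rec in dataset:
        if rec.endpoints is None:
            raise NanpError(f"{rec.nanp_id}: no endpoints; cannot augment")
        # each record gets its own derived seed so variant sampling is
        # independent of dataset ordering upstream of this record
        rec_seed = int(rng.integers(0, 2**31 - 1))
        orders = permute_strands(rec, cap=cap, seed=rec_seed)
        positions = []
        for j, order in enumerate(orders):
            try:
                ts = encode_record(
                    rec, order, vocab, max_len=max_len, permutation_index=j
                )
            except NanpError as exc:
                raise type(exc)(f"{rec.nanp_id}: {exc}") from exc
            positions.append(len(variants))
            variants.append((ts, dict(rec.endpoints)))
        groups[rec.nanp_id] = positions
    return AugmentedDataset(
        variants=variants,
        groups=groups,
        max_len=max_len if max_len is not None else vocab.max_len,
    )
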