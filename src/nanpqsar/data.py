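"""Domain types and I/O for nucleic acid nanoparticle (NANP) datasets.

A NANP is an ordered assembly of short DNA/RNA strands (triangles, squares,
pentagons, cubes) with optionally measured cytokine endpoints (IFN-beta and
IL-6, pg/mL) from microglial stimulation assays.  This module defines the
record types, the strand-manifest / endpoint CSV and FASTA readers and
writers, the log10 target transform, sequence-composition descriptors, and
the seeded train/test split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGUT")

#: endpoint keys used throughout the package (values are pg/mL, or log10
#: pg/mL after :func:`log10_transform_targets`)
IFNB = "IFNB"
IL6 = "IL6"
ENDPOINTS = (IFNB, IL6)

#: default clamp applied before log10 so zero cytokine readings stay finite
DEFAULT_LOG10_FLOOR = 0.1

_ENDPOINT_COLUMNS = {IFNB: "ifn_beta_pg_ml", IL6: "il6_pg_ml"}
_MANIFEST_COLUMNS = [
    "nanp_id", "shape", "strand_index", "strand_id", "nucleic_type", "sequence",
]


class NanpError(Exception):
    """Base class for all package-specific errors."""


class SequenceError(NanpError):
    """Sequence violates the {A,C,G,U,T} alphabet or mixes U and T."""


class AmbiguousStrandTypeError(NanpError):
    """Sequence contains neither U nor T; nucleic type must be declared."""


class FormatError(NanpError):
    """Malformed manifest/endpoint/FASTA input."""


class InvalidMeasurementError(NanpError):
    """Negative or otherwise invalid endpoint value."""


class CannotSplitError(NanpError):
    """Dataset too small to partition."""


class NucleicType(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class Shape(str, Enum):
    TRIANGLE = "triangle"
    SQUARE = "square"
    PENTAGON = "pentagon"
    CUBE = "cube"
    OTHER = "other"


#: canonical strand counts of the panel architectures; ``other`` is exempt
SHAPE_STRAND_COUNTS = {
    Shape.TRIANGLE: 4,
    Shape.SQUARE: 5,
    Shape.PENTAGON: 6,
    Shape.CUBE: 6,
}

#: planar (2D) vs globular (3D) architectures
SHAPES_2D = (Shape.TRIANGLE, Shape.SQUARE, Shape.PENTAGON)
SHAPES_3D = (Shape.CUBE,)


def normalize_sequence(sequence: str) -> str:
    """Upper-case, strip whitespace, and validate the alphabet."""
    seq = "".join(sequence.split()).upper()
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)!r} in sequence")
    if "U" in seq and "T" in seq:
        raise SequenceError("sequence mixes U and T")
    return seq


def infer_strand_type(sequence: str) -> NucleicType:
    """Infer DNA/RNA from the discriminating base (T vs U).

    Raises :class:`AmbiguousStrandTypeError` when the sequence contains
    neither base, in which case the caller must declare the type.
    """
    seq = normalize_sequence(sequence)
    has_u, has_t = "U" in seq, "T" in seq
    if has_u:
        return NucleicType.RNA
    if has_t:
        return NucleicType.DNA
    raise AmbiguousStrandTypeError(
        "sequence contains neither U nor T; declare nucleic_type explicitly"
    )


@dataclass(frozen=True)
class Strand:
    """A single oligonucleotide of a NANP."""

    strand_id: str
    sequence: str
    nucleic_type: NucleicType

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        object.__setattr__(self, "nucleic_type", NucleicType(self.nucleic_type))
        if self.nucleic_type is NucleicType.RNA and "T" in self.sequence:
            raise SequenceError(f"RNA strand {self.strand_id!r} contains T")
        if self.nucleic_type is NucleicType.DNA and "U" in self.sequence:
            raise SequenceError(f"DNA strand {self.strand_id!r} contains U")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NANPRecord:
    """An ordered multi-strand construct with optional measured endpoints.

    Strand order is significant: it is the canonical input ordering that
    permutation augmentation reshuffles.
    """

    nanp_id: str
    shape: Shape
    strands: tuple[Strand, ...]
    endpoints: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", Shape(self.shape))
        object.__setattr__(self, "strands", tuple(self.strands))
        if len(self.strands) < 2:
            raise FormatError(f"{self.nanp_id}: a NANP needs at least 2 strands")
        expected = SHAPE_STRAND_COUNTS.get(self.shape)
        if expected is not None and len(self.strands) != expected:
            raise FormatError(
                f"{self.nanp_id}: shape {self.shape.value} implies "
                f"{expected} strands, got {len(self.strands)}"
            )
        if self.endpoints is not None:
            eps = dict(self.endpoints)
            for key, value in eps.items():
                if key not in ENDPOINTS:
                    raise FormatError(f"unknown endpoint {key!r}")
                if not math.isfinite(value):
                    raise InvalidMeasurementError(
                        f"{self.nanp_id}: non-finite {key} value"
                    )
            object.__setattr__(self, "endpoints", eps)

    @property
    def strand_count(self) -> int:
        return len(self.strands)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.strands)

    @property
    def is_3d(self) -> bool:
        return self.shape in SHAPES_3D


@dataclass
class NANPDataset:
    """A list of NANP records plus free-form provenance metadata."""

    records: list[NANPRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.nanp_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate nanp_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.nanp_id for r in self.records]

    def subset(self, nanp_ids: Iterable[str]) -> "NANPDataset":
        wanted = set(nanp_ids)
        return NANPDataset(
            [r for r in self.records if r.nanp_id in wanted],
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

#: base order for mononucleotide frequencies
MONO_BASES = ("A", "C", "G", "U", "T")

DESCRIPTOR_NAMES = (
    "rna_base_ratio",
    "strand_count",
    "total_length",
    "gc_fraction",
    "purine_fraction",
    "freq_A",
    "freq_C",
    "freq_G",
    "freq_U",
    "freq_T",
)


@dataclass(frozen=True)
class DescriptorVector:
    """Order-invariant composition descriptors of a NANP construct."""

    rna_base_ratio: float
    strand_count: int
    total_length: int
    gc_fraction: float
    purine_fraction: float
    mono_freqs: tuple[float, ...]  # A, C, G, U, T

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.rna_base_ratio,
                float(self.strand_count),
                float(self.total_length),
                self.gc_fraction,
                self.purine_fraction,
                *self.mono_freqs,
            ],
            dtype=float,
        )


def rna_base_ratio(record: NANPRecord) -> float:
    """Fraction of the construct's bases contributed by RNA strands."""
    rna = sum(len(s) for s in record.strands if s.nucleic_type is NucleicType.RNA)
    return rna / record.total_length


def compute_descriptors(record: NANPRecord) -> DescriptorVector:
    """Deterministic, strand-order-invariant composition descriptors."""
    joined = "".join(s.sequence for s in record.strands)
    n = len(joined)
    counts = {b: joined.count(b) for b in MONO_BASES}
    return DescriptorVector(
        rna_base_ratio=rna_base_ratio(record),
        strand_count=record.strand_count,
        total_length=n,
        gc_fraction=(counts["G"] + counts["C"]) / n,
        purine_fraction=(counts["A"] + counts["G"]) / n,
        mono_freqs=tuple(counts[b] / n for b in MONO_BASES),
    )


def descriptor_table(dataset: NANPDataset) -> pd.DataFrame:
    """Descriptor matrix for a dataset, indexed by nanp_id."""
    rows = {r.nanp_id: compute_descriptors(r).to_array() for r in dataset}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(DESCRIPTOR_NAMES)
    )


# ---------------------------------------------------------------------------
# Target transform
# ---------------------------------------------------------------------------


def log10_transform_targets(
    dataset: NANPDataset, floor: float = DEFAULT_LOG10_FLOOR
) -> NANPDataset:
    """Replace each endpoint y (pg/mL) with log10(max(y, floor)).

    The clamp keeps zero/near-zero assay readings finite; the floor is
    recorded in the returned dataset's metadata so the transform is
    invertible (for values above the floor) and metrics stay comparable.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = []
    for rec in dataset:
        if rec.endpoints is None:
            out.append(rec)
            continue
        transformed = {}
        for key, value in rec.endpoints.items():
            if value < 0:
                raise InvalidMeasurementError(
                    f"{rec.nanp_id}: negative {key} measurement ({value})"
                )
            transformed[key] = math.log10(max(value, floor))
        out.append(replace(rec, endpoints=transformed))
    meta = dict(dataset.metadata)
    meta["target_transform"] = {"type": "log10", "floor": floor}
    return NANPDataset(out, metadata=meta)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------


def split_dataset(
    dataset: NANPDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_by_shape: bool = True,
) -> tuple[NANPDataset, NANPDataset]:
    """Seeded disjoint train/test partition with |train| = floor(f * n).

    With ``stratify_by_shape`` each shape class contributes proportionally
    (largest-remainder rounding keeps the exact global train size).
    """
    n = len(dataset)
    if n < 2:
        raise CannotSplitError("need at least 2 records to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = math.floor(train_fraction * n)
    rng = np.random.default_rng(seed)

    if stratify_by_shape:
        groups: dict[Shape, list[int]] = {}
        for i, rec in enumerate(dataset.records):
            groups.setdefault(rec.shape, []).append(i)
        shapes = sorted(groups, key=lambda s: s.value)
        quota = {s: math.floor(train_fraction * len(groups[s])) for s in shapes}
        remainder = {
            s: train_fraction * len(groups[s]) - quota[s] for s in shapes
        }
        short = n_train - sum(quota.values())
        # hand leftover slots to the shapes with the largest fractional parts
        for s in sorted(shapes, key=lambda s: (-remainder[s], s.value)):
            if short <= 0:
                break
            if quota[s] < len(groups[s]):
                quota[s] += 1
                short -= 1
        train_idx: list[int] = []
        for s in shapes:
            order = rng.permutation(len(groups[s]))
            train_idx.extend(groups[s][j] for j in order[: quota[s]])
    else:
        order = rng.permutation(n)
        train_idx = list(order[:n_train])

    train_set = set(train_idx)
    train = [dataset.records[i] for i in sorted(train_set)]
    test = [r for i, r in enumerate(dataset.records) if i not in train_set]
    meta = dict(dataset.metadata)
    split_meta = {
        "train_fraction": train_fraction,
        "seed": seed,
        "stratify_by_shape": stratify_by_shape,
    }
    train_meta = {**meta, "split": {**split_meta, "part": "train"}}
    test_meta = {**meta, "split": {**split_meta, "part": "test"}}
    return NANPDataset(train, train_meta), NANPDataset(test, test_meta)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _records_from_manifest_frame(manifest: pd.DataFrame) -> list[NANPRecord]:
    missing = set(_MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    records = []
    for nanp_id, group in manifest.groupby("nanp_id", sort=False):
        idx = group["strand_index"].astype(int).tolist()
        if len(set(idx)) != len(idx):
            raise FormatError(f"{nanp_id}: duplicated strand_index")
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise FormatError(
                f"{nanp_id}: strand_index must be 1-based and contiguous"
            )
        group = group.iloc[np.argsort(idx)]
        shapes = set(group["shape"])
        if len(shapes) != 1:
            raise FormatError(f"{nanp_id}: inconsistent shape values")
        strands = []
        for _, row in group.iterrows():
            declared = str(row["nucleic_type"]).strip()
            seq = str(row["sequence"])
            if declared.lower() == "auto":
                ntype = infer_strand_type(seq)
            else:
                ntype = NucleicType(declared.upper())
            strands.append(Strand(str(row["strand_id"]), seq, ntype))
        records.append(
            NANPRecord(str(nanp_id), Shape(shapes.pop()), tuple(strands))
        )
    return records


def _attach_endpoints(
    records: list[NANPRecord], endpoints: pd.DataFrame
) -> tuple[list[NANPRecord], list[str]]:
    required = {"nanp_id", *_ENDPOINT_COLUMNS.values()}
    missing = required - set(endpoints.columns)
    if missing:
        raise FormatError(f"endpoint table missing columns: {sorted(missing)}")
    by_id = {}
    for _, row in endpoints.iterrows():
        eps = {}
        for key, col in _ENDPOINT_COLUMNS.items():
            value = row[col]
            if pd.notna(value) and str(value).strip() != "":
                eps[key] = float(value)
        by_id[str(row["nanp_id"])] = eps or None
    known = {r.nanp_id for r in records}
    warnings = [
        f"endpoint row for unknown nanp_id {i!r}" for i in by_id if i not in known
    ]
    out = [
        replace(r, endpoints=by_id[r.nanp_id])
        if r.nanp_id in by_id
        else r
        for r in records
    ]
    return out, warnings


def read_dataset(
    strand_manifest: str | Path,
    endpoints: str | Path | None = None,
) -> NANPDataset:
    """Load a dataset from a strand-manifest CSV (or FASTA) plus an
    optional endpoint CSV joined on ``nanp_id``.

    Manifest CSV columns: ``nanp_id,shape,strand_index,strand_id,
    nucleic_type,sequence`` (``nucleic_type`` may be ``auto``).  FASTA
    headers follow ``>nanp_id/strand_index [key=value ...]``.
    Unmatched endpoint rows are collected as join warnings in metadata.
    """
    strand_manifest = Path(strand_manifest)
    if strand_manifest.suffix.lower() in {".fa", ".fasta", ".fna"}:
        records = _read_fasta_records(strand_manifest)
    else:
        try:
            manifest = pd.read_csv(strand_manifest, dtype=str)
        except Exception as exc:  # malformed CSV
            raise FormatError(f"cannot parse manifest {strand_manifest}: {exc}")
        records = _records_from_manifest_frame(manifest)
    meta = {"source": str(strand_manifest)}
    if endpoints is not None:
        table = pd.read_csv(endpoints)
        records, warnings = _attach_endpoints(records, table)
        if warnings:
            meta["join_warnings"] = warnings
    return NANPDataset(records, metadata=meta)


def write_dataset(
    dataset: NANPDataset,
    strand_manifest: str | Path,
    endpoints: str | Path | None = None,
) -> None:
    """Write the manifest CSV (and optionally the endpoint CSV)."""
    rows = []
    for rec in dataset:
        for i, s in enumerate(rec.strands, start=1):
            rows.append(
                {
                    "nanp_id": rec.nanp_id,
                    "shape": rec.shape.value,
                    "strand_index": i,
                    "strand_id": s.strand_id,
                    "nucleic_type": s.nucleic_type.value,
                    "sequence": s.sequence,
                }
            )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        strand_manifest, index=False
    )
    if endpoints is not None:
        ep_rows = []
        for rec in dataset:
            eps = rec.endpoints or {}
            ep_rows.append(
                {
                    "nanp_id": rec.nanp_id,
                    _ENDPOINT_COLUMNS[IFNB]: eps.get(IFNB, ""),
                    _ENDPOINT_COLUMNS[IL6]: eps.get(IL6, ""),
                }
            )
        pd.DataFrame(ep_rows).to_csv(endpoints, index=False)


def _read_fasta_records(path: Path) -> list[NANPRecord]:
    per_nanp: dict[str, list[tuple[int, Strand, dict]]] = {}
    for seqrec in SeqIO.parse(str(path), "fasta"):
        head = seqrec.id
        if "/" not in head:
            raise FormatError(f"FASTA header {head!r} lacks nanp_id/strand_index")
        nanp_id, _, idx_str = head.partition("/")
        try:
            idx = int(idx_str)
        except ValueError:
            raise FormatError(f"FASTA header {head!r}: bad strand_index")
        attrs = {}
        for tok in seqrec.description.split()[1:]:
            if "=" in tok:
                key, _, value = tok.partition("=")
                attrs[key] = value
        declared = attrs.get("nucleic_type", "auto")
        seq = str(seqrec.seq)
        if declared.lower() == "auto":
            ntype = infer_strand_type(seq)
        else:
            ntype = NucleicType(declared.upper())
        strand = Strand(attrs.get("strand_id", head), seq, ntype)
        per_nanp.setdefault(nanp_id, []).append((idx, strand, attrs))
    records = []
    for nanp_id, entries in per_nanp.items():
        idx = [e[0] for e in entries]
        if len(set(idx)) != len(idx):
            raise FormatError(f"{nanp_id}: duplicated strand_index in FASTA")
        entries.sort(key=lambda e: e[0])
        shapes = {e[2].get("shape", "other") for e in entries}
        shapes.discard("other")
        shape = Shape(shapes.pop()) if len(shapes) == 1 else Shape.OTHER
        records.append(
            NANPRecord(nanp_id, shape, tuple(e[1] for e in entries))
        )
    return records


def write_fasta(dataset: NANPDataset, path: str | Path) -> None:
    """Write strands as FASTA with ``>nanp_id/strand_index`` headers."""
    seqrecs = []
    for rec in dataset:
        for i, s in enumerate(rec.strands, start=1):
            seqrecs.append(
                SeqRecord(
                    Seq(s.sequence),
                    id=f"{rec.nanp_id}/{i}",
                    description=(
                        f"{rec.nanp_id}/{i} shape={rec.shape.value} "
                        f"nucleic_type={s.nucleic_type.value} strand_id={s.strand_id}"
                    ),
                )
            )
    SeqIO.write(seqrecs, str(path), "fasta")


def write_predictions(
    rows: Sequence[Mapping[str, object]], path: str | Path
) -> None:
    """Write the standard predictions CSV."""
    cols = [
        "nanp_id",
        "endpoint",
        "prediction_log10",
        "prediction_pg_ml",
        "n_permutations_aggregated",
    ]
    pd.DataFrame(list(rows), columns=cols).to_csv(path, index=False)
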