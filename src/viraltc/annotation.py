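"""Genome annotation data model and GFF3 / TSV input-output.

Coordinates are 0-based half-open internally; all file formats use the
1-based inclusive convention of GFF3.  This module fixes the coordinate
contract for the whole package: a feature of length L occupies
``[start, end)`` with ``end - start == L``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Strand",
    "FeatureKind",
    "AnnotatedFeature",
    "GenomeAnnotation",
    "read_annotation",
    "write_annotation",
    "intergenic_gap",
    "AnnotationError",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invariant violations."""


class Strand(enum.Enum):
    FORWARD = "+"
    REVERSE = "-"

    @classmethod
    def from_symbol(cls, symbol: str) -> "Strand":
        try:
            return cls(symbol)
        except ValueError:
            raise AnnotationError(f"unknown strand symbol {symbol!r}") from None

    @property
    def opposite(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD


class FeatureKind(enum.Enum):
    ORF = "ORF"
    TRNA = "tRNA"


#: GFF3 type column values accepted for each feature kind.
_GFF_TYPE_TO_KIND = {"CDS": FeatureKind.ORF, "ORF": FeatureKind.ORF, "tRNA": FeatureKind.TRNA}
_KIND_TO_GFF_TYPE = {FeatureKind.ORF: "CDS", FeatureKind.TRNA: "tRNA"}


@dataclass(frozen=True)
class AnnotatedFeature:
    """A single annotated feature (ORF or tRNA) on the genome.

    ``start``/``end`` are 0-based half-open.  ``functional_group`` is a
    free-text module label such as "structural" or "DNA metabolism".
    """

    feature_id: str
    start: int
    end: int
    strand: Strand
    kind: FeatureKind = FeatureKind.ORF
    functional_group: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"feature {self.feature_id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise AnnotationError(f"feature {self.feature_id!r}: negative start {self.start}")
        if self.kind is FeatureKind.ORF and self.length < 3:
            raise AnnotationError(
                f"ORF {self.feature_id!r} has length {self.length} < 3 nt"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """0-based position of the first transcribed base of the feature."""
        return self.start if self.strand is Strand.FORWARD else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand is Strand.FORWARD else self.start


@dataclass
class GenomeAnnotation:
    """An ordered feature set over a single (viral) genome.

    ``topology`` is "linear" or "circular"; gap and coverage arithmetic in
    this package never wraps around, matching a linear analysis of a
    circularly permuted genome.
    """

    genome_id: str
    genome_length: int
    features: list[AnnotatedFeature] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise AnnotationError(f"unknown topology {self.topology!r}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.feature_id in seen:
                raise AnnotationError(f"duplicate feature_id {f.feature_id!r}")
            seen.add(f.feature_id)
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"feature {f.feature_id!r} ends at {f.end}, beyond genome length "
                    f"{self.genome_length}"
                )

    def __iter__(self) -> Iterator[AnnotatedFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, feature_id: str) -> AnnotatedFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def add(self, feature: AnnotatedFeature) -> None:
        """Insert a feature, keeping genome order and invariants."""
        self.features.append(feature)
        self.features.sort(key=lambda f: (f.start, f.end))
        self._validate()

    def on_strand(self, strand: Strand) -> list[AnnotatedFeature]:
        return [f for f in self.features if f.strand is strand]

    def mirrored(self) -> "GenomeAnnotation":
        """Coordinate-mirrored annotation (position p -> L-1-p, strands swapped)."""
        L = self.genome_length
        feats = [
            replace(f, start=L - f.end, end=L - f.start, strand=f.strand.opposite)
            for f in self.features
        ]
        return GenomeAnnotation(self.genome_id, L, feats, self.topology)


def intergenic_gap(a: AnnotatedFeature, b: AnnotatedFeature) -> int:
    """Signed intergenic distance between two same-strand neighbours.

    ``a`` must precede ``b`` in genome order.  Returns ``b.start - a.end``;
    negative values denote overlapping coding sequences (e.g. the 4-nt
    ATGA-type stop/start overlap yields -4).
    """
    if a.strand is not b.strand:
        raise AnnotationError(
            f"intergenic gap undefined across strands ({a.feature_id!r} vs {b.feature_id!r})"
        )
    if b.start < a.start:
        raise AnnotationError(f"{a.feature_id!r} does not precede {b.feature_id!r}")
    return b.start - a.end


def _parse_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in column.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_annotation(
    path: str | Path,
    *,
    function_attr: str = "function",
    topology: str = "linear",
) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  The functional group is taken from the
    attribute named ``function_attr``.  Genome length comes from a
    ``##sequence-region`` directive when present, otherwise from the
    rightmost feature end.
    """
    path = Path(path)
    genome_id = path.stem
    genome_length: int | None = None
    features: list[AnnotatedFeature] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    genome_id = parts[1]
                    genome_length = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, _source, gff_type, start1, end1, _score, strand_sym, _phase, attr_col = cols
            if gff_type not in _GFF_TYPE_TO_KIND:
                continue  # silently skip feature types outside the model (e.g. region)
            try:
                start = int(start1) - 1  # GFF3 1-based inclusive -> 0-based half-open
                end = int(end1)
            except ValueError:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-integer coordinates {start1!r}/{end1!r}"
                ) from None
            attrs = _parse_attributes(attr_col)
            feature_id = attrs.get("ID") or attrs.get("Name")
            if feature_id is None:
                raise AnnotationError(f"{path.name}:{lineno}: feature without ID attribute")
            genome_id = seqid
            try:
                features.append(
                    AnnotatedFeature(
                        feature_id=feature_id,
                        start=start,
                        end=end,
                        strand=Strand.from_symbol(strand_sym),
                        kind=_GFF_TYPE_TO_KIND[gff_type],
                        functional_group=attrs.get(function_attr, ""),
                    )
                )
            except AnnotationError as err:
                raise AnnotationError(f"{path.name}:{lineno}: {err}") from None
    if genome_length is None:
        genome_length = max((f.end for f in features), default=0)
    return GenomeAnnotation(genome_id, genome_length, features, topology)


def write_annotation(
    ann: GenomeAnnotation, path: str | Path, *, function_attr: str = "function"
) -> None:
    """Write a GFF3 file; inverse of :func:`read_annotation` field-for-field."""
    path = Path(path)
    lines = ["##gff-version 3", f"##sequence-region {ann.genome_id} 1 {ann.genome_length}"]
    for f in ann.features:
        attrs = f"ID={f.feature_id}"
        if f.functional_group:
            attrs += f";{function_attr}={f.functional_group}"
        lines.append(
            "\t".join(
                [
                    ann.genome_id,
                    "viraltc",
                    _KIND_TO_GFF_TYPE[f.kind],
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand.value,
                    "0" if f.kind is FeatureKind.ORF else ".",
                    attrs,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def features_to_table(ann: GenomeAnnotation):
    """Feature table with 1-based inclusive coordinates, for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in ann.features],
            "start1": [f.start + 1 for f in ann.features],
            "end1": [f.end for f in ann.features],
            "strand": [f.strand.value for f in ann.features],
            "kind": [f.kind.value for f in ann.features],
            "functional_group": [f.functional_group for f in ann.features],
        }
    )
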