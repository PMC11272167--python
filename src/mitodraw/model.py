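"""Internal annotation model.

A mitochondrial genome annotation is a genome length, a topology, and an
ordered list of features.  Coordinates are stored 0-based with an explicit
length; a feature that spans the origin of a circular genome is a single
record whose ``start + length`` exceeds the genome length and is interpreted
modulo the genome length.  This keeps rotation (re-origin) and strand
reflection as plain modular arithmetic with no split-feature bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Tuple

from .errors import InvalidColor, InvalidFeature

Color = Tuple[int, int, int]


class FeatureClass(str, Enum):
    """Biological class of an annotated feature."""

    PCG = "PCG"      # protein-coding gene
    tRNA = "tRNA"
    rRNA = "rRNA"
    other = "other"  # control region, origins of replication, unknowns


class Strand(str, Enum):
    forward = "+"
    reverse = "-"

    def flipped(self) -> "Strand":
        return Strand.reverse if self is Strand.forward else Strand.forward


class Topology(str, Enum):
    circular = "circular"
    linear = "linear"


def validate_color(color: object) -> Color:
    """Check that *color* is an RGB triple with integer channels in [0, 255]."""
    try:
        r, g, b = color  # type: ignore[misc]
    except (TypeError, ValueError):
        raise InvalidColor(f"not an RGB triple: {color!r}")
    channels = (r, g, b)
    for c in channels:
        if not isinstance(c, int) or isinstance(c, bool) or not 0 <= c <= 255:
            raise InvalidColor(f"channel out of [0, 255]: {c!r}")
    return (r, g, b)


@dataclass(frozen=True)
class Feature:
    """One annotated element: a gene, tRNA, rRNA, or non-coding region.

    Parameters
    ----------
    name:
        Non-empty text label (parsers assign ``feature_<k>`` when the input
        carries no name).
    feature_class:
        One of PCG / tRNA / rRNA / other.
    start:
        0-based base-pair offset, ``0 <= start < genome_length``.
    length:
        Span in base pairs, ``1 <= length <= genome_length``.  A feature with
        ``start + length > genome_length`` wraps the origin.
    strand:
        Forward or reverse.
    color:
        Optional per-feature RGB override; takes precedence over the
        per-class palette.
    source_key:
        The key the feature carried in its source file (``"CDS"``,
        ``"tRNA"``, ``"D-loop"``, ...), kept for provenance.
    """

    name: str
    feature_class: FeatureClass
    start: int
    length: int
    strand: Strand
    color: Optional[Color] = None
    source_key: Optional[str] = None

    @property
    def end(self) -> int:
        """Exclusive end offset; exceeds the genome length for wrapping features."""
        return self.start + self.length

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def midpoint(self, genome_length: int) -> float:
        """Midpoint position in [0, genome_length)."""
        return (self.start + self.length / 2.0) % genome_length

    def validate(self, genome_length: int) -> None:
        if not self.name:
            raise InvalidFeature("feature name is empty")
        if not 0 <= self.start < genome_length:
            raise InvalidFeature(
                f"{self.name}: start {self.start} outside [0, {genome_length})"
            )
        if not 1 <= self.length <= genome_length:
            raise InvalidFeature(
                f"{self.name}: length {self.length} outside [1, {genome_length}]"
            )
        if self.color is not None:
            validate_color(self.color)

    def covered_positions(self, genome_length: int) -> Iterable[int]:
        """Yield every base offset the feature covers (modulo the origin)."""
        for i in range(self.length):
            yield (self.start + i) % genome_length


@dataclass(frozen=True)
class EditEntry:
    """One replayable edit: operation name, parameters, sequence number."""

    op: str
    params: Tuple[Tuple[str, object], ...]
    seq: int

    def param_dict(self) -> dict:
        return dict(self.params)


def _sorted_features(features: Iterable[Feature]) -> Tuple[Feature, ...]:
    return tuple(sorted(features, key=lambda f: (f.start, f.name)))


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome length, a topology, and an ordered set of features.

    Features are kept sorted by ``(start, name)``; all editing operations
    return a new annotation, so instances can be shared freely.
    """

    genome_length: int
    topology: Topology = Topology.circular
    features: Tuple[Feature, ...] = ()
    title: str = ""
    edit_log: Tuple[EditEntry, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise InvalidFeature(f"genome length must be >= 1, got {self.genome_length}")
        object.__setattr__(self, "features", _sorted_features(self.features))
        for f in self.features:
            f.validate(self.genome_length)

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.features)

    def features_named(self, name: str) -> Tuple[Feature, ...]:
        return tuple(f for f in self.features if f.name == name)

    def class_counts(self) -> dict:
        counts = {cls: 0 for cls in FeatureClass}
        for f in self.features:
            counts[f.feature_class] += 1
        return counts

    def semantic_key(self) -> tuple:
        """Fields compared by round-trip and cross-format equivalence checks."""
        return (
            self.genome_length,
            self.topology,
            tuple(
                (f.name, f.feature_class, f.start, f.length, f.strand)
                for f in self.features
            ),
        )

    # -- construction helpers ---------------------------------------------

    def with_features(self, features: Iterable[Feature]) -> "GenomeAnnotation":
        return replace(self, features=_sorted_features(features))

    def logged(self, op: str, **params: object) -> "GenomeAnnotation":
        entry = EditEntry(op=op, params=tuple(sorted(params.items())), seq=len(self.edit_log))
        return replace(self, edit_log=self.edit_log + (entry,))
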