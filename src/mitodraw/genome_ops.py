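"""Coordinate algebra and editing on genome annotations.

De novo mitogenome assemblies linearize the circular molecule at an
arbitrary point and in an arbitrary orientation; these operations rotate
the coordinate system to a new origin and reflect it onto the complementary
strand so that a set of maps can share a standardized style (for instance,
every map starting at tRNA-Met on the forward strand).

All operations are pure: they return a new :class:`GenomeAnnotation` and
append a replayable entry to its edit log.

With genome length ``L``, re-origin to ``k`` maps each feature start ``s``
to ``(s - k) mod L``; strand reflection maps ``s`` to ``(L - s - len) mod
L`` and toggles every strand.  Both preserve feature lengths, names, and
classes; reflection of an origin-spanning feature is again origin-spanning.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Optional, Union

from .errors import (
    AmbiguousName,
    FeatureNotFound,
    InvalidFeature,
    LinearTopology,
)
from .model import (
    Color,
    EditEntry,
    Feature,
    FeatureClass,
    GenomeAnnotation,
    Strand,
    Topology,
    validate_color,
)


def set_origin(annotation: GenomeAnnotation, new_start: int) -> GenomeAnnotation:
    """Rotate a circular annotation so that coordinate *new_start* becomes 0.

    Lengths, strands, names, classes, and the cyclic order of features are
    unchanged; only starts move, by ``(start - new_start) mod L``.
    """
    if annotation.topology is not Topology.circular:
        raise LinearTopology("cannot re-origin a linear annotation")
    L = annotation.genome_length
    if not 0 <= new_start < L:
        raise InvalidFeature(f"new origin {new_start} outside [0, {L})")
    moved = [
        replace(f, start=(f.start - new_start) % L) for f in annotation.features
    ]
    return annotation.with_features(moved).logged("set_origin", new_start=new_start)


def flip_strand(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Re-express the annotation on the complementary strand.

    Every start reflects to ``(L - start - length) mod L`` and every strand
    toggles; the operation is an involution.
    """
    L = annotation.genome_length
    flipped = [
        replace(f, start=(L - f.start - f.length) % L, strand=f.strand.flipped())
        for f in annotation.features
    ]
    return annotation.with_features(flipped).logged("flip_strand")


def _single_feature(annotation: GenomeAnnotation, name: str) -> Feature:
    matches = annotation.features_named(name)
    if not matches:
        raise FeatureNotFound(f"no feature named {name!r}")
    return matches[0]


def set_origin_to_feature(annotation: GenomeAnnotation, feature_name: str) -> GenomeAnnotation:
    """Rotate (and, if needed, strand-flip) so the named feature starts at 0
    on the forward strand.

    This is the one-call standardization step: if the anchor lies on the
    reverse strand the whole annotation is flipped first, then rotated.
    """
    anchor = _single_feature(annotation, feature_name)
    result = annotation
    if anchor.strand is Strand.reverse:
        result = flip_strand(result)
        anchor = _single_feature(result, feature_name)
    return set_origin(result, anchor.start)


def add_feature(annotation: GenomeAnnotation, feature: Feature) -> GenomeAnnotation:
    """Insert *feature*, validating it against the genome length."""
    feature.validate(annotation.genome_length)
    return annotation.with_features(annotation.features + (feature,)).logged(
        "add_feature",
        name=feature.name,
        feature_class=feature.feature_class.value,
        start=feature.start,
        length=feature.length,
        strand=feature.strand.value,
        color=feature.color,
        source_key=feature.source_key,
    )


def delete_feature(annotation: GenomeAnnotation, name: str) -> GenomeAnnotation:
    """Remove every feature with exactly this name."""
    kept = [f for f in annotation.features if f.name != name]
    if len(kept) == len(annotation.features):
        raise FeatureNotFound(f"no feature named {name!r}")
    return annotation.with_features(kept).logged("delete_feature", name=name)


def rename_feature(
    annotation: GenomeAnnotation, old_name: str, new_name: str
) -> GenomeAnnotation:
    """Rename one feature.  The stored class is left untouched; renaming does
    not re-run classification."""
    if not new_name:
        raise InvalidFeature("new name is empty")
    matches = annotation.features_named(old_name)
    if not matches:
        raise FeatureNotFound(f"no feature named {old_name!r}")
    if len(matches) > 1:
        raise AmbiguousName(
            f"{old_name!r} matches {len(matches)} features; rename is one-to-one"
        )
    updated = [
        replace(f, name=new_name) if f.name == old_name else f
        for f in annotation.features
    ]
    return annotation.with_features(updated).logged(
        "rename_feature", old_name=old_name, new_name=new_name
    )


def set_feature_color(
    annotation: GenomeAnnotation, name: str, color: Color
) -> GenomeAnnotation:
    """Set a per-feature color override (strongest precedence)."""
    color = validate_color(color)
    if not annotation.features_named(name):
        raise FeatureNotFound(f"no feature named {name!r}")
    updated = [
        replace(f, color=color) if f.name == name else f for f in annotation.features
    ]
    return annotation.with_features(updated).logged(
        "set_feature_color", name=name, color=color
    )


def set_class_color(target, feature_class, color: Color):
    """Color every feature of one class.

    Applied to a :class:`~mitodraw.layout_engine.Style`, updates its
    palette; applied to a :class:`GenomeAnnotation`, stamps the color onto
    each member feature (later per-feature overrides still win, since they
    simply overwrite it).
    """
    from .layout_engine import Style  # local import to avoid a cycle

    color = validate_color(color)
    feature_class = FeatureClass(feature_class)
    if isinstance(target, Style):
        palette = dict(target.palette)
        palette[feature_class] = color
        return replace(target, palette=palette)
    if isinstance(target, GenomeAnnotation):
        updated = [
            replace(f, color=color) if f.feature_class is feature_class else f
            for f in target.features
        ]
        return target.with_features(updated).logged(
            "set_class_color", feature_class=feature_class.value, color=color
        )
    raise TypeError(f"expected Style or GenomeAnnotation, got {type(target).__name__}")


# ---------------------------------------------------------------------------
# edit-log replay
# ---------------------------------------------------------------------------

def replay_log(
    original: GenomeAnnotation, log: Optional[Iterable[EditEntry]] = None
) -> GenomeAnnotation:
    """Re-apply an edit log to *original*; with the default log this
    reconstructs the annotation that carried it."""
    entries = tuple(log) if log is not None else original.edit_log
    result = replace(original, edit_log=())
    for entry in entries:
        p = entry.param_dict()
        if entry.op == "set_origin":
            result = set_origin(result, p["new_start"])
        elif entry.op == "flip_strand":
            result = flip_strand(result)
        elif entry.op == "add_feature":
            result = add_feature(
                result,
                Feature(
                    name=p["name"],
                    feature_class=FeatureClass(p["feature_class"]),
                    start=p["start"],
                    length=p["length"],
                    strand=Strand(p["strand"]),
                    color=p.get("color"),
                    source_key=p.get("source_key"),
                ),
            )
        elif entry.op == "delete_feature":
            result = delete_feature(result, p["name"])
        elif entry.op == "rename_feature":
            result = rename_feature(result, p["old_name"], p["new_name"])
        elif entry.op == "set_feature_color":
            result = set_feature_color(result, p["name"], tuple(p["color"]))
        elif entry.op == "set_class_color":
            result = set_class_color(
                result, FeatureClass(p["feature_class"]), tuple(p["color"])
            )
        else:
            raise ValueError(f"unknown edit-log operation {entry.op!r}")
    return result
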