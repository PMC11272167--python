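"""Built-in test genomes: a canonical vertebrate mitogenome and seeded
random mitogenomes.

The canonical annotation mirrors the human mitochondrial gene arrangement
(16,569 bp, circular): 13 protein-coding genes, 22 tRNAs, and 2 rRNAs — the
37 transcribed features nearly universal in animals — plus the non-coding
control region, which spans the conventional origin.  It reproduces the
hallmarks that stress a map renderer: the WANCY block of five tandem tRNAs,
the reverse-strand cluster around nad6, short tRNAs whose labels can never
fit inside their arrows, and an origin-spanning feature.  Coordinates are
fixed constants close to the reference gene order; it is the order, strand
pattern, and class counts that matter for drawing, not base-exact spans.

Random mitogenomes draw a genome length uniformly from the 11-28 kb range
observed across animals, then place non-overlapping features with
class-realistic lengths (tRNA 60-80 bp, rRNA 800-1700 bp, protein genes
200-1900 bp) in a seeded shuffle of the canonical gene complement.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Dict, Optional, Tuple

from . import annotation_io
from .annotation_io import Format, classify_feature
from .model import Feature, FeatureClass, GenomeAnnotation, Strand, Topology

CANONICAL_LENGTH = 16_569

# (name, class, start 1-based, end 1-based inclusive, strand); end < start
# on the last row marks the origin-spanning control region.
_CANONICAL_TABLE: Tuple[Tuple[str, str, int, int, str], ...] = (
    ("trnF", "tRNA", 577, 647, "+"),
    ("rrnS", "rRNA", 648, 1601, "+"),
    ("trnV", "tRNA", 1602, 1670, "+"),
    ("rrnL", "rRNA", 1671, 3229, "+"),
    ("trnL2", "tRNA", 3230, 3304, "+"),
    ("nad1", "PCG", 3307, 4262, "+"),
    ("trnI", "tRNA", 4263, 4331, "+"),
    ("trnQ", "tRNA", 4332, 4400, "-"),
    ("trnM", "tRNA", 4402, 4469, "+"),
    ("nad2", "PCG", 4470, 5511, "+"),
    ("trnW", "tRNA", 5512, 5579, "+"),
    ("trnA", "tRNA", 5587, 5655, "-"),
    ("trnN", "tRNA", 5657, 5729, "-"),
    ("trnC", "tRNA", 5761, 5826, "-"),
    ("trnY", "tRNA", 5827, 5891, "-"),
    ("cox1", "PCG", 5904, 7445, "+"),
    ("trnS2", "tRNA", 7446, 7514, "-"),
    ("trnD", "tRNA", 7518, 7585, "+"),
    ("cox2", "PCG", 7586, 8269, "+"),
    ("trnK", "tRNA", 8295, 8364, "+"),
    ("atp8", "PCG", 8366, 8572, "+"),
    ("atp6", "PCG", 8527, 9207, "+"),
    ("cox3", "PCG", 9208, 9990, "+"),
    ("trnG", "tRNA", 9991, 10058, "+"),
    ("nad3", "PCG", 10059, 10404, "+"),
    ("trnR", "tRNA", 10405, 10469, "+"),
    ("nad4l", "PCG", 10470, 10766, "+"),
    ("nad4", "PCG", 10760, 12137, "+"),
    ("trnH", "tRNA", 12138, 12206, "+"),
    ("trnS1", "tRNA", 12207, 12265, "+"),
    ("trnL1", "tRNA", 12266, 12336, "+"),
    ("nad5", "PCG", 12337, 14148, "+"),
    ("nad6", "PCG", 14149, 14673, "-"),
    ("trnE", "tRNA", 14674, 14742, "-"),
    ("cob", "PCG", 14747, 15887, "+"),
    ("trnT", "tRNA", 15888, 15953, "+"),
    ("trnP", "tRNA", 15956, 16023, "-"),
    ("D-loop", "other", 16024, 576, "+"),
)


def make_canonical_mitogenome() -> GenomeAnnotation:
    """The canonical vertebrate mitogenome annotation (37 transcribed
    features + control region, human gene order, 16,569 bp circular)."""
    features = []
    for name, cls, start1, end1, strand in _CANONICAL_TABLE:
        if end1 >= start1:
            length = end1 - start1 + 1
        else:  # spans the origin
            length = (CANONICAL_LENGTH - start1 + 1) + end1
        features.append(
            Feature(
                name=name,
                feature_class=FeatureClass(cls),
                start=start1 - 1,
                length=length,
                strand=Strand(strand),
                source_key="D-loop" if name == "D-loop" else None,
            )
        )
    return GenomeAnnotation(
        genome_length=CANONICAL_LENGTH,
        topology=Topology.circular,
        features=tuple(features),
        title="canonical vertebrate mitogenome",
    )


# class-realistic feature length ranges (bp)
_LENGTH_RANGES: Dict[FeatureClass, Tuple[int, int]] = {
    FeatureClass.tRNA: (60, 80),
    FeatureClass.rRNA: (800, 1700),
    FeatureClass.PCG: (200, 1900),
    FeatureClass.other: (200, 1200),
}

MIN_GENOME_LENGTH = 11_000
MAX_GENOME_LENGTH = 28_000

_TRNA_LETTERS = "FVLIQMWANCYSDKGRHEPT"


def _composition(n_features: int) -> Dict[FeatureClass, int]:
    """Split a feature budget with the canonical 13:22:2 proportions."""
    n_trna = max(0, round(n_features * 22 / 37))
    n_rrna = min(2, max(0, n_features - n_trna)) if n_features > 2 else 0
    n_pcg = max(0, n_features - n_trna - n_rrna)
    return {
        FeatureClass.tRNA: n_trna,
        FeatureClass.rRNA: n_rrna,
        FeatureClass.PCG: n_pcg,
    }


def _names_for(cls: FeatureClass, count: int) -> list:
    canonical = {
        FeatureClass.tRNA: [f"trn{_TRNA_LETTERS[i % len(_TRNA_LETTERS)]}"
                            + ("" if i < len(_TRNA_LETTERS) else str(i))
                            for i in range(count)],
        FeatureClass.rRNA: [["rrnS", "rrnL"][i] if i < 2 else f"rrn{i}"
                            for i in range(count)],
        FeatureClass.PCG: [sorted(annotation_io.PCG_NAMES)[i % 13]
                           + ("" if i < 13 else f"_{i // 13}")
                           for i in range(count)],
    }
    return canonical[cls]


def make_random_mitogenome(
    seed: int, n_features: Optional[int] = None
) -> GenomeAnnotation:
    """A seeded random circular mitogenome annotation.

    Genome length is uniform on [11,000, 28,000] bp; features do not
    overlap and never span the origin; the same seed always yields the
    identical annotation.
    """
    rng = random.Random(int(seed))
    genome_length = rng.randint(MIN_GENOME_LENGTH, MAX_GENOME_LENGTH)

    if n_features is None:
        pool = [
            (name, FeatureClass(cls))
            for name, cls, _, _, _ in _CANONICAL_TABLE
            if cls != "other"
        ]
    else:
        pool = []
        for cls, count in _composition(n_features).items():
            pool.extend((name, cls) for name in _names_for(cls, count))
    rng.shuffle(pool)

    lengths = [rng.randint(*_LENGTH_RANGES[cls]) for _, cls in pool]
    # keep ~10% of the molecule non-coding so placement always succeeds
    budget = int(0.9 * genome_length)
    total = sum(lengths)
    if total > budget:
        shrink = budget / total
        lengths = [
            max(_LENGTH_RANGES[cls][0] // 2, int(l * shrink))
            for l, (_, cls) in zip(lengths, pool)
        ]
        total = sum(lengths)

    slack = genome_length - total
    cuts = sorted(rng.randint(0, slack) for _ in range(len(pool)))
    gaps = [cuts[0]] + [b - a for a, b in zip(cuts, cuts[1:])]

    features = []
    pos = 0
    for (name, cls), length, gap in zip(pool, lengths, gaps):
        pos += gap
        features.append(
            Feature(
                name=name,
                feature_class=cls,
                start=pos,
                length=length,
                strand=Strand.reverse if rng.random() < 0.25 else Strand.forward,
            )
        )
        pos += length
    annotation = GenomeAnnotation(
        genome_length=genome_length,
        topology=Topology.circular,
        features=tuple(features),
        title=f"random mitogenome (seed={seed})",
    )
    return annotation


def write_fixture_tree(annotation: GenomeAnnotation, directory, stem: str = "fixture"):
    """Serialize *annotation* to every supported dialect in *directory*;
    returns the mapping of format name to file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffixes = {
        Format.genbank: ".gb",
        Format.gff3: ".gff3",
        Format.gtf: ".gtf",
        Format.bed: ".bed",
        Format.tsv: ".tsv",
    }
    paths = {}
    for fmt, suffix in suffixes.items():
        path = directory / f"{stem}{suffix}"
        annotation_io.write_annotation(annotation, path, fmt)
        paths[fmt.value] = path
    return paths


def longest_trna_run(annotation: GenomeAnnotation) -> int:
    """Length of the longest run of adjacent tRNA features in start order,
    treating the feature list as circular."""
    classes = [f.feature_class for f in annotation.features]
    if not classes:
        return 0
    if all(c is FeatureClass.tRNA for c in classes):
        return len(classes)
    doubled = classes + classes
    best = run = 0
    for c in doubled:
        run = run + 1 if c is FeatureClass.tRNA else 0
        best = max(best, run)
    return min(best, len(classes))
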