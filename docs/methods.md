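# Methods

## Annotation model

A `GenomeAnnotation` is a genome length `L` (bp), a topology (circular or
linear), and an ordered list of features `(name, class, start, length,
strand, color, source_key)`. Coordinates are 0-based with explicit length.
A feature spanning the origin of a circular molecule is one record with
`start + length > L`, interpreted modulo `L` — never a split pair. This
makes re-origin and strand reflection single modular maps
(`start ↦ (start − k) mod L` and `start ↦ (L − start − length) mod L`) and
keeps both closed over origin-spanning features: the reflection of a wrap
is again a wrap, which the tests verify against a per-base painting oracle.

Feature classes are PCG (protein-coding gene), tRNA, rRNA, and other. The
classifier is a fixed cascade: an unambiguous source key from the file
(`tRNA`, `rRNA`, `CDS`; plus `PCG`/`other` so the package's own TSV column
round-trips exactly) decides immediately; otherwise case-insensitive name
rules fire — `trn`/`tRNA-` prefixes, `rrn`/`12S`/`16S`/`rRNA` markers, and
membership of the normalized name in the canonical animal set {nad1–6,
nad4l, cox1–3, cob, atp6, atp8} with the usual synonyms (ND*, CO I–III,
CYTB, MT- prefixes). Everything else is `other`. Renaming a feature never
re-runs classification; the stored class is authoritative.

## File dialects

GenBank feature tables are read and written through Biopython (feature
table only; ORIGIN blocks are ignored — the tool draws annotations, not
sequence). Origin-spanning `join(a..L,1..b)` locations collapse to one
wrapping record; a CDS/tRNA/rRNA sharing exact coordinates with its `gene`
record collapses to one feature, the gene supplying the name (name
priority `/gene` > `/product` > `/note`). GFF3 and GTF lines are parsed
with gffutils' line-level parser; BED6 (the MITOS export format) and the
TSV dialect are parsed directly. Genome length comes from the LOCUS line,
a `##sequence-region` directive, or a `#length=` directive, else from the
maximum feature end; in tabular formats an end beyond a declared length
marks an origin-spanning feature (the GFF3 circular-genome convention,
extended to BED and TSV). Unknown feature types degrade to class `other`;
out-of-bounds coordinates raise, never truncate. Unnamed features get
`feature_<k>`.

The TSV dialect is: optional `#length=<bp>` (and `#topology=linear`)
directives, header `name/type/start/end/strand` (tab-separated, 1-based
inclusive, strand `+`/`-`). The writer puts the feature class in the type
column, so parse∘write is the identity on all semantic fields — a
property the suite checks for arbitrary generated annotations. A file with
zero feature rows is an error unless a length directive still defines a
genome.

## Map geometry

All geometry is computed on a logical canvas in pixels at 100 dpi
(default 800×800, i.e. 8×8 inches), y growing downward; rendering scales
linearly with the requested dpi. Angles are degrees clockwise from
12 o'clock: position `p` maps to `360·p/L`, so arrow spans conserve angle
(`Σ spans = 360·Σ lengths / L`) to floating-point precision.

Circular maps put forward-strand arrows on the outer ring (centerline at
`ring_radius` × half-canvas, default 0.72) and reverse-strand arrows on an
inner ring one thickness + gap further in. A wrapping feature is one
unbroken glyph whose end angle passes 360°. Linear maps put forward
features on the upper row and reverse on the lower, x scaled into the
canvas minus margins; a wrapping feature splits into right-end and
left-end pieces sharing one label, with the 5′→3′ arrowhead on the piece
holding the 3′ end. Arrowheads occupy `arrowhead_fraction` (default 0.35)
of the glyph span.

Text is measured with a fixed per-character advance (`char_advance`,
default 6 px at `font_size` 10 pt) and a 1.2 em line height, never with
real font metrics: layouts are therefore bit-identical across platforms
and font stacks, at the cost of a few pixels of slack versus true glyph
widths.

### Label placement

A name that fits inside its arrow (arc/chord length minus clearance, and
ring thickness for height) is drawn there — tangentially on circular maps,
flipped where needed so it stays upright. Anything else goes beside the
arrow at 90°: radially outward just beyond the outer ring on circular
maps, vertically above/below the rows on linear maps. Overlap is limited
by a bounded greedy sweep: internal labels are accepted in glyph order
(an internal label that would overlap an accepted box is demoted to
external — possible when features themselves overlap); external labels are
processed in (anchor, name) order and nudged forward in steps of one label
height (angular step `height/radius`) until their axis-aligned boxes stop
intersecting, up to `max_label_shift_steps` (default 24), after which the
label is accepted as-is. Manual per-feature anchor offsets in
`Style.label_offsets` (degrees on circular, pixels on linear maps) are
applied first and exempt that label from nudging. The sweep is a
deterministic heuristic, not a global optimizer: it guarantees
collision-free boxes in all but adversarial cases (dozens of labels forced
to one spot), and ties are broken by feature name so output never depends
on iteration order.

### Auto-fit

Circular layouts finish with an auto-fit: if any label box (or the ring
itself) extends past half-canvas minus margin, all radii are rescaled by
`(limit − worst overshoot depth) / outer radius` (with a half-pixel pad)
and labels are re-placed at the new radii. Because shrinking an arc can
push a previously internal label outside — adding new overshoot — the fit
is a short loop (at most 6 passes; the overshoot is bounded by the longest
name, so two or three passes suffice in practice) rather than a single
pass. If fitting would drop the outer ring below four ring thicknesses the
layout raises `UnfittableCanvas` instead of producing an unreadable map.

## Rendering and export

Rendering goes through matplotlib's Agg backend with no global state:
glyph polygons (annular arrows sampled at ≤3° steps, or rectangles with
triangular heads) and text are drawn onto a white canvas sized
`canvas/100` inches at the requested dpi, so pixel dimensions scale
linearly with dpi while text keeps its physical point size. The pixel
array is encoded by Pillow as TIFF, JPEG (quality fixed at 95 for
determinism of settings), PNG, or BMP, each carrying the dpi in its native
metadata (TIFF resolution tags, JFIF density, PNG pHYs, BMP
pixels-per-meter — the latter two round to integer pixels-per-meter, hence
±1 dpi on decode). Requested resolutions outside 100–1000 dpi are
rejected. Identical layout + style + dpi yields byte-identical PNG/BMP/
TIFF output. The batch command renders at a fixed 300 dpi, mirroring the
unsupervised first-pass role it plays in pipelines; the single-map command
exposes the full range.

## Synthetic genomes

`make_canonical_mitogenome()` is a fixed 16,569 bp circular annotation in
the human mitochondrial gene order: 13 protein-coding genes, 22 tRNAs, 2
rRNAs (the 37 transcribed features nearly universal in animals) plus the
control region, which spans the origin. It reproduces the features that
stress a map drawer — the WANCY block of five tandem tRNAs, the
nad6/trnE reverse-strand block, sub-degree tRNA arrows, overlapping gene
pairs (atp8/atp6, nad4l/nad4) — with coordinates close to, but not
base-exact with, the reference record; it is gene order, strand pattern,
and counts that the maps and tests exercise.

`make_random_mitogenome(seed)` draws a genome length uniformly from
11,000–28,000 bp (the size envelope of animal mitogenomes), shuffles the
canonical 37-gene complement (or a proportionally composed set when
`n_features` is given), draws class-realistic lengths (tRNA 60–80 bp,
rRNA 800–1700 bp, PCG 200–1900 bp, uniformly), shrinks lengths
proportionally in the rare case they exceed 90% of the molecule, and
distributes the remaining slack as random intergenic gaps. Features are
non-overlapping, never origin-spanning, ~25% reverse-strand, and fully
determined by the seed (`random.Random`, stable across platforms). What
the generator does **not** emulate: real gene-order rearrangements with
conserved blocks, overlapping reading frames, duplicated control regions,
or biased strand skew — so tests passing on these genomes demonstrate the
geometry and parsing machinery, not fidelity to any particular taxon.

## Problem sizes used by the test suite and acceptance script

The suite runs on the 38-feature canonical genome, ~100 toy genomes of
1–2 kb for the coordinate-algebra painting oracle, and 1000 generator
draws for the size envelope; render-based tests use a 300×300 px logical
canvas at 100–300 dpi. `scripts/acceptance.py` reports the minimum and
maximum genome length (kb) over 1000 seeded draws at default settings,
with all seeds derived from its `--seed` argument.

## Known limitations

* One annotation per file: multi-record GenBank files are rejected.
* Label boxes are axis-aligned bounds of rotated text, so collision
  avoidance is slightly conservative; no leader lines are drawn.
* EMBL flatfiles, FASTA, and sequence-level operations (including
  reverse-complementing sequence) are out of scope.
* SVG/PDF vector export is not provided; output is raster only.
* The greedy label sweep trades optimality for determinism; extremely
  dense clusters (more labels than the shift budget can separate) may
  still overlap after the bounded number of nudges.
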