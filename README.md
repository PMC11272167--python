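# mitodraw

Circular and linear maps of mitochondrial genomes, from annotation files,
as a Python library and a batch-friendly command line tool.

Whole-mitogenome assembly and annotation (e.g. with MITOS) has become a
routine step in phylogenomic and biodiversity studies, and describing a new
assembly usually means showing its gene complement, order, and strand
orientation as a genome diagram. `mitodraw` turns an annotation — GenBank
flatfile, GFF3, GTF, 6-column BED (MITOS's tabular export), or a simple
TSV — into a publication-quality map:

* **circular maps**: two concentric rings of 5′→3′ arrows, outer ring =
  forward strand, inner ring = reverse strand;
* **linear maps**: two rows of arrows, upper = forward, lower = reverse;
* feature names drawn inside their arrow when they fit, otherwise beside
  it at 90°, with automatic, deterministic limiting of label overlap (the
  tandem tRNA arrays of animal mitogenomes — up to five genes of ~70 bp —
  are the classic stress case);
* automatic resizing of circular maps so no label runs off the image;
* raster export to TIFF, JPEG, PNG, or BMP at 100–1000 dpi with correct
  physical-resolution metadata.

Because de novo assemblies are linearized at arbitrary points and in
arbitrary orientations, the library also does the coordinate algebra needed
to standardize a set of maps: re-origin (rotate all coordinates so a chosen
position or feature starts at 0), strand flip (reflect onto the
complementary strand), and annotation editing (add / delete / rename
features, per-class and per-feature colors).

## The model in brief

An annotation is a genome length `L`, a topology, and features
`(name, class, start, length, strand)` with 0-based starts; a feature that
spans the origin of the circle is a single record with `start + length > L`.
The two standardization operations are pure modular arithmetic:

* re-origin to `k`:  `start ↦ (start − k) mod L`
* strand flip:  `start ↦ (L − start − length) mod L`, strand toggled

On the circular map a position `p` sits at angle `360·p/L` degrees
clockwise from 12 o'clock, so a feature's arrow spans `360·length/L`
degrees — spans always sum to `360·Σlength/L` regardless of wrapping.
Feature classes (protein-coding gene, tRNA, rRNA, other) are assigned by a
deterministic cascade over the source file's feature key and the gene name
(`trn*`, `rrn*`/`12S`/`16S`, the canonical 13 protein-coding genes and
their synonyms).

## Worked example

No input files needed — the package ships a canonical vertebrate
mitogenome annotation (human gene order, 16,569 bp):

```python
import mitodraw as md

ann = md.make_canonical_mitogenome()
ann = md.set_origin_to_feature(ann, "trnM")   # standardize: trnM at 0, forward
layout = md.layout_circular(ann, md.Style())

g = {x.feature.name: x for x in layout.glyphs}
print(len(layout.glyphs))                      # 38  (37 transcribed + control region)
print(g["trnM"].start_angle, g["trnM"].band)   # 0.0 Band.outer
print(round(g["cox1"].start_angle, 3), round(g["cox1"].end_angle, 3))
                                               # 32.634 66.138
md.save_image(layout, md.Style(), "map.png", dpi=300)
```

The trnM arrow starts at 0° on the outer (forward) ring because the map was
re-origined onto it; cox1 occupies 33.5° of the circle, i.e. its 1542 bp ×
360 / 16,569. The same map from the command line:

```
$ mitodraw draw --in fixture.gb --shape circular --origin-feature trnM \
      --dpi 300 --out map.png
38 features: 13 PCG, 22 tRNA, 2 rRNA, 1 other -> map.png
```

The summary line counts the 13 protein-coding genes, 22 tRNAs, and 2 rRNAs
of the canonical animal mitogenome plus the non-coding control region.
Batch mode renders many files unsupervised at a fixed 300 dpi:

```
$ mitodraw batch annotations/ --out-dir maps --image-format tiff
```

Styling (canvas size, ring radii, fonts, per-class palette, manual label
offsets) comes from a JSON file via `--style`; `--color-class tRNA=FF0000`
and `--color-feature trnM=0000FF` override colors from the command line.

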