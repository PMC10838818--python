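"""Aggregate an expert reading-study table.

Three segmentations per case (manual reference, a learned method, a
classical method) were rated for image quality, segmentation quality, and
usability for SIRT planning; one classical-method case produced no result
at all and is a first-class *missing* record.
"""

import json

from hepavess import (
    demo_rating_table,
    intra_reader_consistency,
    quality_ge_reference_rate,
    summarize,
    usability_rate,
)

records = demo_rating_table()

for method in ("reference", "dl", "wang"):
    usable, n, pct = usability_rate(records, method)
    print(f"{method:9s}: {usable:2d}/{n} usable for SIRT = {pct}%")

for method in ("dl", "wang"):
    c, n, pct = quality_ge_reference_rate(records, method)
    print(f"{method:9s}: rated >= reference in {c}/{n} cases = {pct}%")

ident, ncomp = intra_reader_consistency(records)
print(f"image quality rated identically across presentations: "
      f"{ident}/{ncomp} complete cases")

summary = summarize(records)
print("median segmentation quality:",
      {m: v["median_seg_quality"] for m, v in summary.per_method.items()})

# Note the different n per method (36 vs 35): a method that produced no
# result reduces its n instead of scoring zero.
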