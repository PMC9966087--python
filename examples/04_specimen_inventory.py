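"""Working with the packaged specimen inventory.

Loads the 98-specimen metadata table shipped with the package (52
previously studied long-nosed antlion larvae plus 46 newly described
fossils), reproduces the headline bookkeeping, and applies the
analysis-inclusion filter used before any shape analysis.
"""

from larvamorph import Epoch, filter_for_analysis, load_paper_metadata
from larvamorph.specimens import count_by

records = load_paper_metadata()
print(f"{len(records)} specimens on record")
for epoch in (Epoch.cretaceous, Epoch.eocene, Epoch.extant):
    print(f"  {epoch.value:10s}: {count_by(records, epoch=epoch):3d} "
          f"({count_by(records, epoch=epoch, provenance='this_study')} new)")

kept = filter_for_analysis(records)
dropped = [r for r in records if not r.included_in_analysis]
print(f"\n{len(kept)} specimens enter the shape analysis; "
      f"{len(dropped)} are excluded (poor preservation or concealment):")
for r in dropped:
    if r.provenance == "this_study":
        rid = r.repository_id or "(no repository id)"
        print(f"  specimen {r.specimen_no:2d} {rid}")

lengths = [r.body_length_mm for r in kept if r.body_length_mm]
print(f"\nbody lengths of analysed specimens: "
      f"{min(lengths):.1f}-{max(lengths):.1f} mm "
      f"(n={len(lengths)} with a usable length)")
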