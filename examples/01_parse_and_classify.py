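"""Parse AMPDS codes and classify HEMS-level interventions.

An AMPDS code is the category-determinant-subtype descriptor produced
during the emergency call (e.g. 09-E-01 = cardiac/respiratory arrest,
not breathing).  Suffixed codes are distinct dispatch criteria.
"""

import datetime

import hemsdispatch as hd

for text in ["09-E-01", "17-D-02P", "29-D-06 V", "9e1"]:
    code = hd.parse_code(text)
    print(f"{text!r:14} -> {code.canonical_text:9} "
          f"(category {code.category}, determinant {code.determinant})")

try:
    hd.parse_code("9E")
except hd.AmpdsParseError as err:
    print(f"'9E' is rejected: {err}")

# HLIDD = an intervention/drug/diagnostic beyond standard paramedic
# scope; helicopter conveyance counts by convention (configurable).
print()
print("thoracostomy is HLIDD:", hd.classify_hlidd({"thoracostomy"}))
print("cannulation  is HLIDD:", hd.classify_hlidd({"cannulation"}))
no_conveyance = hd.HliddRegistry.default(helicopter_conveyance=False)
print("conveyance with flag off:",
      hd.classify_hlidd({"helicopter_conveyance"}, no_conveyance))

# the day shift window is half-open [07:00, 19:00)
print()
for hh, mm in [(7, 0), (18, 59), (19, 0), (3, 30)]:
    t = datetime.time(hh, mm)
    print(f"{t} -> {hd.assign_shift(t)}")
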