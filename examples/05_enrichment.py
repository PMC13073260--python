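"""Hypergeometric over-representation analysis against a small GMT file.

Writes a three-set GMT, queries it with a feature list overlapping one
set, and prints the enrichment records.
"""

import tempfile
from pathlib import Path

from revnet import ora, read_gmt

gmt = """\
inflammation\tdemo\tTNF\tIL1B\tTLR4\tTLR2\tMYD88\tTREM1\tICAM1
cholesterol_transport\tdemo\tAPOA4\tAPOB\tAPOE\tLDLR\tPCSK9
housekeeping\tdemo\tACTB\tGAPDH\tTUBB\tRPL13\tB2M\tHPRT1
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "sets.gmt"
    path.write_text(gmt)
    collection = read_gmt(path)

query = {"TNF", "IL1B", "TLR4", "TREM1", "APOE", "ACTB"}
result = ora(query, collection)  # universe = union of all set members

print(result.to_string(index=False))
print(
    "\n-> k of K set members hit by the n-feature query in an N-feature "
    "universe; p is the upper-tail hypergeometric probability, q is BH-adjusted"
)
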