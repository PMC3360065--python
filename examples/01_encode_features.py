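"""Encode guide strands into the 497-feature space and inspect descriptors.

Run:  python examples/01_encode_features.py
"""

from sirnarank import build_default_schema, encode

schema = build_default_schema()
print(f"default schema: {len(schema)} features, version {schema.version}")

# A guide strand with a U at the 5' end and moderate GC content — the
# profile the cross-platform ranking associates with potent siRNAs.
seq = "UUCAUCUAGGAAUCGUCCA"
vec = encode(seq, schema)

for name in ("U @ PS1", "A @ PS10", "UCU in PS[1..19]", "GG in PS[1,2]",
             "GC content<0.55", "G stretch of length >=3", "paired fraction"):
    idx = schema.index_of(name)
    print(f"  [{idx:3d}] {name:28s} = {vec[idx - 1]: .4f}")

# Binary flags are 0/1; 'GG in PS[i,i+1]' entries are nearest-neighbor stack
# free energies in kcal/mol (more negative = more stable duplex end);
# 'paired fraction' is the fraction of bases paired in the strand's own
# maximum-matching fold.
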