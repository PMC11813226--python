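"""Hypergeometric over-representation of a gene list against a GMT
collection."""

from pathlib import Path
import tempfile

from crossnet import enrich, read_gmt

gmt_text = (
    "FA_OXIDATION\tfatty acid beta-oxidation\t" + "\t".join(f"fao{i}" for i in range(25)) + "\n"
    "OXPHOS\toxidative phosphorylation\t" + "\t".join(f"oxp{i}" for i in range(30)) + "\n"
    "RANDOM_SET\tunrelated genes\t" + "\t".join(f"rnd{i}" for i in range(20)) + "\n"
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.gmt"
    path.write_text(gmt_text)
    coll = read_gmt(path)

universe = {f"fao{i}" for i in range(25)} | {f"oxp{i}" for i in range(30)} \
    | {f"rnd{i}" for i in range(20)} | {f"bg{i}" for i in range(500)}
query = {f"fao{i}" for i in range(15)} | {f"bg{i}" for i in range(10)}

table = enrich(query, coll, universe)
print(table.to_string(index=False))
# k of K set members hit by the n query genes in a universe of N; the
# fatty-acid set is strongly over-represented, the others are not.
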