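"""Export the gene -> organ contribution network for chord plotting.

Writes sectors.csv (organs, genes, optional combination sectors with
their totals and organ gradient values) and links.csv (weighted gene ->
organ links), plus a self-contained circlize renderer script.  Link
weights are the contribution values, so the sum into each organ equals
that organ's total gene support.
"""

import tempfile
from pathlib import Path

import floralquant as fq

model = fq.default_model()
res = fq.derive_contributions(model)
grad = fq.gradient_values(model, res.contributions, mode="reference")
tables = fq.build_circos_tables(model, res, gradient=grad)

print(f"{len(tables.links)} gene->organ links, e.g.:")
print(tables.links.head(6).to_string(index=False))
print("organ sector totals (= incoming link weight):")
print(tables.sectors[tables.sectors.kind == "organ"].to_string(index=False))

out = Path(tempfile.mkdtemp()) / "circos"
for f in fq.write_renderer_files(tables, out):
    print("wrote", f)
print("render with: Rscript", out / "render_circos.R", out)
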