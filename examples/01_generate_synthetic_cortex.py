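"""Generate a synthetic cortex and write it in the package's file formats.

Builds a 300-sample cortical shell with 100 tissue parcels, 13 contiguous
network label sets, and 500 genes whose correlation decays over a 20 mm
length scale, then writes the sample table and expression matrix as TSV.
"""

from pathlib import Path

import sfnull as sf

cfg = sf.SyntheticConfig(
    n_samples=300, n_genes=500, gene_blocks=((500, 20.0),), seed=7
)
table = sf.generate_cortex_geometry(cfg)
expr = sf.generate_expression(table, cfg)

out = Path("scratch_example_data")
out.mkdir(exist_ok=True)
sf.write_sample_table(table, out / "samples.tsv")
sf.write_expression(expr, out / "expression.tsv")

n_rs = int(table.rsfmri_mask.sum())
print(f"samples: {table.n_samples}  (rsfMRI-network samples: {n_rs})")
print(f"tissue parcels: {len(set(table.tissue_labels))}")
print(f"networks: {len(table.network_ids)}")
print(f"genes: {expr.n_genes}")
print(f"wrote {out / 'samples.tsv'} and {out / 'expression.tsv'}")
# The network samples play the role of the 501 rsfMRI samples of a real
# cortical atlas; everything downstream runs from these two files.
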