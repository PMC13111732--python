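"""Bin-to-exon aggregation of exon-usage results.

Exon-usage callers report counts and log2 fold changes per non-overlapping
bin. For visualisation these are summarised per exon: the lfc as a
bin-length-weighted mean, the counts as a plain sum over bins.
"""

import pandas as pd

from aluedit import aggregate_exon_table

bins = pd.DataFrame({
    "gene_id": ["ADAR1"] * 4,
    "exon_id": ["exon1", "exon1", "exon2", "exon2"],
    "bin_id": ["E001", "E002", "E003", "E004"],
    "bin_length": [100, 300, 150, 150],
    "lfc": [1.0, 2.0, -0.4, -0.8],
    "ctrl": [10.0, 30.0, 8.0, 12.0],
    "kd": [12.0, 25.0, 3.0, 5.0],
})

exons = aggregate_exon_table(bins)
print(exons.round(3).to_string(index=False))

# exon1 lfc = (1.0*100 + 2.0*300) / 400 = 1.75 (length-weighted mean);
# counts are summed per exon, e.g. ctrl exon1 = 10 + 30 = 40.
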