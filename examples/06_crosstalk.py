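"""Filter differential ligand-receptor interactions.

Given DE results for a source cell type's ligands (an input, e.g. from a
pseudobulk DESeq2 contrast) and a ligand-receptor pair table, keep partners
whose receptor is expressed in at least 10% of a receiver type's cells,
with patient-balanced expression fractions.
"""

import numpy as np
import pandas as pd

from atlaskit import crosstalk as ct
from atlaskit.data import InteractionTable
from atlaskit import simulate

cfg = simulate.default_atlas_config(
    n_genes=200, n_cell_types=3, n_datasets=1, patients_per_dataset=6,
    markers_per_type=20, marker_log2_effect=3.0,
    cells_per_patient_per_type=(30, 60), library_size_mean=500, seed=6,
)
dataset, truth = simulate.generate_atlas(cfg)

# pretend the first two markers of type0 came out differentially expressed
ligands = truth.markers["type0"][:2]
all_fracs = ct.expression_fractions(dataset, dataset.genes, "type1")
receptors = [truth.markers["type1"][0],   # abundant in type1
             all_fracs.idxmin()]          # sparsest gene in type1
de = ct.DEResult(pd.DataFrame({
    "cell_type": "type0", "gene": ligands,
    "log2fc": [2.1, -1.4], "adjusted_p": [0.002, 0.03],
}))
pairs = InteractionTable(pd.DataFrame({
    "ligand": [ligands[0], ligands[0], ligands[1]],
    "receptor": [receptors[0], receptors[1], receptors[0]],
    "pair_id": ["i1", "i2", "i3"],
}))

for gene in receptors:
    frac = ct.expression_fraction(dataset, gene, "type1")
    print(f"fraction of type1 cells expressing {gene}: {frac:.3f}")

result = ct.differential_crosstalk(de, pairs, dataset,
                                   receiver_types=["type1", "type2"])
print(f"rows passing the 10% receiver filter: {len(result)}")
print(result.table[["ligand", "receiver_cell_type", "receptor", "direction",
                    "receiver_expr_fraction"]].round(3).to_string(index=False))
# each row is a candidate interaction whose source-side ligand changed and
# whose receiver population plausibly listens (receptor in >= 10% of cells).
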