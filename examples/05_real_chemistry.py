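"""The real-chemistry front end (requires rdkit): SMILES in, conformer
ensembles, 3D fingerprints, and the same downstream feature machinery.

The six molecules below form two deliberately contrasting "targets": one
of arylpropionic acids, one of alkyl amines, so even this toy example
shows within-class similarity exceeding between-class similarity.
"""

import numpy as np

import kld_dti as kd
from kld_dti import chem, fingerprints

ligands = [
    chem.LigandRecord("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "acids"),
    chem.LigandRecord("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O", "acids"),
    chem.LigandRecord("ketoprofen", "CC(C(=O)O)c1cccc(c1)C(=O)c1ccccc1", "acids"),
    chem.LigandRecord("hexylamine", "CCCCCCN", "amines"),
    chem.LigandRecord("heptylamine", "CCCCCCCN", "amines"),
    chem.LigandRecord("octylamine", "CCCCCCCCN", "amines"),
]

sets = [chem.generate_conformers(rec, n_conf=8, seed=7) for rec in ligands]
print("conformers per ligand:",
      {cs.ligand_id: cs.n_conformers for cs in sets})

labels = {rec.ligand_id: rec.target_label for rec in ligands}
collection = fingerprints.fingerprint_conformer_sets(sets, labels)
print(f"{len(collection)} 3D fingerprints of {collection.n_bits} bits")

models = kd.fit_target_models(collection, cap=15_000, seed=0)
table = kd.build_feature_table(collection, models)
print("\nKLD features (rows: query ligands, columns: targets):")
print(table.round(3))
# Each ligand's smallest divergence is against its own class's similarity
# density — the chemocentric signal the classifier consumes at scale.
own_min = [row[f"KLD_{row['label']}"] == row[["KLD_acids", "KLD_amines"]].min()
           for _, row in table.iterrows()]
print(f"\nown-class KLD is the row minimum for {int(np.sum(own_min))}/6 ligands")
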