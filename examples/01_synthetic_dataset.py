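"""Generate a synthetic multi-class fingerprint dataset and check that the
class structure is real: ligands of one target resemble each other more
than they resemble ligands of another target."""

import numpy as np

import kld_dti as kd

specs = kd.default_specs(n_classes=3, n_ligands=50, conformers_per_ligand=4)
collection = kd.generate_dataset(specs, seed=0)
print(f"{len(collection)} fingerprints, {collection.n_bits} bits, "
      f"classes: {collection.class_ids}")

rng = np.random.default_rng(0)
c1 = collection.for_class("T01").packed
c2 = collection.for_class("T02").packed
intra = [kd.tanimoto(c1[i], c1[j])
         for i, j in rng.integers(0, len(c1), (2000, 2)) if i != j]
inter = [kd.tanimoto(c1[i], c2[j])
         for i, j in zip(rng.integers(0, len(c1), 2000),
                         rng.integers(0, len(c2), 2000))]
print(f"mean intra-class Tanimoto: {np.mean(intra):.3f}")
print(f"mean inter-class Tanimoto: {np.mean(inter):.3f}")
# The gap between the two means is what every later stage feeds on: the
# within-target similarity distribution sits well above the between-target
# one, exactly the situation for real target classes.
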