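"""Labeled fingerprint collections and their plain-text interchange format.

A :class:`FingerprintCollection` is the common currency between the
synthetic and real-chemistry paths: a packed bit matrix plus per-row
metadata (target class, ligand, conformer index).  The on-disk dialect is
one record per line::

    class_id <TAB> ligand_id <TAB> conformer_index <TAB> hex-encoded bits

so real and synthetic fingerprints are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._bits import from_hex, to_hex
from .errors import InputError

META_COLUMNS = ["class_id", "ligand_id", "conformer_index"]


@dataclass
class FingerprintCollection:
    """Packed fingerprints with aligned per-row metadata.

    Attributes
    ----------
    packed : uint8 array, shape (n, n_bits // 8)
        Bit-packed fingerprints, one row per conformer (3D mode) or per
        ligand (2D mode).
    n_bits : int
        Unpacked fingerprint length; constant across the collection.
    meta : DataFrame with columns class_id, ligand_id, conformer_index
    """

    packed: np.ndarray
    n_bits: int
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.packed.ndim != 2 or self.packed.shape[1] * 8 != self.n_bits:
            raise InputError(
                f"packed shape {self.packed.shape} inconsistent with "
                f"n_bits={self.n_bits}"
            )
        if len(self.meta) != self.packed.shape[0]:
            raise InputError("metadata rows do not match fingerprint rows")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise InputError(f"metadata missing columns: {missing}")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.packed.shape[0]

    @property
    def class_ids(self) -> list[str]:
        """Distinct target labels, sorted for deterministic ordering."""
        return sorted(self.meta["class_id"].unique())

    def subset(self, indices: np.ndarray) -> "FingerprintCollection":
        indices = np.asarray(indices)
        return FingerprintCollection(
            self.packed[indices], self.n_bits, self.meta.iloc[indices]
        )

    def for_class(self, class_id: str) -> "FingerprintCollection":
        mask = (self.meta["class_id"] == class_id).to_numpy()
        if not mask.any():
            raise InputError(f"no fingerprints for class {class_id!r}")
        return self.subset(np.flatnonzero(mask))

    def for_ligand(self, ligand_id: str) -> "FingerprintCollection":
        mask = (self.meta["ligand_id"] == ligand_id).to_numpy()
        if not mask.any():
            raise InputError(f"no fingerprints for ligand {ligand_id!r}")
        return self.subset(np.flatnonzero(mask))

    def iter_ligands(self):
        """Yield (ligand_id, class_id, packed rows) per ligand, in first-seen order."""
        for ligand_id, grp in self.meta.groupby("ligand_id", sort=False):
            yield ligand_id, grp["class_id"].iloc[0], self.packed[grp.index.to_numpy()]

    @staticmethod
    def concat(parts: list["FingerprintCollection"]) -> "FingerprintCollection":
        if not parts:
            raise InputError("cannot concatenate an empty list of collections")
        n_bits = {p.n_bits for p in parts}
        if len(n_bits) != 1:
            raise InputError(f"mixed fingerprint lengths: {sorted(n_bits)}")
        return FingerprintCollection(
            np.vstack([p.packed for p in parts]),
            n_bits.pop(),
            pd.concat([p.meta for p in parts], ignore_index=True),
        )

    # ------------------------------------------------------------------ I/O

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                row = self.meta.iloc[i]
                fh.write(
                    f"{row.class_id}\t{row.ligand_id}\t"
                    f"{row.conformer_index}\t{to_hex(self.packed[i])}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FingerprintCollection":
        classes, ligands, conf_idx, rows = [], [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise InputError(
                        f"{path}: line {lineno}: expected 4 tab-separated "
                        f"fields, got {len(parts)}"
                    )
                classes.append(parts[0])
                ligands.append(parts[1])
                conf_idx.append(int(parts[2]))
                rows.append(from_hex(parts[3]))
        if not rows:
            raise InputError(f"{path}: no fingerprint records")
        packed = np.vstack(rows)
        meta = pd.DataFrame(
            {"class_id": classes, "ligand_id": ligands, "conformer_index": conf_idx}
        )
        return cls(packed, packed.shape[1] * 8, meta)
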