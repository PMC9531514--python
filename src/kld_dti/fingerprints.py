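"""Fixed-length bit-vector fingerprints in 3D and 2D modes.

3D mode encodes one conformer per fingerprint with an extended
three-dimensional fingerprint: starting from per-atom graph invariants,
atom identifiers are iteratively re-hashed together with the identifiers
and quantized distances of all neighbors inside a growing radial shell,
and every identifier at every iteration is folded into a fixed-length
(default 1024) bit vector.  Because the shells are defined by 3D
distance, two conformers of one ligand that differ in torsions set
different bits — the property the whole similarity pipeline depends on.
The 3D backend is pluggable: any callable mapping (mol, conf_id, n_bits)
to a bit array can stand in via ``backend=``, so an external E3FP
implementation can be dropped in without touching downstream code.

2D mode is a standard Morgan (circular, radius 2) fingerprint via RDKit:
one fingerprint per *ligand*, geometry ignored, so downstream counts
shrink from conformers to ligands.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._bits import pack_bits
from .errors import ConfigurationError, InputError
from .fpset import FingerprintCollection

DEFAULT_N_BITS = 1024
# shell radius grows by this increment (angstrom) per iteration; 1.718 is
# the growth rate commonly used for radial 3D fingerprints
DEFAULT_SHELL_RADIUS = 1.718
DEFAULT_N_SHELLS = 5
_DISTANCE_RESOLUTION = 0.4  # angstrom; distance quantization inside shells


@dataclass
class Fingerprint:
    """One fixed-length bit vector with its provenance."""

    bits: np.ndarray = field(repr=False)  # packed uint8
    n_bits: int
    source_id: tuple[str, int]
    mode: str  # "3d" | "2d"


def _hash64(*parts) -> int:
    digest = hashlib.blake2b(repr(parts).encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def _atom_invariants(mol) -> list[tuple]:
    return [
        (
            a.GetAtomicNum(),
            a.GetDegree(),
            a.GetTotalNumHs(),
            a.GetFormalCharge(),
            int(a.GetIsAromatic()),
            int(a.IsInRing()),
        )
        for a in mol.GetAtoms()
    ]


def radial_shell_bits(
    coords: np.ndarray,
    invariants: list[tuple],
    n_bits: int = DEFAULT_N_BITS,
    n_shells: int = DEFAULT_N_SHELLS,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
) -> np.ndarray:
    """Core 3D hashing: iterative radial-shell neighbor identifiers folded
    to ``n_bits``.  A pure function of coordinates and invariants."""
    n_atoms = coords.shape[0]
    ids = [_hash64("atom", inv) for inv in invariants]
    bits = np.zeros(n_bits, dtype=bool)
    bits[[i % n_bits for i in ids]] = True
    if n_atoms > 1:
        dist = squareform(pdist(coords))
        for level in range(1, n_shells + 1):
            radius = level * shell_radius
            new_ids = []
            for i in range(n_atoms):
                members = sorted(
                    (
                        int(dist[i, j] / _DISTANCE_RESOLUTION),
                        ids[j],
                    )
                    for j in range(n_atoms)
                    if j != i and dist[i, j] <= radius
                )
                new_ids.append(_hash64("shell", level, ids[i], tuple(members)))
            ids = new_ids
            bits[[i % n_bits for i in ids]] = True
    return bits


def fingerprint_3d(
    mol,
    conf_id: int = -1,
    n_bits: int = DEFAULT_N_BITS,
    n_shells: int = DEFAULT_N_SHELLS,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
    source_id: tuple[str, int] | None = None,
    backend: Callable | None = None,
) -> Fingerprint:
    """Fingerprint one conformer of an RDKit mol.

    Deterministic for identical coordinates; sensitive to torsional
    changes through the shell distances.  Raises if the mol carries no 3D
    conformer (generate conformers first).
    """
    if n_bits % 8:
        raise ConfigurationError("n_bits must be a multiple of 8")
    if mol.GetNumConformers() == 0:
        raise InputError(
            "molecule has no 3D conformer; run chem.generate_conformers first"
        )
    if backend is not None:
        bits = np.asarray(backend(mol, conf_id, n_bits), dtype=bool)
        if bits.size != n_bits:
            raise ConfigurationError("backend returned wrong bit length")
    else:
        conf = mol.GetConformer(conf_id)
        coords = np.asarray(conf.GetPositions(), dtype=np.float64)
        bits = radial_shell_bits(
            coords,
            _atom_invariants(mol),
            n_bits=n_bits,
            n_shells=n_shells,
            shell_radius=shell_radius,
        )
    sid = source_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "", conf_id)
    return Fingerprint(bits=pack_bits(bits)[0], n_bits=n_bits, source_id=sid,
                       mode="3d")


def fingerprint_2d(
    mol,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = 2,
    source_id: tuple[str, int] | None = None,
) -> Fingerprint:
    """Morgan (circular) fingerprint of one molecule; geometry ignored."""
    from rdkit.Chem import rdFingerprintGenerator

    if mol is None:
        raise InputError("cannot fingerprint an unparsable molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    bits = np.zeros(n_bits, dtype=bool)
    bits[list(fp.GetOnBits())] = True
    sid = source_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "", 0)
    return Fingerprint(bits=pack_bits(bits)[0], n_bits=n_bits, source_id=sid,
                       mode="2d")


def fingerprint_conformer_sets(
    conformer_sets,
    class_labels: dict[str, str],
    n_bits: int = DEFAULT_N_BITS,
    backend: Callable | None = None,
) -> FingerprintCollection:
    """3D-fingerprint every conformer of every ligand into a collection.

    ``class_labels`` maps ligand_id -> target label.
    """
    rows, meta = [], []
    for cs in conformer_sets:
        label = class_labels[cs.ligand_id]
        for i, mol in enumerate(cs.mols):
            fp = fingerprint_3d(
                mol, conf_id=-1, n_bits=n_bits,
                source_id=(cs.ligand_id, i), backend=backend,
            )
            rows.append(fp.bits)
            meta.append((label, cs.ligand_id, i))
    if not rows:
        raise InputError("no conformers to fingerprint")
    return FingerprintCollection(
        np.vstack(rows),
        n_bits,
        pd.DataFrame(meta, columns=["class_id", "ligand_id", "conformer_index"]),
    )


def fingerprint_ligands_2d(
    records,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = 2,
) -> FingerprintCollection:
    """2D-fingerprint ligand records (one row per ligand, conformer_index 0)."""
    from rdkit import Chem

    rows, meta = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise InputError(f"unparsable SMILES for {rec.ligand_id!r}")
        fp = fingerprint_2d(mol, n_bits=n_bits, radius=radius,
                            source_id=(rec.ligand_id, 0))
        rows.append(fp.bits)
        meta.append((rec.target_label, rec.ligand_id, 0))
    if not rows:
        raise InputError("no ligands to fingerprint")
    return FingerprintCollection(
        np.vstack(rows),
        n_bits,
        pd.DataFrame(meta, columns=["class_id", "ligand_id", "conformer_index"]),
    )
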