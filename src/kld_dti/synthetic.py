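"""Synthetic multi-class fingerprint datasets.

Real target classes have heterogeneous intra-class similarity
distributions — skewed, asymmetric, fat-tailed — because ligand series
within a target share scaffolds to very different degrees.  This module
emulates that structure with a bit-flip generative model: each class owns
a set of "core" bits set with high probability, each ligand draws a
prototype fingerprint from the class distribution, and each conformer
jitters the prototype to model conformational spread.  The model produces
nothing but bit vectors, which is all the downstream pipeline consumes, so
every stage is testable without a chemistry toolkit.

Direct density/divergence fixtures that skip fingerprints entirely come
from :func:`skewed_similarity_sample`, a Beta family on [0, 1] covering the
symmetric, skewed and asymmetric regimes seen in real similarity
distributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._bits import pack_bits
from .errors import ConfigurationError
from .fpset import FingerprintCollection


@dataclass
class SyntheticClassSpec:
    """Generative parameters for one synthetic target class.

    Parameters
    ----------
    class_id : str
        Target label; unique within a dataset.
    n_ligands, conformers_per_ligand : int
        Population sizes (>= 1 each).
    n_bits : int
        Fingerprint length (default 1024).
    core_bits : sequence of int
        Bit indices shared within the class; all in [0, n_bits).
    p_core : float
        Probability a core bit is set in a ligand prototype.
    p_noise : float
        Probability a non-core bit is set; must be < p_core so the class
        is coherent (intra-class similarity exceeds inter-class).
    intra_ligand_jitter : float
        Per-bit flip probability applied independently to each conformer
        of a ligand; models conformational spread.
    """

    class_id: str
    n_ligands: int
    conformers_per_ligand: int
    core_bits: tuple[int, ...] = ()
    n_bits: int = 1024
    p_core: float = 0.9
    p_noise: float = 0.02
    intra_ligand_jitter: float = 0.02

    def __post_init__(self) -> None:
        self.core_bits = tuple(sorted(set(int(b) for b in self.core_bits)))
        if self.n_ligands < 1 or self.conformers_per_ligand < 1:
            raise ConfigurationError(
                "n_ligands and conformers_per_ligand must be >= 1"
            )
        if self.n_bits < 8 or self.n_bits % 8:
            raise ConfigurationError("n_bits must be a positive multiple of 8")
        if self.core_bits and not (
            0 <= self.core_bits[0] and self.core_bits[-1] < self.n_bits
        ):
            raise ConfigurationError("core_bits must lie in [0, n_bits)")
        for name in ("p_core", "p_noise", "intra_ligand_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.p_core <= self.p_noise:
            raise ConfigurationError(
                "p_core must exceed p_noise for class coherence"
            )


def _class_seed(global_seed: int, class_id: str) -> np.random.SeedSequence:
    """Deterministic per-class child seed: SeedSequence keyed on the global
    seed and a CRC-32 of the class label, so editing one class spec never
    perturbs another class's draws."""
    return np.random.SeedSequence([int(global_seed), zlib.crc32(class_id.encode())])


def generate_class(spec: SyntheticClassSpec, seed: int) -> FingerprintCollection:
    """Generate one class's fingerprints under the bit-flip model."""
    rng = np.random.default_rng(_class_seed(seed, spec.class_id))
    core = np.zeros(spec.n_bits, dtype=bool)
    core[list(spec.core_bits)] = True
    p_bit = np.where(core, spec.p_core, spec.p_noise)

    blocks, ligand_ids, conf_idx = [], [], []
    for lig in range(spec.n_ligands):
        prototype = rng.random(spec.n_bits) < p_bit
        flips = (
            rng.random((spec.conformers_per_ligand, spec.n_bits))
            < spec.intra_ligand_jitter
        )
        blocks.append(prototype[None, :] ^ flips)
        lid = f"{spec.class_id}_L{lig:04d}"
        ligand_ids.extend([lid] * spec.conformers_per_ligand)
        conf_idx.extend(range(spec.conformers_per_ligand))

    packed = pack_bits(np.vstack(blocks))
    meta = pd.DataFrame(
        {
            "class_id": spec.class_id,
            "ligand_id": ligand_ids,
            "conformer_index": conf_idx,
        }
    )
    return FingerprintCollection(packed, spec.n_bits, meta)


def generate_dataset(
    specs: list[SyntheticClassSpec], seed: int
) -> FingerprintCollection:
    """Generate a labeled multi-class fingerprint dataset.

    Fully reproducible for a fixed seed; classes are generated from
    independent child seeds derived from ``seed`` and the class label.
    """
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    ids = [s.class_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate class_ids in specs: {ids}")
    n_bits = {s.n_bits for s in specs}
    if len(n_bits) != 1:
        raise ConfigurationError("all classes must share one fingerprint length")
    return FingerprintCollection.concat(
        [generate_class(s, seed) for s in specs]
    )


def default_specs(
    n_classes: int = 5,
    n_ligands: int = 200,
    conformers_per_ligand: int = 4,
    n_bits: int = 1024,
    core_size: int = 48,
    p_core: float = 0.9,
    p_noise: float = 0.02,
    intra_ligand_jitter: float = 0.02,
    core_overlap: int = 0,
) -> list[SyntheticClassSpec]:
    """Well-separated study conditions: K classes with disjoint core-bit
    blocks (optionally overlapping by ``core_overlap`` bits with the next
    class, to study degradation)."""
    if n_classes * core_size > n_bits:
        raise ConfigurationError("core blocks exceed fingerprint length")
    specs = []
    for k in range(n_classes):
        start = k * (core_size - core_overlap)
        core = tuple(range(start, start + core_size))
        if core[-1] >= n_bits:
            raise ConfigurationError("overlapping core blocks exceed n_bits")
        specs.append(
            SyntheticClassSpec(
                class_id=f"T{k + 1:02d}",
                n_ligands=n_ligands,
                conformers_per_ligand=conformers_per_ligand,
                n_bits=n_bits,
                core_bits=core,
                p_core=p_core,
                p_noise=p_noise,
                intra_ligand_jitter=intra_ligand_jitter,
            )
        )
    return specs


def skewed_similarity_sample(
    shape_params: tuple[float, float], n: int, seed: int
) -> np.ndarray:
    """Draw n similarity values in [0, 1] from a Beta(a, b) family.

    The Beta family is bounded on the similarity domain and covers the
    symmetric (a = b), right-skewed (a < b) and left-skewed (a > b)
    regimes of real similarity-score distributions.
    """
    a, b = shape_params
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if a <= 0 or b <= 0:
        raise ConfigurationError("Beta shape parameters must be positive")
    rng = np.random.default_rng(seed)
    return rng.beta(a, b, size=n)
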