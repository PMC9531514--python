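"""Jaccard-Tanimoto similarities, Q-Q matrices and Q-L vectors.

A target class is characterized by the distribution of all pairwise
similarities among its ligands' conformers (the Q-Q matrix); a query's
relationship to a class is the distribution of its conformers' similarities
against the class (the Q-L vector).  Classes larger than a cap (default
15,000 conformers) are randomly resampled once, which bounds dimensionality
and softens data imbalance; the resampling is seed-stable in distribution.

Only the pooled score multisets are stored, never the square matrices —
downstream stages consume nothing but the distributions, and the flat form
keeps a capped class at O(n^2) transient work but O(n^2) float32-free
streaming rather than a persistent dense matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._bits import tanimoto_condensed, tanimoto_cross, tanimoto_packed
from .errors import ConfigurationError, InputError
from .fpset import FingerprintCollection

DEFAULT_CAP = 15_000


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard-Tanimoto coefficient |a AND b| / |a OR b| of two packed
    fingerprints; the empty-vs-empty case (0/0) is defined as 0."""
    return tanimoto_packed(np.asarray(a).ravel(), np.asarray(b).ravel())


def resample_cap(
    fps: FingerprintCollection, cap: int = DEFAULT_CAP, seed: int = 0
) -> FingerprintCollection:
    """Uniform random subset without replacement when the collection
    exceeds ``cap``; the identity otherwise.  Deterministic per seed."""
    if cap < 1:
        raise ConfigurationError("cap must be >= 1")
    if len(fps) <= cap:
        return fps
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(fps), size=cap, replace=False))
    return fps.subset(keep)


@dataclass
class QQMatrix:
    """Pooled within-class pairwise similarity scores.

    ``values`` holds the upper-triangle scores a_{i,j} (i < j) of the
    retained conformers' pairwise similarity matrix; self-pairs are
    excluded because a conformer's unit self-similarity carries no
    inter-ligand information and only biases the density's right tail.
    """

    target_id: str
    values: np.ndarray = field(repr=False)
    n_conformers_retained: int
    sampling_seed: int
    retained: FingerprintCollection | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = self.n_conformers_retained
        if self.values.size != n * (n - 1) // 2:
            raise InputError(
                f"Q-Q value count {self.values.size} != C({n},2)"
            )


@dataclass
class QLVector:
    """Pooled query-conformer x class-conformer similarity scores."""

    query_id: str
    target_id: str
    values: np.ndarray = field(repr=False)


def build_qq_matrix(
    class_fps: FingerprintCollection,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
) -> QQMatrix:
    """Pool all pairwise similarities within one target class.

    The class is capped by :func:`resample_cap` first; the retained subset
    is kept on the result so Q-L vectors are computed against exactly the
    conformers that defined the class density.
    """
    retained = resample_cap(class_fps, cap=cap, seed=seed)
    n = len(retained)
    if n < 2:
        raise InputError(
            f"class {class_fps.meta['class_id'].iloc[0]!r} too small for "
            f"density: {n} fingerprint(s) after capping"
        )
    values = tanimoto_condensed(retained.packed)
    target_id = str(class_fps.meta["class_id"].iloc[0])
    return QQMatrix(
        target_id=target_id,
        values=values,
        n_conformers_retained=n,
        sampling_seed=seed,
        retained=retained,
    )


def build_ql_vector(
    query_fps: FingerprintCollection | np.ndarray,
    qq_class: QQMatrix,
    exclude_self: bool = True,
    query_id: str = "",
) -> QLVector:
    """Pool all query-conformer x class-conformer similarities.

    With ``exclude_self`` on and the query ligand belonging to the class,
    the query's own conformers are removed from the class side first —
    otherwise a training ligand scores unit similarities against itself
    and leaks its label through the feature.
    """
    if qq_class.retained is None:
        raise InputError("QQMatrix lacks its retained conformer set")
    if isinstance(query_fps, FingerprintCollection):
        if len(query_fps) < 1:
            raise InputError("query has no fingerprints")
        query_id = query_id or str(query_fps.meta["ligand_id"].iloc[0])
        query_packed = query_fps.packed
    else:
        query_packed = np.atleast_2d(query_fps)

    class_side = qq_class.retained
    if exclude_self and query_id:
        mask = (class_side.meta["ligand_id"] != query_id).to_numpy()
        if mask.sum() == 0:
            raise InputError(
                f"class {qq_class.target_id!r} empty after excluding "
                f"query {query_id!r}"
            )
        class_packed = class_side.packed[mask]
    else:
        class_packed = class_side.packed

    scores = tanimoto_cross(query_packed, class_packed).ravel()
    return QLVector(query_id=query_id, target_id=qq_class.target_id, values=scores)


def write_scores(path, values: np.ndarray, header: dict) -> None:
    """One float per line preceded by a single JSON header line."""
    import json

    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        np.savetxt(fh, values, fmt="%.10g")


def read_scores(path) -> tuple[np.ndarray, dict]:
    import json

    with open(path) as fh:
        first = fh.readline()
        header = json.loads(first[1:]) if first.startswith("#") else {}
        values = np.loadtxt(fh, ndmin=1)
    return values, header
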