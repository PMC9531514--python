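"""Kernel density estimation of similarity-score distributions.

Every Q-Q and Q-L score multiset is summarized as a Gaussian-kernel KDE
evaluated on one fixed grid: the 100 midpoints of equal subdivisions of
[0, 1] (x_k = (k - 0.5)/100, dx = 0.01).  Midpoints avoid evaluating at
the closed endpoints, where similarity scores pile up.  Bandwidth follows
Scott's rule by default (Silverman's and a fixed bandwidth are available);
the two automatic rules give near-identical profiles on similarity data,
so the choice is not load-bearing.

A plain Gaussian kernel leaks some mass outside [0, 1] near the
boundaries; with ``renormalize`` on (the default) the grid values are
rescaled so that sum(pdf) * dx = 1, which makes profiles comparable
across sample sizes.  Zero-variance input (e.g. a class whose scores are
all 1.0) defeats the automatic bandwidth rules, so it falls back to a
fixed minimal bandwidth of 0.5 * dx instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, GridMismatchError, InputError

N_BINS = 100
DX = 1.0 / N_BINS
GRID = (np.arange(N_BINS) + 0.5) * DX
GRID.setflags(write=False)

_DEGENERATE_BANDWIDTH = 0.5 * DX


@dataclass
class DensityProfile:
    """A 100-point density estimate on [0, 1] with bandwidth metadata."""

    grid: np.ndarray = field(repr=False)
    pdf: np.ndarray = field(repr=False)
    bandwidth: float
    bandwidth_rule: str
    n_samples: int
    renormalized: bool

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.pdf = np.asarray(self.pdf, dtype=np.float64)
        if self.pdf.shape != self.grid.shape:
            raise InputError("pdf and grid lengths differ")
        if np.any(self.pdf < 0) or not np.all(np.isfinite(self.pdf)):
            raise InputError("pdf values must be finite and nonnegative")

    @property
    def dx(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def mass(self) -> float:
        """Grid integral sum(pdf) * dx; 1 (to 1e-9) when renormalized."""
        return float(self.pdf.sum() * self.dx)


def _manual_gaussian_kde(
    values: np.ndarray, bandwidth: float, grid: np.ndarray
) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (
        values.size * bandwidth * np.sqrt(2.0 * np.pi)
    )


def estimate_density(
    values: np.ndarray,
    bandwidth_rule: str = "scott",
    bandwidth: float | None = None,
    renormalize: bool = True,
) -> DensityProfile:
    """Gaussian-kernel KDE of similarity scores on the fixed 100-point grid.

    Parameters
    ----------
    values : array of similarities in [0, 1], length >= 2
    bandwidth_rule : {"scott", "silverman", "fixed"}
        Automatic rules delegate to :class:`scipy.stats.gaussian_kde`;
        "fixed" uses the absolute ``bandwidth`` given.
    bandwidth : float, optional
        Required iff ``bandwidth_rule == "fixed"``.
    renormalize : bool
        Rescale so the grid integral is exactly 1 (default on).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise InputError(f"need >= 2 values for a density, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise InputError("similarity values must be finite")
    if values.min() < 0.0 or values.max() > 1.0:
        raise InputError("similarity values must lie in [0, 1]")

    if bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ConfigurationError("fixed rule requires a positive bandwidth")
        h = float(bandwidth)
        pdf = _manual_gaussian_kde(values, h, GRID)
    elif bandwidth_rule in ("scott", "silverman"):
        if np.ptp(values) == 0.0:
            # zero sample variance: automatic rules return bandwidth 0
            h = _DEGENERATE_BANDWIDTH
            pdf = _manual_gaussian_kde(values, h, GRID)
        else:
            kde = stats.gaussian_kde(values, bw_method=bandwidth_rule)
            h = float(np.sqrt(kde.covariance[0, 0]))
            pdf = kde(GRID)
    else:
        raise ConfigurationError(
            f"unknown bandwidth_rule {bandwidth_rule!r}; "
            "expected scott, silverman or fixed"
        )

    pdf = np.clip(pdf, 0.0, None)
    if renormalize:
        total = pdf.sum() * DX
        if total <= 0:
            raise InputError("estimated density has zero mass on the grid")
        pdf = pdf / total

    return DensityProfile(
        grid=GRID.copy(),
        pdf=pdf,
        bandwidth=h,
        bandwidth_rule=bandwidth_rule,
        n_samples=int(values.size),
        renormalized=renormalize,
    )


def density_distance(p: DensityProfile, q: DensityProfile) -> float:
    """L1 distance sum |p - q| * dx between two profiles on one grid."""
    if p.grid.shape != q.grid.shape or not np.allclose(p.grid, q.grid):
        raise GridMismatchError("density profiles use different grids")
    return float(np.abs(p.pdf - q.pdf).sum() * p.dx)


def write_profile(path, profile: DensityProfile, extra: dict | None = None) -> None:
    """Serialize as a JSON header line plus one pdf value per line."""
    import json

    header = {
        "bandwidth": profile.bandwidth,
        "bandwidth_rule": profile.bandwidth_rule,
        "n_samples": profile.n_samples,
        "renormalized": profile.renormalized,
        "n_bins": len(profile.pdf),
    }
    if extra:
        header.update(extra)
    with open(path, "w") as fh:
        fh.write("#" + json.dumps(header) + "\n")
        np.savetxt(fh, profile.pdf, fmt="%.12g")


def read_profile(path) -> DensityProfile:
    import json

    with open(path) as fh:
        header = json.loads(fh.readline()[1:])
        pdf = np.loadtxt(fh, ndmin=1)
    if pdf.size != header.get("n_bins", N_BINS):
        raise InputError(f"{path}: expected {header.get('n_bins')} pdf values")
    return DensityProfile(
        grid=GRID.copy(),
        pdf=pdf,
        bandwidth=float(header["bandwidth"]),
        bandwidth_rule=header["bandwidth_rule"],
        n_samples=int(header["n_samples"]),
        renormalized=bool(header["renormalized"]),
    )
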