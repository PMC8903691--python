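"""Virtual-sensor reconstruction: LCMV beamforming on a volumetric grid.

Sensor data are projected into source space with a unit-gain, scalar,
linearly constrained minimum-variance (LCMV) spatial filter with diagonal
loading.  The whole grid is scanned (one virtual sensor per voxel) and voxels
closer than 10 mm are merged, keeping the higher-power voxel, matching the
convention that two sources closer than the spatial resolution of the method
are one source.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocessing import BandDefinition

__all__ = [
    "SourceGrid",
    "VirtualSensorSet",
    "lcmv_weights",
    "lcmv_weight_matrix",
    "scan_grid",
    "merge_close_voxels",
]


@dataclass(frozen=True)
class SourceGrid:
    """Volumetric source grid: voxel positions (meters) and region labels."""

    positions: np.ndarray  # voxels x 3
    region_labels: tuple[str, ...]
    spacing: float = 0.006

    def __post_init__(self) -> None:
        positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if positions.shape[1] != 3:
            raise ValueError("positions must be voxels x 3")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(self.region_labels) != positions.shape[0]:
            raise ValueError("one region label per voxel required")
        n = positions.shape[0]
        if n > 1:
            d = np.linalg.norm(
                positions[:, None, :] - positions[None, :, :], axis=-1
            )
            if np.any(d[np.triu_indices(n, k=1)] < 1e-12):
                raise ValueError("grid positions must be pairwise distinct")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]


@dataclass
class VirtualSensorSet:
    """Band-limited source-space time series on a (possibly merged) grid."""

    signals: np.ndarray  # sources x samples
    grid: SourceGrid
    band: BandDefinition | None = None
    subject_id: str = ""
    power: np.ndarray | None = None  # per-voxel output power
    merged_into: dict[int, int] | None = None  # absorbed voxel -> keeper

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != self.grid.n_voxels:
            raise ValueError("one signal row per grid voxel required")
        if self.power is None:
            self.power = self.signals.var(axis=1)

    @property
    def n_sources(self) -> int:
        return self.signals.shape[0]


def lcmv_weights(
    cov: np.ndarray, gain_column: np.ndarray, reg: float = 0.05
) -> np.ndarray:
    """Unit-gain LCMV weight vector for one source.

    w = (C + lam I)^-1 g / (g^T (C + lam I)^-1 g) with diagonal loading
    lam = reg x mean(diag(C)); w^T g = 1 by construction, so a source with
    forward field g passes with unit gain while output variance is minimized.
    """
    cov = np.asarray(cov, dtype=float)
    g = np.asarray(gain_column, dtype=float).ravel()
    if cov.shape[0] != cov.shape[1] or cov.shape[0] != g.size:
        raise ValueError("cov must be square and match the gain column")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("cov must be symmetric")
    if np.linalg.norm(g) == 0:
        raise ValueError("gain column must be nonzero")
    lam = reg * float(np.trace(cov)) / cov.shape[0]
    loaded = cov + lam * np.eye(cov.shape[0])
    try:
        cg = np.linalg.solve(loaded, g)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"regularized covariance is singular (reg={reg}); increase reg"
        ) from err
    denom = g @ cg
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError(
            f"regularized covariance is numerically singular (reg={reg}); "
            "increase reg"
        )
    return cg / denom


def lcmv_weight_matrix(
    cov: np.ndarray,
    gain: np.ndarray,
    reg: float = 0.05,
    null_constraints: bool = False,
) -> np.ndarray:
    """Weight matrix (channels x voxels) for a whole grid.

    With ``null_constraints=False`` each voxel gets the independent
    single-constraint LCMV filter of :func:`lcmv_weights`.  With
    ``null_constraints=True`` the weights additionally place a zero at every
    other grid voxel (unit gain at the target, zero gain at the rest):
    ``W = C^-1 G (G^T C^-1 G)^-1``.  The null-constrained variant eliminates
    leakage between modeled sources — the dominant confound for connectivity
    — at the cost of noise amplification, and is only practical for small
    grids (it solves one joint system over all voxels).
    """
    cov = np.asarray(cov, dtype=float)
    gain = np.asarray(gain, dtype=float)
    if not null_constraints:
        return np.column_stack(
            [lcmv_weights(cov, gain[:, v], reg) for v in range(gain.shape[1])]
        )
    lam = reg * float(np.trace(cov)) / cov.shape[0]
    loaded = cov + lam * np.eye(cov.shape[0])
    cig = np.linalg.solve(loaded, gain)
    gram = gain.T @ cig
    try:
        return cig @ np.linalg.inv(gram)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "gain Gram matrix is singular; voxels are not separable "
            "(merge close voxels or drop null constraints)"
        ) from err


def scan_grid(
    sensor_data: np.ndarray,
    gain: np.ndarray,
    grid: SourceGrid,
    reg: float = 0.05,
    cov: np.ndarray | None = None,
    band: BandDefinition | None = None,
    subject_id: str = "",
    null_constraints: bool = False,
) -> VirtualSensorSet:
    """Beamform every grid voxel; returns one virtual sensor per voxel.

    ``sensor_data`` is channels x samples; ``gain`` channels x voxels (one
    forward column per voxel).  The sensor covariance defaults to the sample
    covariance of ``sensor_data`` but can be supplied (e.g. estimated from a
    pre-stimulus baseline rather than the reconstructed window).
    """
    sensor_data = np.asarray(sensor_data, dtype=float)
    gain = np.asarray(gain, dtype=float)
    if gain.shape[1] != grid.n_voxels:
        raise ValueError("gain must have one column per grid voxel")
    if gain.shape[0] != sensor_data.shape[0]:
        raise ValueError("gain rows must match sensor channels")
    if cov is None:
        cov = np.cov(sensor_data)
    weights = lcmv_weight_matrix(cov, gain, reg, null_constraints=null_constraints)
    signals = weights.T @ sensor_data
    return VirtualSensorSet(
        signals=signals, grid=grid, band=band, subject_id=subject_id
    )


def merge_close_voxels(
    vs: VirtualSensorSet, min_dist: float = 0.010
) -> VirtualSensorSet:
    """Merge voxels closer than ``min_dist`` (default 10 mm).

    Greedy agglomeration in descending output power (ties broken by lowest
    voxel index): a voxel within ``min_dist`` of an already-retained voxel is
    absorbed by it and its signal discarded.  Separation of exactly
    ``min_dist`` keeps both voxels.  Idempotent.
    """
    pos = vs.grid.positions
    n = vs.n_sources
    order = np.lexsort((np.arange(n), -np.asarray(vs.power)))
    retained: list[int] = []
    merged_into: dict[int, int] = {}
    for v in order:
        absorbed = False
        for keeper in retained:
            if np.linalg.norm(pos[v] - pos[keeper]) < min_dist:
                merged_into[int(v)] = int(keeper)
                absorbed = True
                break
        if not absorbed:
            retained.append(int(v))
    retained.sort()
    new_grid = replace(
        vs.grid,
        positions=pos[retained],
        region_labels=tuple(vs.grid.region_labels[i] for i in retained),
    )
    return VirtualSensorSet(
        signals=vs.signals[retained],
        grid=new_grid,
        band=vs.band,
        subject_id=vs.subject_id,
        power=np.asarray(vs.power)[retained],
        merged_into=merged_into,
    )
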