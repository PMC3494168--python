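"""Single-subject preprocessing of 4-D resting-state scans.

The pipeline turns a raw ``L x W x H x T`` intensity array into the masked
``V x T'`` matrix of in-brain voxel waveforms used by every feature-creation
process downstream:

1. :func:`standardize_temporal` — truncate every scan to a common duration
   (185 s by default, the shortest scan time across acquisition sites) and
   linearly up-sample to a common 0.5 s volume time (2 Hz), giving 370 time
   points.  Up-sampling to 0.5 s, rather than resampling to an intermediate
   rate, avoids interpolation error because the sites' native volume times
   are (near-)integer multiples of 0.5 s.
2. :func:`average_subvolumes` — replace each ``k x k x k`` sub-volume by its
   mean intensity, dropping partial edge volumes (k=3 maps a 57x67x50 grid
   to 19x22x16 = 6688 cells).
3. :func:`normalize_signal` — one of three BOLD intensity normalizations:
   per-voxel percent signal change (``psc``), per-voxel z-scoring (``zn1``),
   or z-scoring against the subject's *global* scan mean and standard
   deviation (``zn2``, the default; it corrects between-subject magnitude
   differences introduced by scanner configuration).
4. :func:`compute_brain_mask` / :func:`apply_mask` — drop out-of-brain
   voxels.  Masking happens *after* normalization; the reverse order is
   known to hurt classification accuracy and raises
   :class:`~fmridx.errors.PipelineOrderError` unless explicitly forced.

All stages are per-subject and use no cross-subject statistics, so they can
be applied once, outside any cross-validation loop, without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import (
    DegenerateInputError,
    EmptyMaskError,
    GridMismatchError,
    InsufficientDurationError,
    PipelineOrderError,
    ValidationError,
)

#: Supported BOLD signal normalization methods.
NORMALIZATIONS = ("psc", "zn1", "zn2")

#: Defaults of the temporal standardization (seconds).
DEFAULT_DURATION_S = 185.0
DEFAULT_TARGET_PERIOD_S = 0.5
DEFAULT_AVG_K = 3


@dataclass
class Scan4D:
    """A subject's intensities on an ``L x W x H`` grid over ``T`` volumes.

    Parameters
    ----------
    values
        Real array indexed ``(x, y, z, t)``.
    voxel_size
        Spatial edge lengths in mm.
    sampling_period
        Volume time (TR) in seconds.
    normalization
        Name of the BOLD normalization already applied, or ``None`` for raw
        intensities.  Downstream masking checks this flag to enforce the
        normalize-then-mask order.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    sampling_period: float = 2.0
    normalization: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValidationError(
                f"values must be 4-D (L, W, H, T), got shape {self.values.shape}"
            )
        if self.values.shape[3] < 1:
            raise ValidationError("scan must contain at least one time point")
        if not self.sampling_period > 0:
            raise ValidationError("sampling_period must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Spatial grid size ``(L, W, H)``."""
        return self.values.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]

    @property
    def span_s(self) -> float:
        """Time of the last sample, ``(T - 1) * sampling_period``."""
        return (self.n_timepoints - 1) * self.sampling_period


@dataclass
class BrainMask:
    """Boolean inclusion map on the (averaged) spatial grid."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)
        if self.include.ndim != 3:
            raise ValidationError("mask must be 3-D (L, W, H)")

    @property
    def V(self) -> int:
        """Number of included voxels."""
        return int(self.include.sum())


@dataclass
class MaskedScan:
    """``V x T'`` matrix of in-brain voxel waveforms plus the voxel->grid map.

    Row ``i`` of :attr:`waveforms` is the waveform of the voxel at grid
    coordinate ``index_map[i]``; rows follow raster order (x fastest, then
    y, then z) so that the concatenated layout is identical across subjects.
    """

    waveforms: np.ndarray
    index_map: np.ndarray
    sampling_period: float

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        self.index_map = np.asarray(self.index_map, dtype=int)
        if self.waveforms.ndim != 2:
            raise ValidationError("waveforms must be a V x T' matrix")
        if self.index_map.shape != (self.waveforms.shape[0], 3):
            raise ValidationError("index_map must be V x 3, one row per waveform")

    @property
    def V(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.waveforms.shape[1]

    def scatter(self, dims: tuple[int, int, int]) -> np.ndarray:
        """Scatter rows back onto a grid of shape ``dims`` (NaN elsewhere)."""
        out = np.full(tuple(dims) + (self.n_timepoints,), np.nan)
        x, y, z = self.index_map.T
        out[x, y, z, :] = self.waveforms
        return out


def standardize_temporal(
    scan: Scan4D,
    duration_s: float = DEFAULT_DURATION_S,
    target_period_s: float = DEFAULT_TARGET_PERIOD_S,
) -> Scan4D:
    """Truncate to ``duration_s`` and linearly resample to ``target_period_s``.

    The output covers times ``0, dt, ..., duration_s - dt`` (370 samples for
    185 s at 0.5 s).  Each output value is the linear interpolation between
    the two bracketing input samples; when an output time coincides with an
    input sample the value is copied exactly, so resampling a 2 Hz scan at
    2 Hz is the identity.
    """
    if not duration_s > 0 or not target_period_s > 0:
        raise ValidationError("duration_s and target_period_s must be positive")
    n_out = int(round(duration_s / target_period_s))
    if n_out < 1:
        raise ValidationError("duration shorter than one target period")
    out_t = np.arange(n_out) * target_period_s
    in_t = np.arange(scan.n_timepoints) * scan.sampling_period
    if in_t[-1] + 1e-9 < out_t[-1]:
        raise InsufficientDurationError(
            f"scan spans {in_t[-1]:.3f} s but standardization needs samples "
            f"up to {out_t[-1]:.3f} s (duration {duration_s} s)"
        )
    if scan.n_timepoints == 1:  # only valid when a single output sample at t=0
        vals = np.repeat(scan.values, n_out, axis=3)
        return replace(scan, values=vals, sampling_period=target_period_s)
    j = np.clip(np.searchsorted(in_t, out_t, side="right") - 1, 0, scan.n_timepoints - 2)
    w = (out_t - in_t[j]) / scan.sampling_period
    vals = (1.0 - w) * scan.values[..., j] + w * scan.values[..., j + 1]
    return replace(scan, values=vals, sampling_period=target_period_s)


def average_subvolumes(scan: Scan4D, k: int = DEFAULT_AVG_K) -> Scan4D:
    """Replace each ``k x k x k`` sub-volume by its mean, per time point.

    Partial volumes at the grid edge are dropped, so the output grid is
    ``(L//k, W//k, H//k)`` and the voxel size scales by ``k``.
    """
    if int(k) != k or k < 1:
        raise ValidationError("avg_k must be a positive integer")
    k = int(k)
    L, W, H = scan.dims
    if k > min(L, W, H):
        raise ValidationError(
            f"avg_k={k} exceeds a spatial dimension of the {scan.dims} grid"
        )
    Lk, Wk, Hk = L // k, W // k, H // k
    T = scan.n_timepoints
    v = scan.values[: Lk * k, : Wk * k, : Hk * k, :]
    out = v.reshape(Lk, k, Wk, k, Hk, k, T).mean(axis=(1, 3, 5))
    voxel = tuple(s * k for s in scan.voxel_size)
    return replace(scan, values=out, voxel_size=voxel)


def normalize_signal(scan: Scan4D, method: str = "zn2", ddof: int = 0) -> Scan4D:
    """Apply one of the three BOLD signal intensity normalizations.

    ``psc``
        Percent signal change, ``(x - mu_i) * 100 / mu_i`` with ``mu_i`` the
        voxel's temporal mean.
    ``zn1``
        Per-voxel z-score, ``(x - mu_i) / sigma_i``.
    ``zn2``
        Global z-score, ``(x - mu) / sigma`` with ``mu``, ``sigma`` computed
        over the subject's entire scan; the output has global mean 0 and
        standard deviation 1, which removes per-subject gain and offset.

    ``ddof`` selects the standard-deviation convention (0 = population,
    the package default).
    """
    if method not in NORMALIZATIONS:
        raise ValidationError(f"unknown normalization {method!r}; expected one of {NORMALIZATIONS}")
    x = scan.values
    if method == "psc":
        mu = x.mean(axis=3, keepdims=True)
        bad = np.argwhere(mu[..., 0] == 0)
        if bad.size:
            raise DegenerateInputError(
                f"psc undefined: voxel {tuple(bad[0])} has zero temporal mean"
            )
        out = (x - mu) * 100.0 / mu
    elif method == "zn1":
        mu = x.mean(axis=3, keepdims=True)
        sd = x.std(axis=3, ddof=ddof, keepdims=True)
        bad = np.argwhere(sd[..., 0] == 0)
        if bad.size:
            raise DegenerateInputError(
                f"zn1 undefined: voxel {tuple(bad[0])} has zero temporal variance"
            )
        out = (x - mu) / sd
    else:  # zn2
        mu = x.mean()
        sd = x.std(ddof=ddof)
        if sd == 0:
            raise DegenerateInputError("zn2 undefined: global standard deviation is zero")
        out = (x - mu) / sd
    return replace(scan, values=out, normalization=method)


def compute_brain_mask(scan: Scan4D, force: bool = False) -> BrainMask:
    """Mask of voxels whose temporal mean intensity is positive.

    After global z-normalization, in-brain voxels sit above the scan mean
    (positive values) and out-of-brain voxels below (negative values), so
    the sign of the temporal mean separates the two.  The scan must already
    be normalized; pass ``force=True`` to override the order contract.
    """
    if scan.normalization is None and not force:
        raise PipelineOrderError(
            "compute_brain_mask called on an unnormalized scan; masking before "
            "BOLD normalization degrades accuracy (pass force=True to override)"
        )
    include = scan.values.mean(axis=3) > 0
    if not include.any():
        raise EmptyMaskError("sign-of-mean rule excluded every voxel")
    return BrainMask(include=include)


def apply_mask(scan: Scan4D, mask: BrainMask, force: bool = False) -> MaskedScan:
    """Extract the ``V x T'`` matrix of included voxel waveforms.

    Rows are ordered raster-style over grid coordinates (x fastest, then y,
    then z) so the concatenated row layout is identical for every subject
    sharing the mask.
    """
    if mask.include.shape != scan.dims:
        raise GridMismatchError(
            f"mask grid {mask.include.shape} does not match scan grid {scan.dims}"
        )
    if scan.normalization is None and not force:
        raise PipelineOrderError(
            "apply_mask called on an unnormalized scan; masking before BOLD "
            "normalization degrades accuracy (pass force=True to override)"
        )
    if mask.V < 1:
        raise EmptyMaskError("mask includes no voxels")
    # argwhere on the (z, y, x) transpose yields x-fastest raster order
    zyx = np.argwhere(mask.include.transpose(2, 1, 0))
    index_map = zyx[:, ::-1]
    x, y, z = index_map.T
    waveforms = scan.values[x, y, z, :]
    return MaskedScan(
        waveforms=waveforms, index_map=index_map, sampling_period=scan.sampling_period
    )


def preprocess_scan(
    scan: Scan4D,
    duration_s: float = DEFAULT_DURATION_S,
    target_period_s: float = DEFAULT_TARGET_PERIOD_S,
    avg_k: int = DEFAULT_AVG_K,
    normalization: str = "zn2",
) -> Scan4D:
    """Standardize, average and normalize one raw scan (mask not applied)."""
    out = standardize_temporal(scan, duration_s, target_period_s)
    out = average_subvolumes(out, avg_k)
    return normalize_signal(out, normalization)
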