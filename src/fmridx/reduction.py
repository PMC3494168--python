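"""Feature creation: FFT magnitudes and the three PCA variants.

Seven feature-creation processes are supported, each with out-of-sample
projection for held-out subjects:

========  ==================================================================
process   description
========  ==================================================================
pca_t     PCA over time.  Every voxel waveform of every subject is one row
          of the ``NV x T'`` matrix ``X_t``; the top-m temporal eigenvectors
          compress each waveform to m scores (``V*m`` features/subject).
pca_st    PCA over space and time.  Each subject's concatenated waveforms
          form one row of the ``N x VT'`` matrix ``X_st``; the dual (Gram)
          trick recovers the high-dimensional covariance eigenvectors from
          the ``N x N`` Gram matrix without materializing the ``VT' x VT'``
          covariance (m features/subject).
kpca_st   Kernelized PCA-st: eigendecomposition of the centered ``N x N``
          RBF kernel matrix; scores are the projection of the centered
          kernel onto its eigenvectors.
fft       Voxel-wise one-sided DFT magnitudes used directly as features,
          or as the "waveform" fed to any of the above (the fft+ variants).
========  ==================================================================

Determinism: eigenvectors are sign-canonicalized (largest-magnitude entry
positive) so scores are reproducible across runs and eigensolver backends.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, ValidationError
from .preprocess import MaskedScan

log = logging.getLogger(__name__)

#: RBF kernel width used for kernel PCA over space-time.
DEFAULT_SIGMA = 150.0

#: Relative threshold below which an eigenvalue is treated as zero.
EIGENVALUE_RTOL = 1e-10

VARIANTS = ("pca_t", "pca_st", "kpca_st")
PROCESS_NAMES = (
    "pca-t",
    "pca-st",
    "kpca-st",
    "fft",
    "fft+pca-t",
    "fft+pca-st",
    "fft+kpca-st",
)


def parse_process(name: str) -> tuple[Optional[str], bool]:
    """Map a process name like ``"fft+kpca-st"`` to ``(variant, use_fft)``."""
    if name not in PROCESS_NAMES:
        raise ValidationError(f"unknown process {name!r}; expected one of {PROCESS_NAMES}")
    use_fft = name == "fft" or name.startswith("fft+")
    tail = name.removeprefix("fft+")
    variant = None if tail == "fft" else tail.replace("-", "_")
    return variant, use_fft


# ---------------------------------------------------------------------------
# Data matrices
# ---------------------------------------------------------------------------

@dataclass
class TimeMatrix:
    """``NV x T'`` matrix: one voxel waveform of one subject per row.

    Subject ``s`` owns rows ``[s*V, (s+1)*V)``, voxels in raster order.
    """

    X_t: np.ndarray
    N: int
    V: int

    def __post_init__(self) -> None:
        self.X_t = np.asarray(self.X_t, dtype=float)
        if self.X_t.ndim != 2 or self.X_t.shape[0] != self.N * self.V:
            raise ValidationError(
                f"X_t must have N*V={self.N * self.V} rows, got shape {self.X_t.shape}"
            )

    @property
    def T(self) -> int:
        return self.X_t.shape[1]

    def subject(self, s: int) -> np.ndarray:
        """The ``V x T'`` block of subject ``s``."""
        return self.X_t[s * self.V : (s + 1) * self.V]


@dataclass
class SpaceTimeMatrix:
    """``N x VT'`` matrix: one subject's concatenated waveforms per row."""

    X_st: np.ndarray
    V: int

    def __post_init__(self) -> None:
        self.X_st = np.asarray(self.X_st, dtype=float)
        if self.X_st.ndim != 2:
            raise ValidationError("X_st must be 2-D")
        if self.X_st.shape[1] % self.V:
            raise ValidationError(
                f"X_st column count {self.X_st.shape[1]} is not a multiple of V={self.V}"
            )

    @property
    def N(self) -> int:
        return self.X_st.shape[0]

    @property
    def T(self) -> int:
        return self.X_st.shape[1] // self.V

    def subject(self, s: int) -> np.ndarray:
        """Row ``s`` reshaped back to its ``V x T'`` waveform block."""
        return self.X_st[s].reshape(self.V, self.T)


@dataclass
class KernelMatrix:
    """An ``n x m`` kernel evaluation; square and symmetric when ``A is B``."""

    K: np.ndarray
    sigma: float
    centered: bool = False

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2:
            raise ValidationError("kernel matrix must be 2-D")

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class ReductionModel:
    """A fitted reduction: eigenpairs plus the statistics needed to project
    held-out subjects (training column means for the linear variants;
    training rows, sigma and the uncentered training kernel for kPCA-st)."""

    variant: str
    use_fft: bool
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, unit norm, sign-canonicalized
    m: int
    mean_: Optional[np.ndarray] = None
    train_rows: Optional[np.ndarray] = None
    sigma: Optional[float] = None
    kernel_uncentered: Optional[np.ndarray] = None
    train_scores: Optional[np.ndarray] = None
    scale_scores: bool = False

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-8 * max(abs(ev[0]), 1.0)):
            raise ValidationError("eigenvalues must be nonincreasing")
        if self.m > self.eigenvectors.shape[1]:
            raise ValidationError("retained m exceeds available eigenvectors")

    def fingerprint(self) -> str:
        """Deterministic hash of the fitted state (used by leakage checks)."""
        h = hashlib.sha256()
        h.update(self.variant.encode())
        h.update(b"fft" if self.use_fft else b"raw")
        for arr in (
            self.eigenvalues,
            self.eigenvectors,
            self.mean_,
            self.train_rows,
            self.kernel_uncentered,
        ):
            if arr is not None:
                h.update(np.ascontiguousarray(np.round(arr, 12)).tobytes())
        return h.hexdigest()


@dataclass
class FeatureBlock:
    """``N x d`` feature matrix with provenance of how it was produced."""

    features: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("features must be an N x d matrix")

    @property
    def d(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# FFT magnitudes
# ---------------------------------------------------------------------------

def fft_magnitudes(waveform: np.ndarray) -> np.ndarray:
    """One-sided DFT magnitudes of a waveform (or of each row of a matrix).

    For an even-length input of ``T'`` samples, returns the magnitudes of
    frequency bins ``1 .. T'/2`` (Nyquist included).  The DC bin is excluded:
    it carries only the waveform mean, which global z-normalization has
    already standardized.  A 370-point waveform therefore yields 185 values,
    and applied voxel-wise a ``V x 370`` matrix maps to ``V x 185``.
    """
    w = np.asarray(waveform, dtype=float)
    T = w.shape[-1]
    if T < 2 or T % 2:
        raise ValidationError(f"fft_magnitudes requires an even T' >= 2, got {T}")
    return np.abs(np.fft.rfft(w, axis=-1))[..., 1:]


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _as_waveform_arrays(scans: Sequence[Union[MaskedScan, np.ndarray]]) -> list[np.ndarray]:
    mats = []
    ref_map = None
    for s in scans:
        if isinstance(s, MaskedScan):
            if ref_map is None:
                ref_map = s.index_map
            elif s.index_map.shape != ref_map.shape or not np.array_equal(
                s.index_map, ref_map
            ):
                raise ValidationError("subjects have inconsistent voxel index maps")
            mats.append(s.waveforms)
        else:
            mats.append(np.asarray(s, dtype=float))
    if not mats:
        raise ValidationError("no subjects given")
    shape = mats[0].shape
    for i, m in enumerate(mats):
        if m.ndim != 2 or m.shape != shape:
            raise ValidationError(
                f"subject {i} has waveform shape {m.shape}, expected {shape}"
            )
    return mats


def build_time_matrix(scans: Sequence[Union[MaskedScan, np.ndarray]]) -> TimeMatrix:
    """Stack all subjects' ``V x T'`` blocks vertically into ``X_t``."""
    mats = _as_waveform_arrays(scans)
    V = mats[0].shape[0]
    return TimeMatrix(X_t=np.vstack(mats), N=len(mats), V=V)


def build_spacetime_matrix(scans: Sequence[Union[MaskedScan, np.ndarray]]) -> SpaceTimeMatrix:
    """Concatenate each subject's waveforms into one row of ``X_st``."""
    mats = _as_waveform_arrays(scans)
    V = mats[0].shape[0]
    return SpaceTimeMatrix(X_st=np.stack([m.ravel() for m in mats]), V=V)


# ---------------------------------------------------------------------------
# Shared eigen helpers
# ---------------------------------------------------------------------------

def _canonicalize_signs(E: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if E.size == 0:
        return E
    idx = np.argmax(np.abs(E), axis=0)
    signs = np.sign(E[idx, np.arange(E.shape[1])])
    signs[signs == 0] = 1.0
    return E * signs


def _descending_eigh(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(S)
    return w[::-1], V[:, ::-1]


def _resolve_m(eigenvalues: np.ndarray, n_positive: int, m) -> int:
    """Turn ``m`` (int, variance fraction in (0,1), or None) into a count."""
    if n_positive < 1:
        raise DegenerateInputError("no positive eigenvalues: input has rank 0")
    if m is None:
        return n_positive
    if isinstance(m, float) and 0.0 < m < 1.0:
        frac = np.cumsum(eigenvalues[:n_positive]) / eigenvalues[:n_positive].sum()
        return int(np.searchsorted(frac, m) + 1)
    m = int(m)
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m > n_positive:
        log.warning(
            "requested m=%d exceeds the %d positive eigenvalues; clipping", m, n_positive
        )
        return n_positive
    return m


def _positive_count(w: np.ndarray) -> int:
    if w.size == 0 or w[0] <= 0:
        return 0
    return int(np.sum(w > EIGENVALUE_RTOL * w[0]))


# ---------------------------------------------------------------------------
# PCA over time
# ---------------------------------------------------------------------------

def fit_pca_t(X: TimeMatrix, m=None, use_fft: bool = False) -> ReductionModel:
    """Eigendecompose the ``T' x T'`` covariance of column-centered ``X_t``.

    ``m`` may be an integer count, a variance fraction in (0, 1) (smallest
    count whose eigenvalue sum reaches the fraction), or None for all
    components above the rank tolerance.
    """
    A = X.X_t
    if A.shape[0] < 2:
        raise ValidationError("PCA-t needs at least two rows")
    mean = A.mean(axis=0)
    Ac = A - mean
    cov = Ac.T @ Ac / A.shape[0]
    w, V = _descending_eigh(cov)
    w = np.clip(w, 0.0, None)
    npos = _positive_count(w)
    if npos == 0:
        raise DegenerateInputError("all rows identical: covariance has rank 0")
    m_ = _resolve_m(w, npos, m)
    E = _canonicalize_signs(V[:, :m_])
    return ReductionModel(
        variant="pca_t", use_fft=use_fft, eigenvalues=w, eigenvectors=E, m=m_, mean_=mean
    )


def project_pca_t(model: ReductionModel, scan: Union[MaskedScan, np.ndarray]) -> np.ndarray:
    """Scores of one subject's ``V`` waveforms, concatenated voxel-major.

    Each waveform, after subtracting the training column means, is projected
    onto the top-m eigenvectors; the result has ``V * m`` entries.
    """
    if model.variant != "pca_t":
        raise ValidationError(f"model variant is {model.variant!r}, expected 'pca_t'")
    W = scan.waveforms if isinstance(scan, MaskedScan) else np.asarray(scan, dtype=float)
    if W.ndim != 2 or W.shape[1] != model.mean_.shape[0]:
        raise ValidationError(
            f"waveform length {W.shape} does not match training T'={model.mean_.shape[0]}"
        )
    return ((W - model.mean_) @ model.eigenvectors).ravel()


# ---------------------------------------------------------------------------
# PCA over space and time (dual trick)
# ---------------------------------------------------------------------------

def fit_pca_st(X: SpaceTimeMatrix, m=None, use_fft: bool = False) -> ReductionModel:
    """Dual-trick PCA on the ``N x VT'`` matrix.

    The ``N x N`` Gram matrix of the column-centered data is
    eigendecomposed; each dual eigenvector ``u_i`` with Gram eigenvalue
    ``nu_i`` maps to the unit-norm primal covariance eigenvector
    ``e_i = X_c^T u_i / sqrt(nu_i)``.  The ``VT' x VT'`` covariance is never
    materialized.  Covariance eigenvalues use the population convention
    ``nu_i / N``.
    """
    A = X.X_st
    N = A.shape[0]
    if N < 2:
        raise ValidationError("PCA-st needs at least two subjects")
    mean = A.mean(axis=0)
    Ac = A - mean
    G = Ac @ Ac.T
    nu, U = _descending_eigh(G)
    nu = np.clip(nu, 0.0, None)
    npos = _positive_count(nu)
    if npos == 0:
        raise DegenerateInputError("all subjects identical: Gram matrix has rank 0")
    m_ = _resolve_m(nu, npos, m)
    E = Ac.T @ (U[:, :m_] / np.sqrt(nu[:m_]))
    E = _canonicalize_signs(E)
    return ReductionModel(
        variant="pca_st",
        use_fft=use_fft,
        eigenvalues=nu / N,
        eigenvectors=E,
        m=m_,
        mean_=mean,
    )


def project_pca_st(model: ReductionModel, rows: np.ndarray) -> np.ndarray:
    """Scores ``Z[j, i] = <x_j - mean, e_i>`` for each subject row ``x_j``."""
    if model.variant != "pca_st":
        raise ValidationError(f"model variant is {model.variant!r}, expected 'pca_st'")
    R = np.atleast_2d(np.asarray(rows, dtype=float))
    if R.shape[1] != model.mean_.shape[0]:
        raise ValidationError(
            f"row length {R.shape[1]} does not match training VT'={model.mean_.shape[0]}"
        )
    return (R - model.mean_) @ model.eigenvectors


# ---------------------------------------------------------------------------
# RBF kernel and kernel PCA
# ---------------------------------------------------------------------------

def rbf_kernel(A: np.ndarray, B: Optional[np.ndarray] = None, sigma: float = DEFAULT_SIGMA) -> KernelMatrix:
    """Gaussian kernel ``K[i, j] = exp(-||a_i - b_j||^2 / (2 sigma^2))``.

    With ``B=None`` the kernel of ``A`` against itself is returned,
    symmetric with unit diagonal.
    """
    if not sigma > 0:
        raise ValidationError("sigma must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    symmetric = B is None
    Bm = A if symmetric else np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != Bm.shape[1]:
        raise ValidationError("A and B must share a column count")
    d2 = cdist(A, Bm, "sqeuclidean")
    K = np.exp(-d2 / (2.0 * sigma**2))
    if symmetric:
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return KernelMatrix(K=K, sigma=sigma, centered=False)


def center_kernel(K: KernelMatrix) -> KernelMatrix:
    """Mean-center a square kernel matrix in feature space.

    Computes ``K - 1_N K - K 1_N + 1_N K 1_N`` where every entry of the
    ``N x N`` matrix ``1_N`` is ``1/N``.  Every row and column of the result
    sums to zero; the operation is idempotent.
    """
    M = K.K
    if M.shape[0] != M.shape[1]:
        raise ValidationError("center_kernel requires a square kernel matrix")
    ones = np.full_like(M, 1.0 / M.shape[0])
    Kc = M - ones @ M - M @ ones + ones @ M @ ones
    return KernelMatrix(K=Kc, sigma=K.sigma, centered=True)


def fit_kpca_st(
    X: Union[SpaceTimeMatrix, np.ndarray],
    sigma: float = DEFAULT_SIGMA,
    m=None,
    use_fft: bool = False,
    scale_scores: bool = False,
) -> ReductionModel:
    """Kernel PCA over space-time, in four steps.

    1. Uncentered RBF kernel over the training rows (strictly positive
       definite for distinct rows, so all ``N`` eigenvalues of the raw
       kernel are positive).
    2. Center it in feature space.
    3. Eigendecompose the centered kernel (descending eigenvalues).
    4. Training scores are the centered kernel projected onto its
       eigenvectors, ``Z = K E`` — column ``i`` equals ``lambda_i e_i``.

    ``scale_scores=True`` switches to the textbook ``1/sqrt(lambda)``
    normalization of the score columns.  By default all ``N`` components are
    retained (``m=None``), including the near-zero one introduced by
    centering.
    """
    rows = X.X_st if isinstance(X, SpaceTimeMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    N = rows.shape[0]
    if N < 2:
        raise ValidationError("kPCA-st needs at least two subjects")
    Kt = rbf_kernel(rows, None, sigma)
    Kc = center_kernel(Kt)
    w, U = _descending_eigh(Kc.K)
    w = np.clip(w, 0.0, None)
    E = _canonicalize_signs(U)
    m_ = N if m is None else min(int(m), N)
    if m is not None and int(m) > N:
        log.warning("requested m=%d exceeds N=%d kernel components; clipping", int(m), N)
    E = E[:, :m_]
    Z = Kc.K @ E
    if scale_scores:
        scale = np.where(w[:m_] > EIGENVALUE_RTOL * max(w[0], 1e-300), np.sqrt(w[:m_]), 1.0)
        Z = Z / scale
    return ReductionModel(
        variant="kpca_st",
        use_fft=use_fft,
        eigenvalues=w,
        eigenvectors=E,
        m=m_,
        train_rows=rows.copy(),
        sigma=sigma,
        kernel_uncentered=Kt.K,
        train_scores=Z,
        scale_scores=scale_scores,
    )


def project_kpca_st(model: ReductionModel, rows: np.ndarray) -> FeatureBlock:
    """Out-of-sample kernel-PCA scores for held-out subjects.

    The test-versus-training kernel rows are centered against the
    *training* kernel, ``k = k~ - 1'_t K~ - k~ 1_N + 1'_t K~ 1_N`` (``1'_t``
    a ``t x N`` matrix of entries ``1/N``), then projected onto the training
    eigenvectors.  Projecting a training subject reproduces its training
    score row exactly.
    """
    if model.variant != "kpca_st":
        raise ValidationError(f"model variant is {model.variant!r}, expected 'kpca_st'")
    R = np.atleast_2d(np.asarray(rows, dtype=float))
    if R.shape[1] != model.train_rows.shape[1]:
        raise ValidationError(
            f"row length {R.shape[1]} does not match training {model.train_rows.shape[1]}"
        )
    Kt = rbf_kernel(R, model.train_rows, model.sigma).K
    N = model.train_rows.shape[0]
    ones_t = np.full((R.shape[0], N), 1.0 / N)
    ones_N = np.full((N, N), 1.0 / N)
    KtrU = model.kernel_uncentered
    Kc = Kt - ones_t @ KtrU - Kt @ ones_N + ones_t @ KtrU @ ones_N
    Z = Kc @ model.eigenvectors
    if model.scale_scores:
        w = model.eigenvalues[: model.m]
        scale = np.where(w > EIGENVALUE_RTOL * max(model.eigenvalues[0], 1e-300), np.sqrt(w), 1.0)
        Z = Z / scale
    return FeatureBlock(
        features=Z,
        provenance={"variant": "kpca_st", "m": model.m, "sigma": model.sigma},
    )


# ---------------------------------------------------------------------------
# Dispatch over the seven processes
# ---------------------------------------------------------------------------

def make_features(
    scans: Sequence[Union[MaskedScan, np.ndarray]],
    variant: Optional[str],
    use_fft: bool,
    m=None,
    sigma: float = DEFAULT_SIGMA,
    model: Optional[ReductionModel] = None,
) -> tuple[Optional[ReductionModel], FeatureBlock]:
    """Run one feature-creation process over a cohort of masked scans.

    ``variant`` is one of ``'pca_t'``, ``'pca_st'``, ``'kpca_st'`` or
    ``None`` (FFT magnitudes used directly, which requires ``use_fft``).
    When ``model`` is given, the scans are projected with the existing fit
    (out-of-sample use); otherwise the reduction is fitted on ``scans``.
    """
    if variant is not None and variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    mats = _as_waveform_arrays(scans)
    if use_fft:
        mats = [fft_magnitudes(W) for W in mats]
    V, T = mats[0].shape
    prov = {"variant": variant or "fft", "use_fft": use_fft}

    if variant is None:
        if not use_fft:
            raise ValidationError(
                "the identity process without FFT is not a supported feature set"
            )
        F = np.stack([W.ravel() for W in mats])
        return None, FeatureBlock(features=F, provenance=prov | {"d": F.shape[1]})

    if variant == "pca_t":
        if model is None:
            model = fit_pca_t(build_time_matrix(mats), m=m, use_fft=use_fft)
        F = np.stack([project_pca_t(model, W) for W in mats])
    elif variant == "pca_st":
        X = build_spacetime_matrix(mats)
        if model is None:
            model = fit_pca_st(X, m=m, use_fft=use_fft)
        F = project_pca_st(model, X.X_st)
    else:  # kpca_st
        X = build_spacetime_matrix(mats)
        if model is None:
            model = fit_kpca_st(X, sigma=sigma, m=m, use_fft=use_fft)
        F = project_kpca_st(model, X.X_st).features
    prov |= {"m": model.m, "sigma": sigma if variant == "kpca_st" else None}
    return model, FeatureBlock(features=F, provenance=prov)
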