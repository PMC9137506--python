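"""Subject-level voxelwise GLM for event-related Go/NoGo fMRI.

The BOLD time series at each voxel is modelled as

    y_v = X beta_v + e_v

where the n x p design matrix ``X`` holds one global-signal nuisance
component (the first principal component of the in-mask data), the six
rigid-body motion time series, and the four task regressors obtained by
convolving the one-hot trial-outcome columns of the performance matrix Z
(correct Go, correct NoGo, omission, commission) with a gamma-shaped
hemodynamic response function.  With standard inputs ``p = 11``.

Estimation uses the Moore-Penrose pseudo-inverse ``G = (X'X)^+``:

    beta_hat = G X' y
    sigma2_hat = (y'y - y'X G X'y) / df,   df = n - 1 - rank(X'X)
    t_v = C' beta_hat / sqrt(sigma2_hat * C' G C)

with the NoGo-minus-Go contrast C = (0, ..., -1, +1, 0, 0)'.  Both y and
the columns of X are mean-centred before fitting, which together with the
``n - 1`` term in the df acts as an implicit intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .errors import ConfigurationError, MaskError, UndefinedStatisticError

__all__ = [
    "HrfKernel",
    "DesignMatrix",
    "GlmFit",
    "SubjectBoldMap",
    "SubjectGLM",
    "SubjectGLMResults",
    "gamma_hrf",
    "convolve_events",
    "compute_brain_mask",
    "first_pc_timecourse",
    "build_design_matrix",
    "default_contrast",
    "fit_glm_contrast",
    "subject_map",
]

#: ordered roles of the 11 design-matrix columns
COLUMN_ROLES = (
    "pc1",
    "motion_tx", "motion_ty", "motion_tz",
    "motion_rx", "motion_ry", "motion_rz",
    "correct_go", "correct_nogo", "omission", "commission",
)

#: relative singular-value cutoff for the pseudo-inverse / rank decisions
PINV_RTOL = 1e-10


# ---------------------------------------------------------------------------
# hemodynamic response function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfKernel:
    """Gamma-density-shaped HRF sampled at the TR, scaled to unit peak.

    ``dispersion`` is the gamma scale parameter b (seconds); the shape is
    a = peak/b + 1 so that the density mode sits exactly at ``peak_seconds``.
    """

    peak_seconds: float
    dispersion: float
    tr_seconds: float
    samples: np.ndarray

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.samples)


def gamma_hrf(
    peak_seconds: float = 6.0,
    dispersion: float = 0.7,
    tr_seconds: float = 2.0,
    kernel_length: int = 16,
) -> HrfKernel:
    """Single-gamma HRF.

    Defaults: peak at 6 s, scale 0.7 s (FWHM ~ 5 s), 16 samples at TR 2 s
    (32 s support).  The returned samples are non-negative and normalised
    so the largest sample equals 1.
    """
    if peak_seconds <= 0 or dispersion <= 0 or tr_seconds <= 0:
        raise ConfigurationError("HRF parameters must be positive")
    if kernel_length < 1:
        raise ConfigurationError("kernel_length must be >= 1")
    shape = peak_seconds / dispersion + 1.0
    t = np.arange(kernel_length, dtype=float) * tr_seconds
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h = np.where(t > 0, (shape - 1.0) * np.log(t) - t / dispersion, -np.inf)
    h = np.exp(log_h - log_h.max()) if np.isfinite(log_h).any() else np.zeros_like(t)
    if kernel_length == 1:
        h = np.ones(1)
    peak = h.max()
    if peak <= 0:  # pragma: no cover - unreachable for valid params
        raise ConfigurationError("degenerate HRF kernel")
    return HrfKernel(peak_seconds, dispersion, tr_seconds, h / peak)


def convolve_events(Z: np.ndarray, h: HrfKernel) -> np.ndarray:
    """Causal convolution of each event column z_j with the HRF kernel,
    truncated to the n scan volumes.  Returns an n x 4 regressor block."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ConfigurationError("Z must be a 2-D (n x 4) matrix")
    n = Z.shape[0]
    out = np.empty_like(Z)
    for j in range(Z.shape[1]):
        out[:, j] = np.convolve(Z[:, j], h.samples)[:n]
    return out


def convolution_matrix(h: HrfKernel, n: int) -> np.ndarray:
    """Lower-triangular Toeplitz matrix H with H @ Z == convolve_events(Z, h)."""
    col = np.zeros(n)
    k = min(len(h.samples), n)
    col[:k] = h.samples[:k]
    from scipy.linalg import toeplitz

    return toeplitz(col, np.zeros(n))


# ---------------------------------------------------------------------------
# mask and nuisance component
# ---------------------------------------------------------------------------

def compute_brain_mask(mean_volume: np.ndarray, threshold_fraction: float = 0.4) -> np.ndarray:
    """Intensity-threshold brain mask from the temporal-mean volume.

    A voxel enters the mask when its mean intensity is at least
    ``threshold_fraction`` times the robust maximum (99th percentile).
    """
    vol = np.asarray(mean_volume, dtype=float)
    if not np.isfinite(vol).all():
        raise MaskError("mean volume contains non-finite values")
    robust_max = np.percentile(vol, 99)
    mask = vol >= threshold_fraction * robust_max
    if not mask.any():
        raise MaskError(
            f"empty brain mask: threshold {threshold_fraction} x 99th pct "
            f"({robust_max:.3g}) exceeds every voxel (max {vol.max():.3g})"
        )
    return mask


def first_pc_timecourse(bold: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """First principal-component time course of the in-mask data.

    The time x voxel matrix (each voxel's temporal mean removed) is
    decomposed; the returned unit-norm n-vector is the first left-singular
    direction, sign-fixed to correlate positively with the global mean
    time course (largest-magnitude element positive if that correlation
    is exactly zero).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise MaskError("need at least 2 voxels in mask for PCA")
    M = np.asarray(bold, dtype=float)[mask].T  # n x V
    Mc = M - M.mean(axis=0, keepdims=True)
    if not Mc.any():
        raise MaskError("no temporal variance inside mask")
    # top left-singular vector via the (small) temporal Gram matrix
    evals, evecs = np.linalg.eigh(Mc @ Mc.T)
    pc1 = evecs[:, -1]
    ref = Mc.mean(axis=1)
    proj = float(pc1 @ ref)
    if proj < 0:
        pc1 = -pc1
    elif proj == 0 and pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return pc1


# ---------------------------------------------------------------------------
# design matrix and contrast
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """n x p design matrix with recorded column roles (p = 11 when built
    from the standard pc1 + 6 motion + 4 event-regressor inputs)."""

    X: np.ndarray
    column_roles: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design_matrix(
    pc1: np.ndarray,
    motion: np.ndarray,
    Z: np.ndarray,
    h: HrfKernel,
) -> DesignMatrix:
    """Assemble X = [pc1 | motion (6) | h*z1 .. h*z4]; p = 11."""
    pc1 = np.asarray(pc1, dtype=float).reshape(-1)
    motion = np.asarray(motion, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = pc1.shape[0]
    if motion.ndim != 2 or motion.shape != (n, 6):
        raise ConfigurationError(f"motion must be {n} x 6, got {motion.shape}")
    if Z.shape != (n, 4):
        raise ConfigurationError(f"Z must be {n} x 4, got {Z.shape}")
    events = convolve_events(Z, h)
    X = np.column_stack([pc1, motion, events])
    return DesignMatrix(X=X, column_roles=COLUMN_ROLES)


def default_contrast(p: int = 11) -> np.ndarray:
    """NoGo-minus-Go contrast: -1 at the correct-Go regressor, +1 at the
    correct-NoGo regressor, 0 elsewhere."""
    if p < 10:
        raise ConfigurationError("contrast needs at least 10 columns")
    C = np.zeros(p)
    C[p - 4] = -1.0  # correct Go
    C[p - 3] = 1.0   # correct NoGo
    return C


@dataclass(frozen=True)
class GlmFit:
    """Per-voxel GLM estimate bundle."""

    beta_hat: np.ndarray
    sigma2_hat: float
    df: int
    G: np.ndarray


def _design_core(X: np.ndarray):
    """Centre columns, form G = pinv(X'X), rank and df.  Shared by the
    scalar and vectorised fitting paths."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    XtX = Xc.T @ Xc
    s = np.linalg.svd(XtX, compute_uv=False)
    cutoff = PINV_RTOL * (s[0] if s.size else 0.0)
    rank = int((s > cutoff).sum())
    G = np.linalg.pinv(XtX, rcond=PINV_RTOL)
    df = n - 1 - rank
    if df <= 0:
        raise ConfigurationError(f"non-positive degrees of freedom (n={n}, rank={rank})")
    return Xc, G, rank, df


def fit_glm_contrast(y: np.ndarray, X: DesignMatrix | np.ndarray, C: np.ndarray) -> float:
    """Contrast t statistic for a single voxel time series."""
    Xmat = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.shape[0] != Xmat.shape[0]:
        raise ConfigurationError("y and X have different numbers of rows")
    C = np.asarray(C, dtype=float).reshape(-1)
    if C.shape[0] != Xmat.shape[1]:
        raise ConfigurationError("contrast length does not match p")
    Xc, G, _, df = _design_core(Xmat)
    yc = y - y.mean()
    Xty = Xc.T @ yc
    beta = G @ Xty
    rss = float(yc @ yc - Xty @ beta)
    sigma2 = rss / df
    ctgc = float(C @ G @ C)
    num = float(C @ beta)
    if num == 0 and sigma2 > 0:
        # null contrast (e.g. C = 0) with residual variance: t = 0
        return 0.0
    if sigma2 <= 0 or ctgc <= 0:
        raise UndefinedStatisticError(
            f"undefined t: sigma2={sigma2:.3g}, C'GC={ctgc:.3g}"
        )
    return num / np.sqrt(sigma2 * ctgc)


def _fit_tmap(Y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Vectorised contrast t over voxels.

    Y is n x V.  Returns (t, undefined) where ``undefined`` marks voxels
    with zero residual variance; their t is set to 0.
    """
    Xc, G, _, df = _design_core(X)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    XtY = Xc.T @ Yc
    beta = G @ XtY
    rss = np.einsum("ij,ij->j", Yc, Yc) - np.einsum("ij,ij->j", XtY, beta)
    sigma2 = rss / df
    ctgc = float(C @ G @ C)
    if ctgc <= 0:
        raise UndefinedStatisticError(f"contrast variance C'GC = {ctgc:.3g} <= 0")
    num = C @ beta
    scale = np.sqrt(np.maximum(sigma2, 0.0) * ctgc)
    undefined = sigma2 <= PINV_RTOL * max(float(np.max(np.abs(rss)) / df), 1.0)
    t = np.zeros_like(num)
    ok = ~undefined
    t[ok] = num[ok] / scale[ok]
    return t, undefined


# ---------------------------------------------------------------------------
# subject-level model object
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectBoldMap:
    """Subject-level BOLD response map: voxelwise t with its brain mask."""

    tmap: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)


class SubjectGLM:
    """Voxelwise GLM for one subject's 4-D BOLD run.

    Parameters
    ----------
    bold : (x, y, z, n) array
        Motion-corrected BOLD volumes.
    Z : (n, 4) array
        One-hot trial-outcome (performance) matrix.
    motion : (n, 6) array
        Rigid-body motion time series (3 translations, 3 rotations).
    hrf : HrfKernel, optional
        Defaults to the canonical single-gamma kernel at the run's TR = 2 s.
    mask : 3-D bool array, optional
        Brain mask; computed from the mean volume if omitted.
    mask_fraction : float
        Intensity threshold fraction for the automatic mask.
    contrast : array, optional
        Defaults to the NoGo-minus-Go contrast.
    """

    def __init__(self, bold, Z, motion, hrf: HrfKernel | None = None,
                 mask: np.ndarray | None = None, mask_fraction: float = 0.4,
                 contrast: np.ndarray | None = None, meta: dict | None = None):
        bold = np.asarray(bold, dtype=float)
        if bold.ndim != 4:
            raise ConfigurationError("bold must be 4-D (x, y, z, n)")
        n = bold.shape[-1]
        Z = np.asarray(Z)
        motion = np.asarray(motion, dtype=float)
        if Z.shape[0] != n or motion.shape[0] != n:
            raise ConfigurationError("time dimension of bold, Z and motion must agree")
        self.bold = bold
        self.Z = Z
        self.motion = motion
        self.hrf = hrf if hrf is not None else gamma_hrf()
        self.mask = (np.asarray(mask, dtype=bool) if mask is not None
                     else compute_brain_mask(bold.mean(axis=-1), mask_fraction))
        self.contrast = (np.asarray(contrast, dtype=float)
                         if contrast is not None else default_contrast())
        self.meta = dict(meta or {})

    def fit(self) -> "SubjectGLMResults":
        pc1 = first_pc_timecourse(self.bold, self.mask)
        design = build_design_matrix(pc1, self.motion, self.Z, self.hrf)
        Y = self.bold[self.mask].T  # n x V
        t, undefined = _fit_tmap(Y, design.X, self.contrast)
        tmap = np.zeros(self.bold.shape[:3])
        tmap[self.mask] = t
        _, _, rank, df = _design_core(design.X)
        return SubjectGLMResults(
            model=self, design=design, pc1=pc1, tmap=tmap,
            df=df, rank=rank, n_undefined=int(undefined.sum()),
        )


@dataclass(frozen=True)
class SubjectGLMResults:
    """Fitted subject-level GLM: the t-map and its bookkeeping."""

    model: SubjectGLM
    design: DesignMatrix
    pc1: np.ndarray
    tmap: np.ndarray
    df: int
    rank: int
    n_undefined: int

    @property
    def bold_map(self) -> SubjectBoldMap:
        return SubjectBoldMap(tmap=self.tmap, mask=self.model.mask, meta=self.model.meta)

    def summary(self) -> str:
        inside = self.tmap[self.model.mask]
        lines = [
            "Subject-level GLM (NoGo vs Go contrast)",
            f"  volumes (n):        {self.design.n}",
            f"  design columns (p): {self.design.p}",
            f"  rank(X'X):          {self.rank}",
            f"  df:                 {self.df}",
            f"  mask voxels:        {int(self.model.mask.sum())}",
            f"  undefined voxels:   {self.n_undefined}",
            f"  t range:            [{inside.min():.3f}, {inside.max():.3f}]",
        ]
        return "\n".join(lines)


def subject_map(dataset, hrf: HrfKernel | None = None,
                mask_fraction: float = 0.4) -> SubjectBoldMap:
    """One-call subject-level BOLD response map from a SubjectDataset."""
    if hrf is None:
        hrf = gamma_hrf(tr_seconds=getattr(dataset, "tr_seconds", 2.0))
    meta = {"subject_id": getattr(dataset, "subject_id", None),
            "group": getattr(dataset, "group", None)}
    model = SubjectGLM(dataset.bold, dataset.Z, dataset.motion, hrf=hrf,
                       mask_fraction=mask_fraction, meta=meta)
    return model.fit().bold_map
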