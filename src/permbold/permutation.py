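"""Permutation-based familywise-error control for the group BOLD map.

The null distribution is built by rerunning the subject-GLM -> smooth ->
median pipeline with each subject's performance matrix Z row-shuffled
(which preserves every subject's outcome counts, i.e. their accuracy,
while destroying the event timing).  The global maximum and minimum of
each permuted group map form two empirical distributions, from which six
thresholds are read off: T_aU for the upper tail and the (negative)
lower cutoffs for a in {0.001, 0.01, 0.05}.  A voxel of the one true
group map anywhere above T_aU (below the lower cutoff) would arise with
empirical probability strictly less than a under the null, which is
familywise control per tail.

Contiguous suprathreshold clusters larger than a minimum volume
(default 100 mm^3) are then extracted per sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .glm import (PINV_RTOL, HrfKernel, compute_brain_mask, convolution_matrix,
                  default_contrast, first_pc_timecourse, gamma_hrf)
from .group import median_map, smoothing_normalizer

__all__ = [
    "NullDistribution",
    "ThresholdSet",
    "ClusterRecord",
    "permute_performance",
    "PermutationEngine",
    "null_distribution",
    "compute_thresholds",
    "threshold_map",
    "extract_clusters",
    "DEFAULT_ALPHAS",
]

DEFAULT_ALPHAS = (0.001, 0.01, 0.05)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class NullDistribution:
    """Per-run global maxima and minima of B permuted group maps."""

    maxima: np.ndarray
    minima: np.ndarray
    master_seed: int

    @property
    def B(self) -> int:
        return len(self.maxima)

    def __post_init__(self):
        if len(self.maxima) != len(self.minima):
            raise ConfigurationError("maxima and minima lengths differ")
        if np.any(self.maxima < self.minima):
            raise ConfigurationError("found run with maximum < minimum")


@dataclass(frozen=True)
class ThresholdSet:
    """Six empirical FWER thresholds.

    ``upper[a]`` is the positive cutoff T_aU; ``lower[a]`` is the signed
    negative lower cutoff (-T_aL): a voxel is significant at level ``a``
    when its value is > upper[a] or < lower[a].
    """

    upper: dict[float, float]
    lower: dict[float, float]
    alphas: tuple[float, ...] = DEFAULT_ALPHAS

    def __post_init__(self):
        ups = [self.upper[a] for a in sorted(self.alphas)]
        los = [self.lower[a] for a in sorted(self.alphas)]
        if any(np.diff(ups) > 0) or any(np.diff(los) < 0):
            raise ConfigurationError("thresholds are not nested in alpha")

    def __len__(self) -> int:
        return len(self.upper) + len(self.lower)


@dataclass(frozen=True)
class ClusterRecord:
    """One significant suprathreshold cluster."""

    sign: str                      # "positive" | "negative"
    size_voxels: int
    size_mm3: float
    peak_coord: tuple[int, int, int]
    peak_value: float
    tier: int                      # most stringent alpha tier at the peak
    label: str = ""
    peak_mm: tuple[float, float, float] | None = None
    voxels: np.ndarray | None = None  # (size_voxels, 3) member coordinates


def permute_performance(Z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random row shuffle of Z; column sums (performance
    levels) are preserved exactly."""
    Z = np.asarray(Z)
    return Z[rng.permutation(Z.shape[0])]


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

class PermutationEngine:
    """Shared machinery for the true analysis and the permutation runs.

    Quantities that do not depend on the event timing -- each subject's
    brain mask, nuisance principal component, motion regressors, and the
    projection of the data onto the nuisance-orthogonal subspace -- are
    computed once.  Each run then only rebuilds the four HRF-convolved
    event regressors from a (possibly permuted) Z and solves the reduced
    4-column problem, which is algebraically identical to the full
    11-column GLM contrast for full-rank designs (Frisch-Waugh).
    """

    def __init__(self, cohort, hrf: HrfKernel | None = None,
                 mask_fraction: float = 0.4, smoothing_sd_mm: float = 3.0,
                 voxel_size_mm: Sequence[float] = (2.5, 2.5, 3.5)):
        if len(cohort) == 0:
            raise ConfigurationError("empty cohort")
        self.cohort = list(cohort)
        n = self.cohort[0].bold.shape[-1]
        self.n = n
        self.hrf = hrf if hrf is not None else gamma_hrf(
            tr_seconds=getattr(self.cohort[0], "tr_seconds", 2.0))
        self.smoothing_sd_mm = float(smoothing_sd_mm)
        self.voxel_size_mm = tuple(voxel_size_mm)
        self.contrast_events = np.array([-1.0, 1.0, 0.0, 0.0])
        self.H = convolution_matrix(self.hrf, n)

        self._subjects = []
        masks = []
        for ds in self.cohort:
            if ds.bold.shape[-1] != n:
                raise ConfigurationError("subjects have different run lengths")
            mask = compute_brain_mask(ds.bold.mean(axis=-1), mask_fraction)
            pc1 = first_pc_timecourse(ds.bold, mask)
            X0 = np.column_stack([pc1, ds.motion])
            X0c = X0 - X0.mean(axis=0, keepdims=True)
            Q0, R0 = np.linalg.qr(X0c)
            diag = np.abs(np.diag(R0))
            keep = diag > PINV_RTOL * max(diag.max(), 1.0)
            Q0 = Q0[:, keep]
            rank0 = int(keep.sum())
            Y = ds.bold[mask].T.astype(float)           # n x V
            Yc = Y - Y.mean(axis=0, keepdims=True)
            Yr = Yc - Q0 @ (Q0.T @ Yc)
            self._subjects.append({
                "mask": mask, "Q0": Q0, "rank0": rank0, "Z": np.asarray(ds.Z),
                "Yr": Yr, "ytyr": np.einsum("ij,ij->j", Yr, Yr),
            })
            masks.append(mask)
        self.group_mask = np.logical_and.reduce(masks)
        if not self.group_mask.any():
            raise ConfigurationError("empty intersection brain mask")
        self._norm = {}
        for i, sub in enumerate(self._subjects):
            key = sub["mask"].tobytes()
            if key not in self._norm:
                self._norm[key] = smoothing_normalizer(
                    sub["mask"], self.smoothing_sd_mm, self.voxel_size_mm)
            sub["norm"] = self._norm[key]

    # -- per-subject reduced GLM ------------------------------------------

    def _subject_tmap(self, sub: dict, Z: np.ndarray) -> np.ndarray:
        E = self.H @ Z.astype(float)
        Ec = E - E.mean(axis=0, keepdims=True)
        Er = Ec - sub["Q0"] @ (sub["Q0"].T @ Ec)
        Ue, se, Vte = np.linalg.svd(Er, full_matrices=False)
        keep = se > PINV_RTOL * max(se[0] if se.size else 0.0, 1.0)
        rank_e = int(keep.sum())
        df = self.n - 1 - (sub["rank0"] + rank_e)
        if df <= 0:
            raise ConfigurationError("non-positive df in permutation run")
        # G restricted to event block: pinv(Er'Er) = V diag(1/s^2) V'
        Vk = Vte[keep].T
        inv_s2 = 1.0 / se[keep] ** 2
        EtY = Er.T @ sub["Yr"]
        beta = Vk @ (inv_s2[:, None] * (Vk.T @ EtY))
        Ce = self.contrast_events
        ctgc = float((Vk.T @ Ce) ** 2 @ inv_s2)
        num = Ce @ beta
        rss = sub["ytyr"] - np.einsum("ij,ij->j", EtY, beta)
        sigma2 = rss / df
        if ctgc <= 0:
            return np.zeros(int(sub["mask"].sum()))
        scale = np.sqrt(np.maximum(sigma2, 0.0) * ctgc)
        t = np.zeros_like(num)
        ok = scale > 0
        t[ok] = num[ok] / scale[ok]
        return t

    def _smoothed_subject_map(self, sub: dict, Z: np.ndarray) -> np.ndarray:
        t = self._subject_tmap(sub, Z)
        vol = np.zeros(sub["mask"].shape)
        vol[sub["mask"]] = t
        if self.smoothing_sd_mm == 0:
            return vol
        sigma_vox = [self.smoothing_sd_mm / v for v in self.voxel_size_mm]
        num = ndimage.gaussian_filter(vol, sigma_vox, mode="constant",
                                      truncate=4.0)
        out = np.zeros_like(vol)
        m = sub["mask"]
        out[m] = num[m] / sub["norm"][m]
        return out

    # -- public pipeline ---------------------------------------------------

    def subject_maps(self, permutations: Sequence[np.ndarray] | None = None):
        """Smoothed subject maps; identity permutations give the true maps."""
        maps = []
        for i, sub in enumerate(self._subjects):
            Z = sub["Z"]
            if permutations is not None:
                Z = Z[permutations[i]]
            maps.append(self._smoothed_subject_map(sub, Z))
        return maps

    def group_map(self, permutations: Sequence[np.ndarray] | None = None):
        maps = self.subject_maps(permutations)
        gm = median_map(maps, smoothing_sd_mm=self.smoothing_sd_mm,
                        mask=self.group_mask)
        return gm

    def run_extremes(self, permutations) -> tuple[float, float]:
        gm = self.group_map(permutations).median_map[self.group_mask]
        return float(gm.max()), float(gm.min())

    def null_distribution(self, B: int, master_seed: int) -> NullDistribution:
        """B permutation runs; each run draws one independent uniform row
        permutation per subject, deterministic for a fixed master seed.

        Implemented subject-major and batched over runs (one GEMM per
        subject, 4-D batched smoothing); numerically identical to
        looping :meth:`run_extremes` over per-run permutations drawn in
        the same order.
        """
        if B < 1:
            raise ConfigurationError("B must be >= 1")
        rng = np.random.default_rng(master_seed)
        n = self.n
        S = len(self._subjects)
        perms = np.empty((B, S, n), dtype=np.int32)
        for b in range(B):
            for i in range(S):
                perms[b, i] = rng.permutation(n)
        gm_idx = self.group_mask
        Ce = self.contrast_events
        med_stack = np.empty((S, B, int(gm_idx.sum())))
        sigma_vox = [0.0] + [self.smoothing_sd_mm / v
                             for v in self.voxel_size_mm]
        for i, sub in enumerate(self._subjects):
            Z = np.asarray(sub["Z"], dtype=float)
            Zp = Z[perms[:, i]]                                # B x n x 4
            flat = Zp.transpose(1, 0, 2).reshape(n, B * 4)
            E = self.H @ flat
            E -= E.mean(axis=0, keepdims=True)
            E -= sub["Q0"] @ (sub["Q0"].T @ E)                 # residualised
            EtY = (E.T @ sub["Yr"]).reshape(B, 4, -1)          # B x 4 x V
            Er = E.reshape(n, B, 4)
            M = np.einsum("nbj,nbk->bjk", Er, Er)
            evals, evecs = np.linalg.eigh(M)
            se = np.sqrt(np.clip(evals, 0.0, None))
            keep = se > PINV_RTOL * np.maximum(se[:, -1:], 1.0)
            inv_s2 = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
            proj = np.matmul(evecs.transpose(0, 2, 1), EtY)    # B x 4 x V
            beta = np.matmul(evecs, inv_s2[:, :, None] * proj)
            vtc = np.einsum("bjk,j->bk", evecs, Ce)
            ctgc = np.einsum("bk,bk->b", vtc ** 2, inv_s2)
            df = n - 1 - (sub["rank0"] + keep.sum(axis=1))
            if np.any(df <= 0):
                raise ConfigurationError("non-positive df in permutation run")
            num = np.einsum("j,bjv->bv", Ce, beta)
            rss = sub["ytyr"][None, :] - np.einsum("bjv,bjv->bv", EtY, beta)
            sigma2 = rss / df[:, None]
            scale = np.sqrt(np.maximum(sigma2, 0.0) * ctgc[:, None])
            t = np.zeros_like(num)
            ok = scale > 0
            np.divide(num, scale, out=t, where=ok)
            vols = np.zeros((B,) + sub["mask"].shape)
            vols[:, sub["mask"]] = t
            if self.smoothing_sd_mm > 0:
                vols = ndimage.gaussian_filter(vols, sigma_vox,
                                               mode="constant", truncate=4.0)
                med_stack[i] = vols[:, gm_idx] / sub["norm"][gm_idx][None, :]
            else:
                med_stack[i] = vols[:, gm_idx]
        group = np.median(med_stack, axis=0)                   # B x Vg
        return NullDistribution(maxima=group.max(axis=1),
                                minima=group.min(axis=1),
                                master_seed=master_seed)


def null_distribution(cohort, B: int = 1000, master_seed: int = 0,
                      engine: PermutationEngine | None = None,
                      **pipeline_cfg) -> NullDistribution:
    """Functional wrapper: build the engine and draw B permutation runs."""
    if engine is None:
        engine = PermutationEngine(cohort, **pipeline_cfg)
    return engine.null_distribution(B, master_seed)


# ---------------------------------------------------------------------------
# thresholds, significance labels, clusters
# ---------------------------------------------------------------------------

def _order_index(B: int, alpha: float) -> int:
    """0-based ascending order-statistic index m such that exceedance
    beyond the (B - m)-th largest value has empirical probability
    strictly below alpha: m = ceil(alpha B) - 1."""
    m = math.ceil(alpha * B) - 1
    return min(max(m, 0), B - 1)


def compute_thresholds(null: NullDistribution,
                       alphas: Sequence[float] = DEFAULT_ALPHAS,
                       warn: bool = True) -> ThresholdSet:
    """Empirical FWER thresholds from the maxima/minima distributions.

    ``upper[a]`` is the smallest observed value t with
    #{maxima > t} / B < a; ``lower[a]`` is symmetric on the minima.
    """
    B = null.B
    if B < 1:
        raise ConfigurationError("empty null distribution")
    alphas = tuple(alphas)
    if warn and B < math.ceil(1.0 / min(alphas)):
        import warnings

        warnings.warn(
            f"B={B} permutations cannot resolve alpha={min(alphas)}: the "
            "empirical exceedance probability has resolution 1/B",
            stacklevel=2)
    mx = np.sort(null.maxima)
    mn = np.sort(null.minima)
    upper = {}
    lower = {}
    for a in alphas:
        m = _order_index(B, a)
        upper[a] = float(mx[B - 1 - m])
        lower[a] = float(mn[m])
    return ThresholdSet(upper=upper, lower=lower, alphas=alphas)


def threshold_map(group_map: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Signed tier labels: +-1, +-2, +-3 for the 0.05, 0.01, 0.001 tiers
    (the most stringent tier passed wins); 0 below all thresholds."""
    vol = np.asarray(group_map, dtype=float)
    labels = np.zeros(vol.shape, dtype=np.int8)
    for tier, a in enumerate(sorted(thresholds.alphas, reverse=True), start=1):
        labels[vol > thresholds.upper[a]] = tier
        labels[vol < thresholds.lower[a]] = -tier
    return labels


def extract_clusters(
    sig_image: np.ndarray,
    voxel_size_mm: Sequence[float],
    connectivity: int = 18,
    min_size_mm3: float = 100.0,
    stat_map: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> list[ClusterRecord]:
    """Connected suprathreshold clusters, per sign, strictly larger than
    ``min_size_mm3``.

    Components are found separately among positively and negatively
    labelled voxels (any tier); signs never merge.  The peak is the
    largest-|value| voxel of ``stat_map`` inside the cluster (tier labels
    are used when no statistic map is supplied).  Clusters are sorted by
    size, descending.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ConfigurationError("connectivity must be one of 6, 18, 26")
    sig = np.asarray(sig_image)
    values = np.asarray(stat_map, dtype=float) if stat_map is not None \
        else sig.astype(float)
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_RANK[connectivity])
    voxel_volume = float(np.prod(voxel_size_mm))
    records: list[ClusterRecord] = []
    for sign, selector in (("positive", sig > 0), ("negative", sig < 0)):
        labelled, n_comp = ndimage.label(selector, structure=structure)
        for comp in range(1, n_comp + 1):
            coords = np.argwhere(labelled == comp)
            size_mm3 = len(coords) * voxel_volume
            if size_mm3 <= min_size_mm3:
                continue
            vals = values[tuple(coords.T)]
            peak_i = int(np.argmax(np.abs(vals)))
            peak = tuple(int(c) for c in coords[peak_i])
            tier = int(abs(sig[peak]))
            peak_mm = None
            if affine is not None:
                hom = affine @ np.array([*peak, 1.0])
                peak_mm = tuple(float(x) for x in hom[:3])
            records.append(ClusterRecord(
                sign=sign, size_voxels=len(coords), size_mm3=size_mm3,
                peak_coord=peak, peak_value=float(vals[peak_i]),
                tier=tier, peak_mm=peak_mm, voxels=coords))
    records.sort(key=lambda r: r.size_mm3, reverse=True)
    return records
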