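"""Group-level machinery for contrast maps.

Covers the standard second-level steps around the first-level models:
precision-weighted combination of per-run contrast estimates, percent
signal change (PSC) scaling of estimates, Cohen's d conversion, a
site-stratified sign-flip max-cluster-size permutation test controlling
family-wise error, and subject-level outlier flagging.

Statistic maps use 6-connectivity (face-adjacent voxels) clustering in 3D.
The sign-flip null flips all subjects within a scanner site jointly — one
sign per site — preserving the multi-site grouping; with S sites there are
2^S possible flips (8192 for the 13-site case), enumerated exhaustively
when feasible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import HRFSpec, RegressorSpec, convolve_regressor

__all__ = [
    "StatMap",
    "Cluster",
    "GroupPermResult",
    "fixed_effects_combine",
    "psc_scale",
    "cohens_d",
    "extract_clusters",
    "sign_flip_cluster_test",
    "flag_outliers",
]


@dataclass
class StatMap:
    """A 3D statistic map with an in-mask validity mask and grid metadata."""

    values: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
        if self.affine is None:
            self.affine = np.eye(4)

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None) -> "StatMap":
        import nibabel as nib

        img = nib.load(path)
        return cls(values=np.asarray(img.get_fdata(), dtype=float), mask=mask,
                   affine=img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values, self.affine), path)


def fixed_effects_combine(
    estimates: np.ndarray, variances: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Precision-weighted (inverse-variance) combination across runs.

    ``estimate = sum(b_i / v_i) / sum(1 / v_i)``, ``variance = 1 / sum(1 / v_i)``.
    This is the minimum-variance linear unbiased combination.  Accepts
    scalars or arrays with runs along the first axis.
    """
    estimates = np.atleast_1d(np.asarray(estimates, dtype=float))
    variances = np.atleast_1d(np.asarray(variances, dtype=float))
    if estimates.shape != variances.shape:
        raise ValueError("estimates and variances must have matching shapes")
    if estimates.shape[0] < 1:
        raise ValueError("at least one run is required")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    precision = 1.0 / variances
    combined_var = 1.0 / precision.sum(axis=0)
    combined_est = (estimates * precision).sum(axis=0) * combined_var
    return combined_est, combined_var


def psc_scale(
    contrast_estimate: float | np.ndarray,
    mean_duration: float,
    hrf: HRFSpec = HRFSpec(),
    baseline: float = 100.0,
) -> float | np.ndarray:
    """Percent-signal-change scaling of a contrast estimate.

    The estimate is multiplied by the peak height of the HRF-convolved unit
    boxcar whose duration is the mean event duration for that stimulus type,
    then expressed as a percentage of ``baseline``.
    """
    if mean_duration <= 0:
        raise ValueError("mean_duration must be positive")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    # reference response sampled on the microtime grid: one isolated event
    pad = hrf.kernel_length + mean_duration
    frame_times = np.arange(0.0, pad, hrf.microtime_dt)
    spec = RegressorSpec("psc_reference", (0.0,), (mean_duration,))
    ref = convolve_regressor(spec, frame_times, hrf)
    peak = float(ref[:, 0].max())
    return contrast_estimate * peak * 100.0 / baseline


def cohens_d(t: float | np.ndarray, n: int) -> float | np.ndarray:
    """Cohen's d from a one-sample t statistic: d = t / sqrt(n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return t / np.sqrt(n)


@dataclass(frozen=True)
class Cluster:
    size: int
    peak_value: float
    voxels: tuple[tuple[int, int, int], ...]
    sign: int  # +1 or -1


_STRUCTURE_6 = ndimage.generate_binary_structure(3, 1)


def _clusters_one_sign(values: np.ndarray, supra: np.ndarray, sign: int) -> list[Cluster]:
    labels, n = ndimage.label(supra, structure=_STRUCTURE_6)
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = values[labels == lab]
        peak = vals.max() if sign > 0 else vals.min()
        out.append(Cluster(size=len(idx), peak_value=float(peak),
                           voxels=tuple(map(tuple, idx)), sign=sign))
    return out


def extract_clusters(
    stat_map: StatMap, threshold: float, two_sided: bool = True
) -> list[Cluster]:
    """Connected components of supra-threshold voxels (6-connectivity).

    With ``two_sided``, voxels above +threshold and below -threshold are
    clustered separately and both contribute to the result.
    """
    values = np.where(stat_map.mask, stat_map.values, 0.0)
    if not np.all(np.isfinite(values)):
        raise ValueError("statistic map contains non-finite values inside the mask")
    clusters = _clusters_one_sign(values, values > threshold, +1)
    if two_sided:
        clusters += _clusters_one_sign(values, values < -threshold, -1)
    return sorted(clusters, key=lambda c: -c.size)


def _max_cluster_size(values: np.ndarray, mask: np.ndarray, threshold: float) -> int:
    values = np.where(mask, values, 0.0)
    best = 0
    for supra in (values > threshold, values < -threshold):
        labels, n = ndimage.label(supra, structure=_STRUCTURE_6)
        if n:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


@dataclass
class GroupPermResult:
    """Result of the site-stratified sign-flip cluster permutation test."""

    t_map: StatMap
    null_max_cluster_sizes: np.ndarray
    cluster_size_threshold: int
    significant_clusters: list[Cluster]
    n_permutations: int
    exhaustive: bool

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {"size": c.size, "peak_t": c.peak_value, "sign": c.sign}
            for c in self.significant_clusters
        ]
        return pd.DataFrame(rows, columns=["size", "peak_t", "sign"])


def _one_sample_t(
    flipped_site_sums: np.ndarray, sum_sq: np.ndarray, n: int
) -> np.ndarray:
    """t statistics from per-site sums under a sign flip.

    Sign flips leave each subject's squared values unchanged, so only the
    mean depends on the flip: sum(x^2) is reused across permutations.
    """
    mean = flipped_site_sums / n
    var = (sum_sq - n * mean**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def sign_flip_cluster_test(
    subject_maps: list[StatMap] | np.ndarray,
    site_labels,
    cf_threshold: float = 3.1,
    alpha: float = 0.05,
    max_perms: int = 10_000,
    seed: int = 0,
) -> GroupPermResult:
    """One-sample group t-test with site-stratified sign-flip cluster FWER.

    The null distribution of the maximum cluster size (positive and negative
    clusters pooled per flip) is built by jointly flipping the sign of all
    subjects within a scanner site.  All ``2^S`` flips are enumerated when
    that is at most ``max_perms``; otherwise a seeded Monte-Carlo subset is
    used (always containing the identity flip).  Significant clusters are
    the observed clusters whose size reaches the smallest integer k with
    ``P(null >= k) <= alpha``.
    """
    if isinstance(subject_maps, np.ndarray):
        data = np.asarray(subject_maps, dtype=float)
        mask = np.ones(data.shape[1:], dtype=bool)
    else:
        shapes = {m.values.shape for m in subject_maps}
        if len(shapes) != 1:
            raise ValueError("subject maps must share a common grid")
        data = np.stack([m.values for m in subject_maps])
        mask = np.logical_and.reduce([m.mask for m in subject_maps])
    n = data.shape[0]
    site_labels = np.asarray(site_labels)
    if site_labels.shape != (n,):
        raise ValueError("site_labels must have one entry per subject")
    sites = np.unique(site_labels)
    n_sites = len(sites)
    if n_sites < 2:
        raise ValueError("at least two sites are required for the stratified flip")

    shape = data.shape[1:]
    flat = data.reshape(n, -1)
    # exclude voxels with zero variance across subjects
    var_ok = flat.std(axis=0) > 0
    mask = mask & var_ok.reshape(shape)
    flat = np.where(mask.ravel(), flat, 0.0)

    site_sums = np.stack([flat[site_labels == s].sum(axis=0) for s in sites])
    sum_sq = (flat**2).sum(axis=0)

    n_all = 2**n_sites
    if n_all <= max_perms:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_sites)))
        # put the identity flip first
        signs = np.vstack([np.ones(n_sites), signs[~np.all(signs == 1.0, axis=1)]])
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(max_perms - 1, n_sites))
        signs = np.vstack([np.ones(n_sites), signs])
        exhaustive = False
    n_perms = signs.shape[0]

    null_sizes = np.empty(n_perms, dtype=int)
    t_obs = None
    for i, s in enumerate(signs):
        t = _one_sample_t(s @ site_sums, sum_sq, n).reshape(shape)
        if i == 0:
            t_obs = t
        null_sizes[i] = _max_cluster_size(t, mask, cf_threshold)

    # ceiling rule: smallest integer size whose null exceedance is <= alpha
    candidates = np.arange(1, null_sizes.max() + 2)
    exceed = np.array([(null_sizes >= k).mean() for k in candidates])
    threshold = int(candidates[np.argmax(exceed <= alpha)]) if np.any(exceed <= alpha) \
        else int(null_sizes.max() + 1)

    t_map = StatMap(values=np.where(mask, t_obs, 0.0), mask=mask)
    observed = extract_clusters(t_map, cf_threshold, two_sided=True)
    significant = [c for c in observed if c.size >= threshold]
    return GroupPermResult(
        t_map=t_map,
        null_max_cluster_sizes=null_sizes,
        cluster_size_threshold=threshold,
        significant_clusters=significant,
        n_permutations=n_perms,
        exhaustive=exhaustive,
    )


def flag_outliers(
    subject_maps: list[StatMap] | np.ndarray,
    k: float = 2.0,
    voxel_fraction_threshold: float = 0.1,
) -> np.ndarray:
    """Flag subjects whose contrast map is extreme across many voxels.

    A voxel marks a subject when ``|estimate - mean| > k * SD`` (mean and SD
    across subjects); a subject is flagged when the marked fraction of
    in-mask voxels exceeds ``voxel_fraction_threshold``.  Voxels with zero
    SD mark nobody.  Conventional choices are k = 2 or 3.
    """
    if isinstance(subject_maps, np.ndarray):
        data = np.asarray(subject_maps, dtype=float)
        mask = np.ones(data.shape[1:], dtype=bool)
    else:
        data = np.stack([m.values for m in subject_maps])
        mask = np.logical_and.reduce([m.mask for m in subject_maps])
    n = data.shape[0]
    if n < 3:
        raise ValueError("outlier flagging requires at least 3 subjects")
    flat = data.reshape(n, -1)[:, mask.ravel()]
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        marked = np.abs(flat - mean) > k * sd
    marked[:, sd == 0] = False
    fraction = marked.mean(axis=1)
    return fraction > voxel_fraction_threshold
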