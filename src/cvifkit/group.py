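"""Group-level one-sample inference with site-stratified sign flipping.

Subject-level contrast maps are combined across runs by precision
weighting, tested voxelwise with a one-sample t statistic, and assessed
for significance with a cluster-extent permutation test: under the null of
symmetric errors, the signs of whole subjects may be flipped, and to
preserve the multi-site structure of the data all subjects scanned at the
same site are flipped jointly.  With ``k`` sites there are ``2^k``
stratified sign assignments (8192 for 13 sites); all are enumerated when
feasible, otherwise a uniform sample is drawn.  For each assignment the
maximum suprathreshold cluster size is recorded (|t| above the
cluster-forming threshold, default 3.1, positive and negative excursions
labeled separately with face-adjacent 6-connectivity and pooled into one
maximum).  Observed clusters larger than the 95th percentile of this null
distribution are significant, controlling the family-wise error rate at
0.05.  For display, t maps convert to Cohen's d via ``d = t / sqrt(n)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ClusterTestResult",
    "fixed_effects_combine",
    "one_sample_tmap",
    "cohens_d",
    "cluster_permutation_test",
    "load_map",
    "save_map",
]


def load_map(path) -> np.ndarray:
    """Read a 3D volume from a NIfTI file."""
    import nibabel as nib

    return np.asanyarray(nib.load(str(path)).dataobj, dtype=float)


def save_map(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3D volume to NIfTI (identity affine by default)."""
    import nibabel as nib

    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))

#: Face-adjacency structuring element (6-connectivity in 3D).
_STRUCT_3D = ndimage.generate_binary_structure(3, 1)


def fixed_effects_combine(
    estimates: list[np.ndarray], variances: list[np.ndarray]
) -> np.ndarray:
    """Precision-weighted (inverse-variance) average of per-run estimates."""
    if not estimates or len(estimates) != len(variances):
        raise ValueError("need matching, non-empty estimate and variance lists")
    est = np.stack([np.asarray(e, dtype=float) for e in estimates])
    var = np.stack([np.asarray(v, dtype=float) for v in variances])
    if np.any(var <= 0):
        raise ValueError("run variances must be strictly positive")
    weights = 1.0 / var
    return (weights * est).sum(axis=0) / weights.sum(axis=0)


def one_sample_tmap(maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t statistic of subject maps against zero.

    ``maps`` is (n_subjects, ...spatial).  Voxels with zero sample
    variance but nonzero mean give an unbounded t, reported as the largest
    finite float with a warning.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("one-sample t requires at least 2 subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    big = np.finfo(float).max
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & (mean != 0)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} voxel(s) have zero variance; "
            "their t statistics are unbounded and clipped to +/-max-float",
            RuntimeWarning,
            stacklevel=2,
        )
        t[degenerate] = np.sign(mean[degenerate]) * big
    t[(sd == 0) & (mean == 0)] = 0.0
    return t


def cohens_d(t_map: np.ndarray, n: int) -> np.ndarray:
    """One-sample effect size ``d = t / sqrt(n)``, elementwise."""
    if n < 2:
        raise ValueError("n must be at least 2")
    return np.asarray(t_map, dtype=float) / np.sqrt(n)


def _max_cluster_size(t: np.ndarray, thresh: float, structure: np.ndarray) -> int:
    largest = 0
    for sign in (1, -1):
        labels, n_lab = ndimage.label(sign * t > thresh, structure=structure)
        if n_lab:
            largest = max(largest, int(np.bincount(labels.ravel())[1:].max()))
    return largest


@dataclass
class ClusterTestResult:
    """Outcome of the stratified sign-flip cluster-extent test."""

    t_map: np.ndarray
    d_map: np.ndarray
    t_thresh: float
    null_max_sizes: np.ndarray
    size_threshold: float
    cluster_labels: np.ndarray      # labeled map of all suprathreshold clusters
    cluster_table: pd.DataFrame     # label, size, sign, peak t, peak index, significant
    n_permutations: int
    exhaustive: bool
    significant_labels: list[int] = field(default_factory=list)

    @property
    def significant_mask(self) -> np.ndarray:
        return np.isin(self.cluster_labels, self.significant_labels)


def _site_sign_matrix(sites: np.ndarray, max_perms: int, rng):
    """Subject-level sign rows for stratified flips; identity included."""
    site_labels, site_idx = np.unique(sites, return_inverse=True)
    k = len(site_labels)
    if 2**k <= max_perms:
        site_signs = np.array(
            [[1 - 2 * ((m >> b) & 1) for b in range(k)] for m in range(2**k)]
        )
        exhaustive = True
    else:
        site_signs = 1 - 2 * rng.integers(0, 2, size=(max_perms, k))
        site_signs[0] = 1  # keep the identity in the null distribution
        exhaustive = False
    return site_signs[:, site_idx], site_signs.shape[0], exhaustive


def cluster_permutation_test(
    maps: np.ndarray,
    sites,
    t_thresh: float = 3.1,
    alpha: float = 0.05,
    max_perms: int = 10000,
    rng=None,
    structure: np.ndarray | None = None,
) -> ClusterTestResult:
    """Site-stratified sign-flip maximum-cluster-size permutation test.

    Parameters
    ----------
    maps : (n_subjects, nx, ny, nz) array
        Per-subject combined contrast maps.
    sites : sequence of length n_subjects
        Scanner-site label per subject; all subjects of a site flip
        together.
    t_thresh : float
        Two-sided cluster-forming threshold on the t map.
    max_perms : int
        Enumerate all ``2^n_sites`` assignments when that is <= max_perms,
        otherwise draw this many uniform assignments (identity included).
    """
    maps = np.asarray(maps, dtype=float)
    sites = np.asarray(sites)
    n = maps.shape[0]
    if sites.shape[0] != n:
        raise ValueError("need one site label per subject")
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, nx, ny, nz)")
    if structure is None:
        structure = _STRUCT_3D
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    signs, n_perms, exhaustive = _site_sign_matrix(sites, max_perms, rng)

    flat = maps.reshape(n, -1)
    ssq = (flat**2).sum(axis=0)  # invariant under sign flips
    sqrt_n = np.sqrt(n)
    null_max = np.empty(n_perms, dtype=int)
    for p in range(n_perms):
        m = signs[p] @ flat / n
        var = (ssq - n * m**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, m / np.sqrt(var) * sqrt_n, 0.0)
        null_max[p] = _max_cluster_size(t.reshape(maps.shape[1:]), t_thresh, structure)

    size_threshold = float(np.percentile(null_max, 100 * (1 - alpha)))

    t_map = one_sample_tmap(maps)
    pos, n_pos = ndimage.label(t_map > t_thresh, structure=structure)
    neg, n_neg = ndimage.label(t_map < -t_thresh, structure=structure)
    labels = pos.astype(int)
    labels[neg > 0] = neg[neg > 0] + n_pos
    rows = []
    significant = []
    for lab in range(1, n_pos + n_neg + 1):
        mask = labels == lab
        size = int(mask.sum())
        t_vals = t_map[mask]
        peak_flat = np.abs(np.where(mask, t_map, 0)).argmax()
        sig = size > size_threshold
        if sig:
            significant.append(lab)
        rows.append(
            {
                "label": lab,
                "size": size,
                "sign": "positive" if lab <= n_pos else "negative",
                "peak_t": float(t_vals[np.abs(t_vals).argmax()]),
                "peak_index": tuple(int(i) for i in np.unravel_index(peak_flat, t_map.shape)),
                "significant": sig,
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "size", "sign", "peak_t", "peak_index", "significant"]
    )
    return ClusterTestResult(
        t_map=t_map,
        d_map=cohens_d(t_map, n),
        t_thresh=t_thresh,
        null_max_sizes=null_max,
        size_threshold=size_threshold,
        cluster_labels=labels,
        cluster_table=table,
        n_permutations=n_perms,
        exhaustive=exhaustive,
        significant_labels=significant,
    )
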