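"""Loop-centred reactivity-profile alignment, PCA, and K-means.

Transcripts are aligned on the centre of their central hairpin loop;
the 60 flanking positions (-30..-1, +1..+30, centre nucleotide
excluded) form the feature matrix.  PCA (mean-centred, not
variance-scaled) reduces to two components and K-means (K = 3, Lloyd,
10 restarts) groups the profiles.  Cluster labels are renumbered by
descending cluster size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLANK = 30
ALIGN_COLUMNS = tuple(list(range(-FLANK, 0)) + list(range(1, FLANK + 1)))
MAX_NULL_FRACTION = 0.5
DEFAULT_K = 3
KMEANS_RESTARTS = 10


def align_profiles(profiles, structures, impute: str = "transcript_mean"
                   ) -> pd.DataFrame:
    """Build the loop-centred 60-column score matrix.

    ``profiles``/``structures`` are matched lists (ReactivityProfile-like
    objects with ``transcript`` and ``scores``, and SecondaryStructure).
    Columns beyond a transcript's ends are null; nulls are imputed by
    the transcript's mean non-null score (``impute='zero'`` or
    ``'column_mean'`` select the alternatives).  Transcripts with more
    than 50% null columns, or no hairpin loop, are dropped and logged.
    """
    if len(profiles) != len(structures):
        raise ValueError("profiles and structures must be matched lists")
    rows, names = [], []
    raw_rows = []
    for profile, structure in zip(profiles, structures):
        name = getattr(profile, "transcript", f"tx_{len(names) + 1}")
        try:
            center = structure.central_loop_center()
        except ValueError:
            logger.info("transcript %s dropped: no hairpin loop", name)
            continue
        scores = profile.scores if hasattr(profile, "scores") \
            else np.asarray(profile, float)
        n = len(scores)
        row = np.full(len(ALIGN_COLUMNS), np.nan)
        for c, offset in enumerate(ALIGN_COLUMNS):
            pos = center + offset  # 1-based transcript coordinate
            if 1 <= pos <= n:
                row[c] = scores[pos - 1]
        null_frac = np.mean(~np.isfinite(row))
        if null_frac > MAX_NULL_FRACTION:
            logger.info("transcript %s dropped: %.0f%% null columns",
                        name, 100 * null_frac)
            continue
        raw_rows.append(row)
        names.append(name)

    if not raw_rows:
        raise ValueError("no transcripts with a usable aligned profile")
    matrix = np.vstack(raw_rows)
    if impute == "transcript_mean":
        for r in range(matrix.shape[0]):
            mask = ~np.isfinite(matrix[r])
            if mask.any():
                matrix[r, mask] = np.nanmean(matrix[r])
    elif impute == "zero":
        matrix[~np.isfinite(matrix)] = 0.0
    elif impute == "column_mean":
        col_means = np.nanmean(matrix, axis=0)
        idx = np.where(~np.isfinite(matrix))
        matrix[idx] = col_means[idx[1]]
    else:
        raise ValueError(f"unknown imputation {impute!r}")
    return pd.DataFrame(matrix, index=names, columns=list(ALIGN_COLUMNS))


def pca_project(matrix: pd.DataFrame):
    """Mean-centred PCA to 2 components.

    Returns ``(coords, loadings, explained)``: per-row 2D coordinates,
    per-position loadings with unit norm per component (sign convention:
    each component's largest-magnitude entry is positive), and explained
    variance fractions.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("matrix has zero total variance")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for c in range(loadings.shape[0]):
        if loadings[c, np.argmax(np.abs(loadings[c]))] < 0:
            loadings[c] *= -1
            coords[:, c] *= -1
    return coords, loadings, pca.explained_variance_ratio_.copy()


def kmeans_cluster(coords, k: int = DEFAULT_K, seed: int = 0) -> np.ndarray:
    """K-means labels in 1..k, renumbered by descending cluster size."""
    import warnings

    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows {coords.shape[0]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate duplicate-point inputs
        km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed,
                    algorithm="lloyd")
        raw = km.fit_predict(coords)
    sizes = np.bincount(raw, minlength=k)
    if np.any(sizes == 0):
        logger.warning("degenerate clustering: %d empty cluster(s)",
                       int(np.sum(sizes == 0)))
    # stable renumber: by size desc, ties by original label
    order = sorted(range(k), key=lambda lab: (-sizes[lab], lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[lab] for lab in raw])


def cluster_profiles(profiles, structures, k: int = DEFAULT_K,
                     seed: int = 0, impute: str = "transcript_mean"):
    """align -> PCA -> K-means pipeline; returns a result table + loadings.

    The table has one row per retained transcript with its 2D
    coordinates and cluster label; ``loadings`` and ``explained`` come
    from :func:`pca_project`.
    """
    matrix = align_profiles(profiles, structures, impute=impute)
    coords, loadings, explained = pca_project(matrix)
    labels = kmeans_cluster(coords, k=k, seed=seed)
    table = pd.DataFrame({
        "transcript": matrix.index,
        "pc1": coords[:, 0],
        "pc2": coords[:, 1],
        "cluster": labels,
    })
    loadings_df = pd.DataFrame(loadings.T, index=matrix.columns,
                               columns=["pc1", "pc2"])
    return table, loadings_df, explained, matrix
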