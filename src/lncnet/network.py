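"""Weighted co-expression network construction and module analysis.

The network is unsigned: adjacency A_ij = |cor_ij|^beta with the soft
threshold beta chosen as the smallest power whose connectivity
distribution fits a scale-free topology (signed R^2 >= target) while
keeping the mean connectivity above a floor.  Topological overlap

    TOM_ij = (l_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij),
    l_ij = sum_{u != i,j} A_iu A_uj,   k_i = sum_{u != i} A_iu,

is clustered (average linkage on 1 - TOM, static height cut) into
modules; module eigengenes are first principal components, correlated
against the binary trait to select the trait-associated module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_POWERS = tuple(range(1, 16))  # candidate soft thresholds, capped at 15


# ---------------------------------------------------------------------------
# sample QC

def detect_outlier_samples(
    X: pd.DataFrame,
    cut_height: Optional[float] = None,
    min_cluster: int = 2,
) -> list[str]:
    """Flag outlier samples by average-linkage clustering of sample profiles.

    *X* is transcripts x samples.  The sample dendrogram (Euclidean
    distance) is cut at *cut_height*; samples falling in clusters of
    size < *min_cluster* are flagged.  When *cut_height* is None a
    robust default (median merge height + 5 MAD) is used, so a clean
    dataset flags nothing.
    """
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if cut_height is not None and cut_height <= 0:
        raise ValueError("cut_height must be positive")
    profiles = X.to_numpy(dtype=float).T
    Z = linkage(profiles, method="average", metric="euclidean")
    heights = Z[:, 2]
    if cut_height is None:
        med = float(np.median(heights))
        mad = float(np.median(np.abs(heights - med)))
        cut_height = med + 5.0 * mad
        if heights.max() <= cut_height or heights.max() == 0.0:
            return []
    labels = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    flagged = [
        s for s, lab in zip(X.columns, labels) if sizes[lab] < min_cluster
    ]
    return flagged


# ---------------------------------------------------------------------------
# soft threshold

@dataclass
class SoftThresholdScan:
    powers: list[int]
    scale_free_r2: list[float]  # signed R^2 per power
    mean_connectivity: list[float]
    chosen_power: int
    satisfied: bool  # False when no power met the selection rule

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "signed_r2": self.scale_free_r2,
                "mean_k": self.mean_connectivity,
                "chosen": [p == self.chosen_power for p in self.powers],
            }
        )


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.all():
        raise ValueError("all transcripts have zero variance")
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} zero-variance transcripts "
            "before network construction"
        )
        X = X.loc[~constant]
    return X


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit index of a connectivity vector.

    Connectivities are binned into *n_bins* equal-count bins; the log10
    count density per bin is regressed on the log10 mean connectivity.
    Returns R^2 * sign(-slope); degenerate inputs (fewer than 3 usable
    bins) give -inf.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.allclose(k, k[0]):
        return float("-inf")
    quantiles = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles)
    if edges.size < 4:
        return float("-inf")
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    xs, ys = [], []
    total = k.size
    for b in range(edges.size - 1):
        mask = which == b
        count = int(mask.sum())
        width = edges[b + 1] - edges[b]
        if count == 0 or width <= 0:
            continue
        mean_k = k[mask].mean()
        density = count / (total * width)
        if mean_k > 0 and density > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(density))
    if len(xs) < 3:
        return float("-inf")
    slope, _inter, r, _p, _se = stats.linregress(xs, ys)
    return float(r * r * np.sign(-slope))


def pick_soft_threshold(
    X: pd.DataFrame,
    candidates: Sequence[int] = DEFAULT_POWERS,
    r2_target: float = 0.8,
    min_mean_k: Optional[float] = None,
) -> SoftThresholdScan:
    """Scan candidate powers and pick the smallest satisfying the rule.

    For each beta the unsigned adjacency |cor|^beta is formed, the
    connectivity k_i = sum_{j != i} A_ij computed, and the signed
    scale-free fit R^2 evaluated.  Chosen: the smallest beta with signed
    R^2 >= r2_target and mean(k) >= min_mean_k; if none qualifies the
    beta maximizing signed R^2 is reported with ``satisfied=False``.
    ``min_mean_k`` defaults to 1% of the transcript count.
    """
    if X.shape[0] < 20:
        raise ValueError("need at least 20 transcripts")
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    X = _drop_constant(X)
    if min_mean_k is None:
        min_mean_k = 0.005 * X.shape[0]
    candidates = sorted(int(b) for b in candidates)
    if candidates[0] < 1:
        raise ValueError("powers must be >= 1")

    abs_cor = np.abs(np.corrcoef(X.to_numpy(dtype=float)))
    np.fill_diagonal(abs_cor, 0.0)

    r2s, mean_ks = [], []
    for beta in candidates:
        A = abs_cor**beta
        k = A.sum(axis=1)
        r2s.append(scale_free_fit(k))
        mean_ks.append(float(k.mean()))

    chosen, satisfied = None, False
    for beta, r2, mk in zip(candidates, r2s, mean_ks):
        if r2 >= r2_target and mk >= min_mean_k:
            chosen, satisfied = beta, True
            break
    if chosen is None:
        finite = [(b, r2) for b, r2 in zip(candidates, r2s) if np.isfinite(r2)]
        if finite:
            best = max(r2 for _b, r2 in finite)
            # smallest power close to the best fit, to avoid runaway powers
            chosen = min(b for b, r2 in finite if r2 >= 0.95 * best)
        else:
            chosen = candidates[0]
        warnings.warn(
            "no candidate power met the scale-free criterion; "
            f"falling back to power {chosen} (near-best signed R^2)"
        )
    return SoftThresholdScan(candidates, r2s, mean_ks, chosen, satisfied)


# ---------------------------------------------------------------------------
# adjacency / TOM

def correlation_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between transcript profiles (rows of X)."""
    X = _drop_constant(X)
    corr = np.corrcoef(X.to_numpy(dtype=float))
    return pd.DataFrame(corr, index=X.index, columns=X.index)


def adjacency(corr: pd.DataFrame | np.ndarray, beta: int) -> np.ndarray:
    """Unsigned adjacency |corr|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    C = np.asarray(corr, dtype=float)
    if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(C)) > 1 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    A = np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a valid adjacency (unit diagonal)."""
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (A < -1e-12).any() or (A > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    # l_ij over u != i, j; with unit diagonal (A @ A)_ij counts u = i and u = j
    L = A @ A - 2.0 * A * 1.0
    k = A.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def tom_from_expression(X: pd.DataFrame, beta: int) -> pd.DataFrame:
    corr = correlation_matrix(X)
    tom = tom_similarity(adjacency(corr.to_numpy(), beta))
    return pd.DataFrame(tom, index=corr.index, columns=corr.columns)


# ---------------------------------------------------------------------------
# modules

def detect_modules(
    tom: pd.DataFrame | np.ndarray,
    min_module_size: int = 20,
    cut_height: Optional[float] = None,
    ids: Optional[Sequence[str]] = None,
    cut_fraction: float = 0.92,
) -> pd.Series:
    """Cluster 1 - TOM (average linkage, static cut) into modules.

    Clusters of size >= *min_module_size* become modules numbered 1, 2,
    ... by decreasing size; everything else is labeled 0 (unassigned).
    When *cut_height* is None the cut adapts to the dendrogram scale
    (92% of the maximum merge height), mirroring common practice of
    cutting just below the top of the tree.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if isinstance(tom, pd.DataFrame):
        ids = list(tom.index)
        tom = tom.to_numpy(dtype=float)
    elif ids is None:
        ids = [str(i) for i in range(tom.shape[0])]
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dissim, checks=False), method="average")
    if cut_height is None:
        cut_height = cut_fraction * float(Z[:, 2].max())
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].sort_values(ascending=False)
    remap = {lab: i + 1 for i, lab in enumerate(keep.index)}
    labels = np.array([remap.get(lab, 0) for lab in raw])
    return pd.Series(labels, index=ids, name="module")


def module_eigengene(X_module: pd.DataFrame) -> np.ndarray:
    """First principal component of the z-scored module submatrix.

    *X_module* is transcripts x samples with >= 1 transcript.  The
    eigengene is scaled to unit variance and oriented so that its
    correlation with the mean standardized expression is non-negative.
    A single-transcript module returns that transcript's z-score.
    """
    mat = X_module.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 1:
        raise ValueError("module must contain at least one transcript")
    sd = mat.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    zs = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    if mat.shape[0] == 1:
        return zs[0]
    _u, _s, vt = np.linalg.svd(zs, full_matrices=False)
    eig = vt[0]
    eig_sd = eig.std(ddof=0)
    if eig_sd > 0:
        eig = (eig - eig.mean()) / eig_sd
    mean_profile = zs.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    return eig


def module_eigengenes(X: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Eigengene per module (samples x modules); module 0 is skipped."""
    mods = sorted(m for m in labels.unique() if m != 0)
    data = {
        m: module_eigengene(X.loc[labels.index[labels == m]]) for m in mods
    }
    return pd.DataFrame(data, index=X.columns)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided Student-t p-value for a Pearson correlation."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait: Sequence[int]
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with the binary trait."""
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.all(trait == trait[0]):
        raise ValueError("trait is constant")
    rows = []
    for m in eigengenes.columns:
        r = float(np.corrcoef(eigengenes[m].to_numpy(), trait)[0, 1])
        rows.append((m, r, correlation_pvalue(r, n)))
    return pd.DataFrame(rows, columns=["module", "r", "pvalue"]).set_index("module")


def module_membership_gene_significance(
    X: pd.DataFrame,
    labels: pd.Series,
    eigengenes: pd.DataFrame,
    trait: Sequence[int],
) -> pd.DataFrame:
    """MM = cor(transcript, own-module eigengene); GS = |cor(transcript, trait)|.

    Unassigned transcripts (module 0) get NaN module membership.
    """
    trait = np.asarray(trait, dtype=float)
    rows = []
    for tid in X.index:
        profile = X.loc[tid].to_numpy(dtype=float)
        gs = abs(float(np.corrcoef(profile, trait)[0, 1]))
        m = labels.loc[tid]
        mm = (
            float(np.corrcoef(profile, eigengenes[m].to_numpy())[0, 1])
            if m != 0
            else np.nan
        )
        rows.append((tid, m, mm, gs))
    return pd.DataFrame(
        rows, columns=["transcript_id", "module", "mm", "gs"]
    ).set_index("transcript_id")


# ---------------------------------------------------------------------------
# per-group driver

@dataclass
class NetworkResult:
    group: str
    power: int
    scan: SoftThresholdScan
    labels: pd.Series  # transcript -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    module_trait: pd.DataFrame  # module -> (r, pvalue, size)
    selected_module: int
    module_tom: pd.DataFrame = field(repr=False, default=None)

    @property
    def selected_transcripts(self) -> list[str]:
        return list(self.labels.index[self.labels == self.selected_module])


def analyze_group(
    X: pd.DataFrame,
    trait: Sequence[int],
    group: str = "group",
    powers: Sequence[int] = DEFAULT_POWERS,
    r2_target: float = 0.8,
    min_mean_k: Optional[float] = None,
    min_module_size: int = 20,
    cut_height: Optional[float] = None,
) -> NetworkResult:
    """Full per-group analysis: power selection, TOM, modules, eigengenes,
    module-trait correlation, trait-module selection, and the TOM
    submatrix of the selected module."""
    X = _drop_constant(X)
    scan = pick_soft_threshold(X, powers, r2_target, min_mean_k)
    tom = tom_from_expression(X, scan.chosen_power)
    if cut_height is not None:
        labels = detect_modules(tom, min_module_size, cut_height)
    else:
        # adaptive: cut just below the top of the tree, raising the cut
        # until at least one module forms
        for frac in (0.92, 0.95, 0.97, 0.985):
            labels = detect_modules(tom, min_module_size, cut_fraction=frac)
            if (labels > 0).any():
                break
    if (labels == 0).all():
        raise ValueError(
            f"{group}: no module of size >= {min_module_size} detected; "
            "lower min_module_size or raise cut_height"
        )
    eig = module_eigengenes(X, labels)
    mt = module_trait_correlation(eig, trait)
    mt["size"] = [int((labels == m).sum()) for m in mt.index]
    selected = int(mt["r"].abs().idxmax())
    members = labels.index[labels == selected]
    return NetworkResult(
        group=group,
        power=scan.chosen_power,
        scan=scan,
        labels=labels,
        eigengenes=eig,
        module_trait=mt,
        selected_module=selected,
        module_tom=tom.loc[members, members],
    )
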