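"""Group statistics for the four-arm OIR design.

Two statistical chains are provided:

* **SMIA chain** — z-scored feature matrix → PCA → one-way MANOVA
  (Wilks' Λ with Rao's F approximation) → pairwise Mahalanobis
  distances between group centroids computed from the pooled
  within-group covariance → single-linkage (nearest-neighbour)
  agglomerative clustering of the group distance matrix, reported
  both pairwise and relative to control.

* **Scalar chain** — one-way fixed-effects ANOVA with Tukey's HSD
  post hoc for per-retina scalars (obliteration %, tuft %,
  haemorrhage counts) and per-layer TUNEL profile frequencies
  (per-animal frequency = Σcounts / Σsection length, animals with
  fewer than three sections excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

CANONICAL_GROUP_ORDER = ("control", "r670", "oir", "r670_oir")


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to treatment groups."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must be parallel lists")
        if len(set(self.groups)) < 2:
            raise ValueError("need at least two groups")

    @classmethod
    def from_lists(cls, sample_ids: Sequence[str], groups: Sequence[str]):
        return cls(tuple(sample_ids), tuple(groups))

    @property
    def group_names(self) -> list[str]:
        present = set(self.groups)
        ordered = [g for g in CANONICAL_GROUP_ORDER if g in present]
        ordered += sorted(present - set(CANONICAL_GROUP_ORDER))
        return ordered

    def indices(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group])


@dataclass
class Dendrogram:
    """Single-linkage merge list: (left labels, right labels, height)."""

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]
    labels: tuple[str, ...]

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def last_singleton(self) -> str | None:
        """Label merged alone in the final merge, if any ("clusters alone")."""
        left, right, _ = self.merges[-1]
        if len(left) == 1:
            return left[0]
        if len(right) == 1:
            return right[0]
        return None

    def to_newick(self) -> str:
        node: dict[tuple[str, ...], str] = {(l,): l for l in self.labels}
        height: dict[tuple[str, ...], float] = {(l,): 0.0 for l in self.labels}
        for left, right, h in self.merges:
            bl = h - height[left]
            br = h - height[right]
            merged = tuple(sorted(left + right))
            node[merged] = f"({node[left]}:{bl:.6g},{node[right]}:{br:.6g})"
            height[merged] = h
        return node[tuple(sorted(self.labels))] + ";"


@dataclass
class MahalanobisClustering:
    """MANOVA / Mahalanobis / single-linkage summary of the SMIA chain."""

    pc_scores: np.ndarray
    group_names: list[str]
    distance_matrix: np.ndarray
    distances_to_control: dict[str, float]
    dendrogram: Dendrogram
    wilks_lambda: float
    F: float
    p_value: float
    df: tuple[float, float]


def pca_scores(
    X: np.ndarray, m: int, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Top-m principal-component scores and explained-variance ratios.

    Columns are centred (and z-scored by default, because SMIA areas,
    perimeters and Euler numbers live on incommensurate scales). The
    sign of each component is fixed so its largest-magnitude loading is
    positive. If the data rank is below m, m is reduced with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a samples × features matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    n, p = X.shape
    if not (1 <= m <= p):
        raise ValueError("need 1 <= m <= n_features")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max() * max(n, p) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if rank < m:
        warnings.warn(f"data rank {rank} below requested m={m}; reducing",
                      stacklevel=2)
        m = max(rank, 1)
    # deterministic sign: largest-|loading| entry of each PC positive
    for j in range(m):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :m] * S[:m]
    var = S**2 / max(n - 1, 1)
    explained = var / var.sum() if var.sum() > 0 else var
    return scores, explained[:m]


def choose_n_components(
    X: np.ndarray, design: GroupDesign, var_target: float = 0.90
) -> int:
    """Smallest m explaining >= var_target variance, capped at n − k − 1."""
    _, explained_all = pca_scores(X, m=min(X.shape), standardize=True)
    cum = np.cumsum(explained_all)
    m = int(np.searchsorted(cum, var_target) + 1)
    cap = len(design.sample_ids) - len(design.group_names) - 1
    return max(1, min(m, cap, X.shape[1]))


def _pooled_within_cov(scores: np.ndarray, design: GroupDesign) -> np.ndarray:
    n, p = scores.shape
    k = len(design.group_names)
    E = np.zeros((p, p))
    for g in design.group_names:
        idx = design.indices(g)
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        xg = scores[idx]
        d = xg - xg.mean(axis=0)
        E += d.T @ d
    return E / (n - k)


def manova_mahalanobis(
    scores: np.ndarray, design: GroupDesign
) -> MahalanobisClustering:
    """MANOVA + pairwise Mahalanobis distances + single-linkage tree.

    D(g, h) = sqrt((x̄_g − x̄_h)ᵀ W⁻¹ (x̄_g − x̄_h)) with W the pooled
    within-group covariance (the MANOVA error SSCP divided by its
    degrees of freedom). Wilks' Λ = det(E)/det(E + H) with Rao's F
    approximation. A singular W falls back to the pseudo-inverse with
    a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n, p = scores.shape
    if n != len(design.sample_ids):
        raise ValueError("scores rows and design length differ")
    groups = design.group_names
    k = len(groups)
    W = _pooled_within_cov(scores, design)
    try:
        Winv = np.linalg.inv(W)
        cond = np.linalg.cond(W)
        if cond > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; using pseudo-inverse",
                      stacklevel=2)
        Winv = np.linalg.pinv(W)

    means = {g: scores[design.indices(g)].mean(axis=0) for g in groups}
    D = np.zeros((k, k))
    for i, g in enumerate(groups):
        for j, h in enumerate(groups):
            if j <= i:
                continue
            d = means[g] - means[h]
            D[i, j] = D[j, i] = float(np.sqrt(max(d @ Winv @ d, 0.0)))

    # Wilks' lambda
    grand = scores.mean(axis=0)
    E = W * (n - k)
    H = np.zeros((p, p))
    for g in groups:
        ng = len(design.indices(g))
        d = (means[g] - grand)[:, None]
        H += ng * (d @ d.T)
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    F, pval, df = _wilks_rao_f(lam, n=n, p=p, k=k)

    dendro = single_linkage(D, groups)
    dist_to_control = {}
    if "control" in groups:
        ci = groups.index("control")
        dist_to_control = {g: float(D[ci, j]) for j, g in enumerate(groups)
                           if g != "control"}
    return MahalanobisClustering(
        pc_scores=scores,
        group_names=list(groups),
        distance_matrix=D,
        distances_to_control=dist_to_control,
        dendrogram=dendro,
        wilks_lambda=lam,
        F=F,
        p_value=pval,
        df=df,
    )


def _wilks_rao_f(lam: float, n: int, p: int, k: int):
    """Rao's F approximation to the Wilks' Λ sampling distribution."""
    q = k - 1
    num = p * p * q * q - 4
    den = p * p + q * q - 5
    t = np.sqrt(num / den) if den > 0 and num > 0 else 1.0
    w = n - 1 - (p + k) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    ratio = lam ** (1.0 / t)
    if df2 <= 0:
        return np.nan, np.nan, (df1, df2)
    F = (1 - ratio) / ratio * df2 / df1
    pval = float(sps.f.sf(F, df1, df2))
    return float(F), pval, (float(df1), float(df2))


def single_linkage(dist: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """Single-linkage (nearest-neighbour) agglomerative clustering.

    Inter-cluster distance is the minimum pairwise distance; ties are
    broken deterministically by lexicographic order of the candidate
    clusters' smallest labels. Merge heights are non-decreasing, a
    property of single linkage.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if (dist < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix is not symmetric")

    labels = [str(l) for l in labels]
    clusters: list[tuple[str, ...]] = [(l,) for l in labels]
    members: list[list[int]] = [[i] for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(
                    dist[i, j] for i in members[a] for j in members[b]
                )
                key = (d, min(clusters[a][0], clusters[b][0]),
                       max(clusters[a][0], clusters[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        left, right = clusters[a], clusters[b]
        if right[0] < left[0]:
            left, right = right, left
        merges.append((left, right, float(d)))
        merged = tuple(sorted(left + right))
        new_members = members[a] + members[b]
        for idx in sorted((a, b), reverse=True):
            del clusters[idx]
            del members[idx]
        clusters.append(merged)
        members.append(new_members)
    return Dendrogram(merges=merges, labels=tuple(labels))


@dataclass
class AnovaTukeyResult:
    F: float
    p_value: float
    df: tuple[int, int]
    tukey: pd.DataFrame | None
    degenerate: bool = False


def anova_tukey(
    values: Sequence[float], design: GroupDesign, alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey's HSD post hoc.

    The Tukey table (statsmodels, studentised-range distribution)
    reports all pairwise comparisons with adjusted p-values and
    simultaneous confidence intervals. If every observation within a
    group equals its group mean and all group means coincide, the F
    statistic is undefined and the result is flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(design.sample_ids):
        raise ValueError("values and design length differ")
    groups = design.group_names
    arrays = [values[design.indices(g)] for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    within_var = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = [a.mean() for a in arrays]
    if within_var == 0 and np.allclose(means, means[0]):
        return AnovaTukeyResult(
            F=np.nan, p_value=np.nan,
            df=(len(groups) - 1, len(values) - len(groups)),
            tukey=None, degenerate=True,
        )
    F, p = sps.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(values, np.asarray(design.groups), alpha=alpha)
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return AnovaTukeyResult(
        F=float(F), p_value=float(p),
        df=(len(groups) - 1, len(values) - len(groups)),
        tukey=tukey_df,
    )


def oneway_f_statistic(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way F over replicated balanced designs.

    ``data`` has shape (reps, k, n): reps independent experiments of k
    groups × n observations. Returns (F, p) arrays of length reps.
    Used for Monte-Carlo calibration of the ANOVA chain.
    """
    reps, k, n = data.shape
    gm = data.mean(axis=2)
    grand = data.mean(axis=(1, 2))
    ssb = n * ((gm - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
    df1, df2 = k - 1, k * (n - 1)
    F = (ssb / df1) / (ssw / df2)
    return F, sps.f.sf(F, df1, df2)


@dataclass
class TunelSummary:
    """Per (group, layer) mean TUNEL+ frequency (profiles/mm) ± SE."""

    table: pd.DataFrame  # columns: group, layer, mean, se, n
    per_animal: pd.DataFrame  # columns: sample_id, group, layer, frequency
    anova: dict[str, AnovaTukeyResult] = field(default_factory=dict)


def tunel_summary(
    tables: dict[str, pd.DataFrame], design: GroupDesign, alpha: float = 0.05
) -> TunelSummary:
    """Summarise TUNEL counts per group and layer with per-layer ANOVA.

    ``tables`` maps sample_id → section table with columns
    (section_id, layer, count, length_mm). Per-animal frequency in a
    layer is total counts over total section length; animals with fewer
    than three sections are excluded with a warning.
    """
    group_of = dict(zip(design.sample_ids, design.groups))
    rows = []
    for sid, tab in tables.items():
        required = {"section_id", "layer", "count", "length_mm"}
        missing = required - set(tab.columns)
        if missing:
            raise ValueError(f"TUNEL table for {sid!r} missing columns {missing}")
        n_sections = tab["section_id"].nunique()
        if n_sections < 3:
            warnings.warn(f"animal {sid!r} has {n_sections} sections; excluded",
                          stacklevel=2)
            continue
        for layer, sub in tab.groupby("layer"):
            total_len = float(sub["length_mm"].sum())
            if total_len <= 0:
                raise ValueError(f"zero total section length for {sid!r}/{layer}")
            rows.append({
                "sample_id": sid,
                "group": group_of.get(sid, "unknown"),
                "layer": layer,
                "frequency": float(sub["count"].sum()) / total_len,
            })
    per_animal = pd.DataFrame(rows)
    summ = (
        per_animal.groupby(["group", "layer"])["frequency"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    anova: dict[str, AnovaTukeyResult] = {}
    for layer, sub in per_animal.groupby("layer"):
        sub = sub.sort_values("sample_id")
        d = GroupDesign.from_lists(sub["sample_id"], sub["group"])
        try:
            anova[layer] = anova_tukey(sub["frequency"].to_numpy(), d, alpha=alpha)
        except ValueError:
            continue
    return TunelSummary(table=summ, per_animal=per_animal, anova=anova)


def distances_relative_to_control(clustering: MahalanobisClustering) -> pd.Series:
    """Mahalanobis distance from control to each other group."""
    if "control" not in clustering.group_names:
        raise ValueError("design has no control group")
    order = [g for g in clustering.group_names if g != "control"]
    return pd.Series(
        [clustering.distances_to_control[g] for g in order], index=order,
        name="mahalanobis_to_control",
    )
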