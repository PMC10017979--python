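"""Population-structure summaries: genotype PCA, k-subgroup clustering with
a silhouette diagnostic, and a neighbor-joining tree.

PCA uses alternate-allele dosages (0/1/2) with Patterson normalisation:
each marker is centred by twice its estimated allele frequency and scaled
by ``sqrt(2 p (1 - p))``; missing dosages are imputed to the marker mean
before scaling. Subgroup assignment clusters the top principal components
with k-means over a range of K and selects the K with the highest mean
silhouette width. The tree is standard Saitou-Nei neighbor joining on
per-comparable-marker genotype-difference proportions, with negative branch
lengths clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .diversity import DifferenceMatrix
from .genotypes import GenotypePanel

logger = logging.getLogger("snpfingerprint")


@dataclass
class PcaResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    center: np.ndarray  # per retained marker: 2 * p_hat
    scale: np.ndarray   # per retained marker: sqrt(2 p_hat (1 - p_hat))
    marker_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k+1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


@dataclass
class SubgroupAssignment:
    k: int
    labels: dict[str, int]  # sample id -> group label in 1..K
    diagnostic: dict[int, float]  # K -> mean silhouette width
    degenerate: bool = False


@dataclass
class Phylogeny:
    """An unrooted tree over sample leaves, Newick-serialisable."""

    tree: TreeNode

    @property
    def newick(self) -> str:
        return str(self.tree).strip()

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def has_split(self, leaves: Sequence[str]) -> bool:
        """True if some edge bipartition separates exactly ``leaves`` from
        the rest — i.e. the set is a clade of the unrooted tree."""
        target = set(leaves)
        every = self.leaf_names()
        if not target <= every:
            raise KeyError(f"unknown leaves: {sorted(target - every)}")
        complement = every - target
        for node in self.tree.non_tips(include_self=True):
            below = {t.name for t in node.tips()}
            if below == target or below == complement:
                return True
        return len(target) == 1 or len(complement) == 1

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick + "\n")


def genotype_pca(
    panel: GenotypePanel,
    n_components: int = 10,
    missing_policy: str = "impute-mean",
) -> PcaResult:
    """Principal components of the Patterson-scaled dosage matrix.

    Zero-variance and all-missing markers are dropped before decomposition.
    ``missing_policy`` is ``"impute-mean"`` (default) or ``"drop-marker"``
    (drop any marker with a missing call).
    """
    if panel.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if missing_policy not in ("impute-mean", "drop-marker"):
        raise ValueError("missing_policy must be 'impute-mean' or 'drop-marker'")
    dose = panel.dosage_matrix()  # (n, m), NaN missing
    if missing_policy == "drop-marker":
        keep = ~np.isnan(dose).any(axis=0)
    else:
        keep = ~np.isnan(dose).all(axis=0)
    dose = dose[:, keep]
    marker_ids = [m for m, k in zip(panel.marker_ids, keep) if k]
    mean = np.nanmean(dose, axis=0)
    # impute missing to marker mean
    idx = np.where(np.isnan(dose))
    dose[idx] = mean[idx[1]]
    var = dose.var(axis=0)
    poly = var > 0
    if (~poly).any():
        logger.info("genotype_pca: dropped %d zero-variance markers", int((~poly).sum()))
    dose = dose[:, poly]
    marker_ids = [m for m, k in zip(marker_ids, poly) if k]
    p_hat = dose.mean(axis=0) / 2.0
    center = 2.0 * p_hat
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    x = (dose - center) / scale
    n_components = min(n_components, panel.n_samples, x.shape[1])
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    scores = u[:, :n_components] * s[:n_components]
    evr = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PcaResult(
        sample_ids=panel.sample_ids,
        scores=scores,
        explained_variance_ratio=evr,
        center=center,
        scale=scale,
        marker_ids=marker_ids,
    )


def assign_subgroups(
    pca: PcaResult,
    k_range: tuple[int, int] = (2, 8),
    n_components: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> SubgroupAssignment:
    """Cluster top principal components over a range of K; the K with the
    highest mean silhouette width is selected (ties to the smaller K)."""
    n = len(pca.sample_ids)
    lo, hi = k_range
    if lo < 2 or hi > n - 1 or lo > hi:
        raise ValueError(f"k_range {k_range} outside [2, n_samples-1]")
    x = pca.scores[:, : min(n_components, pca.scores.shape[1])]
    if np.allclose(x, x[0]):
        return SubgroupAssignment(
            k=1,
            labels={s: 1 for s in pca.sample_ids},
            diagnostic={},
            degenerate=True,
        )
    best_k, best_score, best_labels = None, -np.inf, None
    curve: dict[int, float] = {}
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        if len(set(labels)) < 2:
            continue
        score = float(silhouette_score(x, labels))
        curve[k] = score
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    assert best_labels is not None
    # relabel groups 1..K by first appearance for determinism
    remap: dict[int, int] = {}
    for lab in best_labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    return SubgroupAssignment(
        k=int(best_k),
        labels={s: remap[l] for s, l in zip(pca.sample_ids, best_labels)},
        diagnostic=curve,
    )


def labels_to_tsv(assign: SubgroupAssignment, path) -> None:
    pd.DataFrame(
        [{"sample_id": s, "subgroup": g} for s, g in assign.labels.items()]
    ).to_csv(path, sep="\t", index=False)


def nj_tree(dm: DifferenceMatrix) -> Phylogeny:
    """Saitou-Nei neighbor joining on normalised difference proportions.

    Distances are ``d(s,t) / m(s,t)`` (differences per comparable marker);
    negative branch lengths produced by NJ are clamped to zero.
    """
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    p = dm.proportion()
    skdm = _SkbioDM(p, ids=dm.sample_ids)
    tree = _skbio_nj(skdm, neg_as_zero=True)
    return Phylogeny(tree)
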