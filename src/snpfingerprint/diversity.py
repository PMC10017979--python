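"""Marker informativeness, pairwise genotype distances and replicate
concordance.

PIC follows Botstein's definition

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

where p_i are allele frequencies at the locus; the biallelic maximum is
0.375 at p = 0.5. Distances are genotype-level identity counts: two samples
differ at a marker when both calls are non-missing and the unordered
genotypes are unequal (so A/A vs A/G counts as a difference). Replicate
concordance compares each call to the modal (most frequent) genotype of its
marker across replicates — the "genetic stability" statistic of clonal
year-replicate panels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .filtering import allele_frequencies, _site_maf
from .genotypes import Genotype, GenotypePanel


@dataclass
class MarkerStats:
    marker_id: str
    maf: float
    pic: float
    completeness: float
    frequencies: dict[str, float] = field(default_factory=dict)


@dataclass
class DifferenceMatrix:
    """Pairwise counts of differing markers and of comparable markers.

    ``differences[i, j]`` counts markers where both samples have calls and
    the genotypes differ; ``comparable[i, j]`` counts markers where both
    have calls. Both are symmetric with zero diagonal.
    """

    sample_ids: list[str]
    differences: np.ndarray
    comparable: np.ndarray

    def proportion(self) -> np.ndarray:
        """Per-comparable-marker difference proportions (0 where nothing
        is comparable)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.differences / self.comparable
        return np.nan_to_num(p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.differences, index=self.sample_ids, columns=self.sample_ids
        )

    def to_phylip(self, path) -> None:
        """Square PHYLIP distance format of the difference proportions."""
        p = self.proportion()
        with open(path, "w") as fh:
            fh.write(f"{len(self.sample_ids)}\n")
            for i, sid in enumerate(self.sample_ids):
                row = " ".join(f"{v:.6f}" for v in p[i])
                fh.write(f"{sid.replace(' ', '_'):<12s} {row}\n")


@dataclass
class ConcordanceResult:
    n_calls_compared: int
    n_matching: int
    discordances: list[tuple[str, str]] = field(default_factory=list)  # (sample, marker)

    @property
    def concordance_pct(self) -> float:
        return round(100.0 * self.n_matching / self.n_calls_compared, 2)


def pic(freqs: Mapping[str, float], tol: float = 1e-9) -> float:
    """Botstein's polymorphism information content for one locus."""
    if not freqs:
        raise ValueError("PIC is undefined for an empty frequency map")
    p = np.asarray(list(freqs.values()), dtype=float)
    if abs(p.sum() - 1.0) > max(tol, 1e-9):
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    sq = p**2
    hom = sq.sum()
    cross = (np.outer(sq, sq).sum() - (sq**2).sum()) / 2.0
    return float(1.0 - hom - 2.0 * cross)


def expected_heterozygosity(freqs: Mapping[str, float]) -> float:
    p = np.asarray(list(freqs.values()), dtype=float)
    return float(1.0 - (p**2).sum())


def marker_stats(panel: GenotypePanel) -> list[MarkerStats]:
    """Per-marker MAF, PIC and call rate."""
    out = []
    miss = panel.missing_mask()
    for j, m in enumerate(panel.markers):
        freqs = allele_frequencies(panel, m.id)
        completeness = 1.0 - miss[:, j].mean()
        if freqs:
            maf = _site_maf(panel, j) or 0.0
            p = pic(freqs)
        else:
            maf, p = 0.0, 0.0
        out.append(
            MarkerStats(
                marker_id=m.id,
                maf=maf,
                pic=p,
                completeness=float(completeness),
                frequencies=freqs,
            )
        )
    return out


def stats_to_tsv(stats: Sequence[MarkerStats], path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": s.marker_id,
                "maf": s.maf,
                "pic": s.pic,
                "completeness": s.completeness,
            }
            for s in stats
        ]
    ).to_csv(path, sep="\t", index=False)


def difference_matrix(
    panel: GenotypePanel, markers: Optional[Sequence[str]] = None
) -> DifferenceMatrix:
    """Pairwise genotype-difference counts over (a subset of) markers."""
    p = panel if markers is None else panel.subset_markers(list(markers))
    calls = p.calls  # (n, m, 2)
    called = calls[:, :, 0] >= 0  # (n, m)
    n = p.n_samples
    diffs = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = called[i][None, :] & called  # (n, m)
        neq = (calls[i][None, :, :] != calls).any(axis=2)  # (n, m)
        diffs[i] = (both & neq).sum(axis=1)
        comp[i] = both.sum(axis=1)
    np.fill_diagonal(diffs, 0)
    return DifferenceMatrix(p.sample_ids, diffs, comp)


def _modal_genotype_index(column: np.ndarray) -> Optional[tuple[int, int]]:
    """Most frequent non-missing allele pair in a (n, 2) call column; ties
    broken by the smaller allele-code pair. None if all calls missing."""
    called = column[column[:, 0] >= 0]
    if called.size == 0:
        return None
    pairs, counts = np.unique(called, axis=0, return_counts=True)
    best = np.lexsort((pairs[:, 1], pairs[:, 0], -counts))[0]
    return tuple(pairs[best])


def concordance_to_modal(panel: GenotypePanel) -> ConcordanceResult:
    """Concordance of replicate samples to the per-marker modal genotype.

    The panel is expected to hold >= 2 replicate samples of one variety.
    Missing calls and all-missing markers are excluded from both numerator
    and denominator. The discordance list names (sample, marker) for every
    non-modal call.
    """
    if panel.n_samples < 2:
        raise ValueError("concordance_to_modal needs at least 2 replicate samples")
    n_compared = 0
    n_match = 0
    disc: list[tuple[str, str]] = []
    for j, m in enumerate(panel.markers):
        col = panel.calls[:, j, :]
        modal = _modal_genotype_index(col)
        if modal is None:
            continue
        for i, sid in enumerate(panel.sample_ids):
            if col[i, 0] < 0:
                continue
            n_compared += 1
            if tuple(col[i]) == modal:
                n_match += 1
            else:
                disc.append((sid, m.id))
    return ConcordanceResult(n_compared, n_match, disc)


def _overlap_match(a: Genotype, b: Genotype) -> bool:
    return bool(set(a.alleles) & set(b.alleles))  # type: ignore[arg-type]


def concordance_pairwise(
    a: GenotypePanel, b: GenotypePanel, mode: str = "strict"
) -> ConcordanceResult:
    """Call-by-call concordance of two panels over their shared samples and
    markers.

    ``mode="strict"`` requires genotype equality; ``mode="allele-overlap"``
    additionally counts a heterozygote as matching a constituent homozygote
    (useful when one platform under-calls heterozygotes). Calls missing in
    either panel are skipped.
    """
    if mode not in ("strict", "allele-overlap"):
        raise ValueError("mode must be 'strict' or 'allele-overlap'")
    shared_markers = [m for m in a.marker_ids if m in set(b.marker_ids)]
    shared_samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if not shared_markers or not shared_samples:
        raise ValueError("panels share no markers or no samples")
    n_compared = 0
    n_match = 0
    disc: list[tuple[str, str]] = []
    for sid, mid in itertools.product(shared_samples, shared_markers):
        ga = a.genotype(sid, mid)
        gb = b.genotype(sid, mid)
        if ga.is_missing or gb.is_missing:
            continue
        n_compared += 1
        ok = ga == gb or (mode == "allele-overlap" and _overlap_match(ga, gb))
        if ok:
            n_match += 1
        else:
            disc.append((sid, mid))
    if n_compared == 0:
        raise ValueError("no comparable calls between the panels")
    return ConcordanceResult(n_compared, n_match, disc)
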