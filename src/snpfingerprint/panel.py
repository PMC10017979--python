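"""Core-panel selection and minimal discriminating SNP sets.

The fingerprinting workflow has two reduction stages:

1. **Core panel** — from all filtered SNPs, keep high-information markers
   (PIC >= 0.30, call rate >= 0.90 by default) spread evenly over the
   chromosomes (equal per-chromosome quota), up to a target size (50 by
   default). The panel must distinguish every pair of samples at >= k
   markers; if the quota-filled set does not, markers are greedily appended
   from the remaining candidates by marginal pair coverage.

2. **Minimal set** — reduce the core panel to the smallest marker subset
   that still distinguishes every sample pair at >= k markers. "Distinguish"
   means both calls non-missing and the unordered genotypes unequal. This is
   a k-multicover of sample pairs by markers; a greedy algorithm (with the
   classical ln(#pairs)+1 guarantee) and an exact branch-and-bound solver
   are provided. All tie-breaks are deterministic, so runs are reproducible.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .diversity import MarkerStats
from .genotypes import GenotypePanel, GenotypeCategory, category_encode, iupac_encode


class InfeasibleError(ValueError):
    """Raised when some sample pair cannot be distinguished at the
    requested multiplicity by any available marker set."""

    def __init__(self, message: str, pairs: Sequence[tuple[str, str]] = ()):
        super().__init__(message)
        self.pairs = list(pairs)


class ExactSearchRefused(RuntimeError):
    """Raised when the exact solver's search-space guard trips."""


@dataclass
class PanelConfig:
    """Selection thresholds for the core fingerprint panel."""

    min_pic: float = 0.30
    min_completeness: float = 0.90
    target_size: int = 50
    per_chromosome_quota: str = "equal"  # equal | proportional | none
    min_pairwise_differences: int = 1  # k

    def __post_init__(self) -> None:
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")
        if self.min_pairwise_differences < 1:
            raise ValueError("min_pairwise_differences must be >= 1")
        if self.per_chromosome_quota not in ("equal", "proportional", "none"):
            raise ValueError("per_chromosome_quota must be equal|proportional|none")


@dataclass
class CoverInstance:
    """Set-cover view of 'distinguish all sample pairs with markers'.

    ``pairs`` lists unordered sample-id pairs in panel order; for each
    marker, ``cover_sets`` holds a bitmask over pairs (bit q set when the
    marker distinguishes pair q).
    """

    marker_ids: list[str]
    pairs: list[tuple[str, str]]
    cover_sets: list[int]

    def uncoverable_pairs(self, k: int = 1) -> list[tuple[str, str]]:
        counts = [0] * len(self.pairs)
        for mask in self.cover_sets:
            q = 0
            while mask:
                if mask & 1:
                    counts[q] += 1
                mask >>= 1
                q += 1
        return [p for p, c in zip(self.pairs, counts) if c < k]

    def covers_all(self, marker_subset: Sequence[str], k: int = 1) -> bool:
        idx = {m: i for i, m in enumerate(self.marker_ids)}
        counts = [0] * len(self.pairs)
        for m in marker_subset:
            mask = self.cover_sets[idx[m]]
            q = 0
            while mask:
                if mask & 1:
                    counts[q] += 1
                mask >>= 1
                q += 1
        return all(c >= k for c in counts)


@dataclass
class FingerprintPanel:
    """An ordered marker subset with its encoded fingerprint table."""

    marker_ids: list[str]
    sample_ids: list[str]
    barcodes: dict[str, str]  # sample -> concatenated IUPAC letters
    categories: dict[str, list[GenotypeCategory]]
    selection_log: dict = field(default_factory=dict)

    def write_tsv(self, panel: GenotypePanel, path) -> None:
        sub = panel.subset_markers(self.marker_ids)
        df = sub.to_frame()
        df.index.name = "Marker"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cover-instance construction
# ---------------------------------------------------------------------------


def build_cover_instance(
    panel: GenotypePanel, markers: Optional[Sequence[str]] = None
) -> CoverInstance:
    """Enumerate sample pairs and, per marker, the pairs it distinguishes.

    A marker distinguishes a pair when both calls are non-missing and the
    unordered genotypes differ.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    sub = panel if markers is None else panel.subset_markers(list(markers))
    sids = sub.sample_ids
    pairs = [(sids[i], sids[j]) for i, j in itertools.combinations(range(len(sids)), 2)]
    calls = sub.calls
    called = calls[:, :, 0] >= 0
    cover_sets: list[int] = []
    pair_idx = list(itertools.combinations(range(len(sids)), 2))
    i_idx = np.array([i for i, _ in pair_idx])
    j_idx = np.array([j for _, j in pair_idx])
    for mj in range(sub.n_markers):
        col = calls[:, mj, :]
        ok = called[:, mj][i_idx] & called[:, mj][j_idx]
        neq = (col[i_idx] != col[j_idx]).any(axis=1)
        bits = np.nonzero(ok & neq)[0]
        mask = 0
        for q in bits:
            mask |= 1 << int(q)
        cover_sets.append(mask)
    return CoverInstance(sub.marker_ids, pairs, cover_sets)


# ---------------------------------------------------------------------------
# Greedy k-multicover
# ---------------------------------------------------------------------------


def _tie_key(
    ci: CoverInstance,
    stats_by_id: dict[str, MarkerStats],
    panel: Optional[GenotypePanel],
    m_idx: int,
):
    mid = ci.marker_ids[m_idx]
    s = stats_by_id.get(mid)
    pic = s.pic if s else 0.0
    chrom, pos = "", m_idx
    if panel is not None:
        mk = panel.markers[panel.marker_index(mid)]
        chrom, pos = mk.chrom, mk.pos
    # higher PIC first, then lower (chrom, pos), then marker order
    return (-pic, chrom, pos, m_idx)


def minimal_discriminating_set_greedy(
    ci: CoverInstance,
    k: int = 1,
    stats: Optional[Sequence[MarkerStats]] = None,
    panel: Optional[GenotypePanel] = None,
) -> list[str]:
    """Greedy k-multicover: repeatedly add the marker covering the most
    pairs still below multiplicity k; ties by higher PIC, then (chrom, pos),
    then marker order. The result is re-verified before return."""
    bad = ci.uncoverable_pairs(k)
    if bad:
        raise InfeasibleError(
            f"{len(bad)} pair(s) cannot be distinguished at k={k}: {bad[:5]}", bad
        )
    stats_by_id = {s.marker_id: s for s in (stats or [])}
    n_pairs = len(ci.pairs)
    deficit = [k] * n_pairs
    chosen: list[int] = []
    remaining = set(range(len(ci.marker_ids)))
    while any(d > 0 for d in deficit):
        best, best_gain, best_key = None, 0, None
        for m in sorted(remaining):
            mask = ci.cover_sets[m]
            gain = sum(
                1 for q in range(n_pairs) if deficit[q] > 0 and (mask >> q) & 1
            )
            if gain == 0:
                continue
            key = _tie_key(ci, stats_by_id, panel, m)
            if gain > best_gain or (gain == best_gain and key < best_key):
                best, best_gain, best_key = m, gain, key
        assert best is not None  # feasibility pre-checked
        chosen.append(best)
        remaining.discard(best)
        mask = ci.cover_sets[best]
        for q in range(n_pairs):
            if (mask >> q) & 1 and deficit[q] > 0:
                deficit[q] -= 1
    result = [ci.marker_ids[m] for m in chosen]
    assert ci.covers_all(result, k)
    return result


# ---------------------------------------------------------------------------
# Exact branch-and-bound k-multicover
# ---------------------------------------------------------------------------


def minimal_discriminating_set_exact(
    ci: CoverInstance,
    k: int = 1,
    size_cap: Optional[int] = None,
    max_markers: int = 25,
) -> list[str]:
    """Provably minimum-cardinality marker subset that k-distinguishes all
    pairs, via branch-and-bound.

    The greedy solution provides the initial upper bound; branching is on
    the pair with the largest remaining deficit and fewest covering markers.
    Among equal-size optima the lexicographically smallest subset (by marker
    order) is returned. Instances with more than ``max_markers`` markers are
    refused unless ``size_cap`` bounds the search depth.
    """
    n_m = len(ci.marker_ids)
    if n_m > max_markers and (size_cap is None or size_cap > 8):
        raise ExactSearchRefused(
            f"{n_m} markers exceeds the exact-search guard ({max_markers}); "
            "use the greedy solver or set a small size_cap"
        )
    bad = ci.uncoverable_pairs(k)
    if bad:
        raise InfeasibleError(
            f"{len(bad)} pair(s) cannot be distinguished at k={k}: {bad[:5]}", bad
        )
    n_pairs = len(ci.pairs)
    covers_of_pair: list[list[int]] = [[] for _ in range(n_pairs)]
    for m, mask in enumerate(ci.cover_sets):
        for q in range(n_pairs):
            if (mask >> q) & 1:
                covers_of_pair[q].append(m)

    greedy = minimal_discriminating_set_greedy(ci, k)
    best_size = len(greedy)
    if size_cap is not None and best_size > size_cap:
        best_size = size_cap + 1
    best_solution: Optional[tuple[int, ...]] = (
        tuple(sorted(ci.marker_ids.index(m) for m in greedy))
        if len(greedy) == best_size
        else None
    )

    max_cover = max((mask.bit_count() for mask in ci.cover_sets), default=0)

    def search(chosen: list[int], deficit: list[int]) -> None:
        nonlocal best_size, best_solution
        total_deficit = sum(deficit)
        if total_deficit == 0:
            cand = tuple(sorted(chosen))
            if len(cand) < best_size or (
                len(cand) == best_size
                and (best_solution is None or cand < best_solution)
            ):
                best_size = len(cand)
                best_solution = cand
            return
        if max_cover == 0:
            return
        lb = math.ceil(total_deficit / max_cover)
        if len(chosen) + lb > best_size:
            return
        # branch on the unmet pair with fewest remaining covering markers
        chosen_set = set(chosen)
        target, options = None, None
        for q in range(n_pairs):
            if deficit[q] <= 0:
                continue
            opts = [m for m in covers_of_pair[q] if m not in chosen_set]
            if len(opts) < deficit[q]:
                return  # dead end
            if options is None or len(opts) < len(options):
                target, options = q, opts
        assert options is not None
        for m in options:
            mask = ci.cover_sets[m]
            new_deficit = list(deficit)
            q2 = 0
            mm = mask
            while mm:
                if mm & 1 and new_deficit[q2] > 0:
                    new_deficit[q2] -= 1
                mm >>= 1
                q2 += 1
            chosen.append(m)
            search(chosen, new_deficit)
            chosen.pop()

    search([], [k] * n_pairs)
    if best_solution is None:
        raise InfeasibleError(f"no subset of size <= {size_cap} covers all pairs")
    result = [ci.marker_ids[m] for m in best_solution]
    assert ci.covers_all(result, k)
    return result


# ---------------------------------------------------------------------------
# Core-panel selection
# ---------------------------------------------------------------------------


def _chromosome_quotas(
    chroms: Sequence[str], target: int, best_pic: dict[str, float]
) -> dict[str, int]:
    """Equal quotas: floor(target / n_chrom) each, remainder (+1) to the
    chromosomes with the highest-PIC top candidate (ties by label)."""
    n = len(chroms)
    base = target // n
    rem = target - base * n
    ranked = sorted(chroms, key=lambda c: (-best_pic.get(c, 0.0), c))
    quotas = {c: base for c in chroms}
    for c in ranked[:rem]:
        quotas[c] += 1
    return quotas


def select_core_panel(
    panel: GenotypePanel,
    stats: Sequence[MarkerStats],
    cfg: Optional[PanelConfig] = None,
) -> FingerprintPanel:
    """Select the chromosome-balanced, high-PIC core fingerprint panel.

    Candidates are markers with ``pic >= min_pic`` and ``completeness >=
    min_completeness``. Within each chromosome candidates are ranked by PIC
    (descending), ties by position (ascending); chromosome quotas are filled
    up to ``target_size``. If the quota-filled set fails to distinguish every
    sample pair at >= k markers, remaining candidates are greedily appended
    by marginal pair coverage until it does; if candidates run out first, an
    :class:`InfeasibleError` lists the indistinguishable pairs.
    """
    cfg = cfg or PanelConfig()
    stats_by_id = {s.marker_id: s for s in stats}
    missing = [m for m in panel.marker_ids if m not in stats_by_id]
    if missing:
        raise ValueError(f"stats missing for markers: {missing[:5]}")
    candidates = [
        m
        for m in panel.markers
        if stats_by_id[m.id].pic >= cfg.min_pic
        and stats_by_id[m.id].completeness >= cfg.min_completeness
    ]
    if not candidates:
        raise InfeasibleError("no candidate markers pass the PIC/completeness screen")

    by_chrom: dict[str, list] = {}
    for m in candidates:
        by_chrom.setdefault(m.chrom, []).append(m)
    for ms in by_chrom.values():
        ms.sort(key=lambda m: (-stats_by_id[m.id].pic, m.pos))

    k = cfg.min_pairwise_differences
    target = min(cfg.target_size, len(candidates))
    if cfg.per_chromosome_quota == "none":
        ranked = sorted(
            candidates, key=lambda m: (-stats_by_id[m.id].pic, m.chrom, m.pos)
        )
        selected = [m.id for m in ranked[:target]]
        quotas: dict[str, int] = {}
    else:
        if cfg.per_chromosome_quota == "equal":
            quotas = _chromosome_quotas(
                sorted(by_chrom),
                target,
                {c: stats_by_id[ms[0].id].pic for c, ms in by_chrom.items()},
            )
        else:  # proportional to candidate counts
            total = len(candidates)
            quotas = {
                c: max(1, round(target * len(ms) / total))
                for c, ms in sorted(by_chrom.items())
            }
        selected = []
        leftovers: list = []
        for c in sorted(by_chrom):
            q = quotas.get(c, 0)
            selected.extend(m.id for m in by_chrom[c][:q])
            leftovers.extend(by_chrom[c][q:])
        # top up to target from leftover candidates by PIC if quotas undershot
        leftovers.sort(key=lambda m: (-stats_by_id[m.id].pic, m.chrom, m.pos))
        for m in leftovers:
            if len(selected) >= target:
                break
            selected.append(m.id)

    # verify distinguishability; greedily append from remaining candidates
    ci_all = build_cover_instance(panel, [m.id for m in candidates])
    bad = ci_all.uncoverable_pairs(k)
    if bad:
        raise InfeasibleError(
            f"{len(bad)} sample pair(s) identical across all candidates: {bad[:5]}",
            bad,
        )
    idx = {m: i for i, m in enumerate(ci_all.marker_ids)}
    n_pairs = len(ci_all.pairs)
    deficit = [k] * n_pairs
    for mid in selected:
        mask = ci_all.cover_sets[idx[mid]]
        for q in range(n_pairs):
            if (mask >> q) & 1 and deficit[q] > 0:
                deficit[q] -= 1
    appended: list[str] = []
    remaining = [m.id for m in candidates if m.id not in set(selected)]
    while any(d > 0 for d in deficit):
        best, best_gain = None, 0
        for mid in remaining:
            mask = ci_all.cover_sets[idx[mid]]
            gain = sum(1 for q in range(n_pairs) if deficit[q] > 0 and (mask >> q) & 1)
            if gain > best_gain:
                best, best_gain = mid, gain
        if best is None:
            still = [p for p, d in zip(ci_all.pairs, deficit) if d > 0]
            raise InfeasibleError(
                f"candidates exhausted; {len(still)} pair(s) unresolved: {still[:5]}",
                still,
            )
        appended.append(best)
        remaining.remove(best)
        mask = ci_all.cover_sets[idx[best]]
        for q in range(n_pairs):
            if (mask >> q) & 1 and deficit[q] > 0:
                deficit[q] -= 1
    final = selected + appended
    log = {
        "n_candidates": len(candidates),
        "quotas": quotas,
        "n_quota_selected": len(selected),
        "n_appended_for_coverage": len(appended),
        "k": k,
    }
    return make_fingerprint(panel, final, selection_log=log)


def make_fingerprint(
    panel: GenotypePanel,
    marker_ids: Sequence[str],
    selection_log: Optional[dict] = None,
    require_distinct: bool = True,
) -> FingerprintPanel:
    """Render a marker subset as an encoded fingerprint panel."""
    sub = panel.subset_markers(list(marker_ids))
    barcodes = {}
    categories = {}
    for i, sid in enumerate(sub.sample_ids):
        gts = [sub.genotype(i, j) for j in range(sub.n_markers)]
        barcodes[sid] = "".join(iupac_encode(g) for g in gts)
        categories[sid] = [category_encode(g) for g in gts]
    if require_distinct:
        ci = build_cover_instance(sub)
        bad = ci.uncoverable_pairs(1)
        if bad:
            raise InfeasibleError(
                f"fingerprint does not distinguish {len(bad)} pair(s): {bad[:5]}", bad
            )
    return FingerprintPanel(
        marker_ids=list(marker_ids),
        sample_ids=sub.sample_ids,
        barcodes=barcodes,
        categories=categories,
        selection_log=selection_log or {},
    )


def render_fingerprint(
    panel: GenotypePanel,
    markers: Sequence[str],
    fmt: str = "tsv",
    path=None,
) -> str:
    """Render sample fingerprints over a marker subset.

    ``fmt``: ``tsv`` (marker rows x sample genotype columns),
    ``iupac-string`` (one concatenated barcode per sample), or
    ``category-grid`` (display-category tokens for heat-map plotting).
    A subset that fails to distinguish some pair triggers a warning, not an
    error.
    """
    import warnings

    if fmt not in ("tsv", "iupac-string", "category-grid"):
        raise ValueError(f"unknown format {fmt!r}")
    fp = make_fingerprint(panel, markers, require_distinct=False)
    sub = panel.subset_markers(list(markers))
    ci = build_cover_instance(sub)
    bad = ci.uncoverable_pairs(1)
    if bad:
        warnings.warn(
            f"fingerprint does not distinguish {len(bad)} sample pair(s)",
            stacklevel=2,
        )
    if fmt == "tsv":
        df = sub.to_frame()
        df.index.name = "Marker"
        text = df.to_csv(sep="\t")
    elif fmt == "iupac-string":
        text = "".join(f"{s}\t{fp.barcodes[s]}\n" for s in fp.sample_ids)
    else:
        lines = ["sample\t" + "\t".join(fp.marker_ids)]
        for s in fp.sample_ids:
            lines.append(s + "\t" + "\t".join(c.value for c in fp.categories[s]))
        text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def selection_log_json(fp: FingerprintPanel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"markers": fp.marker_ids, "log": fp.selection_log}, fh, indent=2
        )
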