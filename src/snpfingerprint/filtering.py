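"""Site-level hard filtering of SNPs.

Implements the screening criteria used for ddRAD cultivar-fingerprinting
panels: mean sequencing depth >= 5x, minor allele frequency >= 0.05, call
rate ("information integrity") >= 0.70, phred site quality Q >= 30, and the
GATK-style annotation exclusions QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 6.0,
MQRankSum < -12.5, ReadPosRankSum < -8.0.

The six annotation thresholds are applied as *exclusion* conditions (the
GATK hard-filter convention): a site failing any of them is removed. Sites
lacking an annotation are kept by default (annotations such as MQRankSum
are undefined at sites with no heterozygotes), configurable via
``missing_annotation_policy``.

Each removed site is attributed to the FIRST criterion it fails, in the
fixed order: depth, maf, completeness, qual, QD, MQ, FS, SOR, MQRankSum,
ReadPosRankSum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genotypes import BASES, GenotypePanel

#: Attribution order for the filter report.
CRITERIA = (
    "depth",
    "maf",
    "completeness",
    "qual",
    "QD",
    "MQ",
    "FS",
    "SOR",
    "MQRankSum",
    "ReadPosRankSum",
)


@dataclass
class FilterConfig:
    """Thresholds for site-level hard filtering."""

    min_mean_depth: float = 5.0
    min_maf: float = 0.05
    min_completeness: float = 0.70
    min_qual: float = 30.0
    max_qd_fail: float = 2.0      # exclude if QD < 2.0
    max_mq_fail: float = 40.0     # exclude if MQ < 40.0
    min_fs_fail: float = 60.0     # exclude if FS > 60.0
    min_sor_fail: float = 6.0     # exclude if SOR > 6.0
    max_mqranksum_fail: float = -12.5     # exclude if MQRankSum < -12.5
    max_readposranksum_fail: float = -8.0  # exclude if ReadPosRankSum < -8.0
    missing_annotation_policy: str = "keep"  # keep | drop

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if not (0.0 <= self.min_completeness <= 1.0):
            raise ValueError("min_completeness must be in [0, 1]")
        if self.missing_annotation_policy not in ("keep", "drop"):
            raise ValueError("missing_annotation_policy must be 'keep' or 'drop'")
        for name in (
            "min_mean_depth",
            "min_qual",
            "max_qd_fail",
            "max_mq_fail",
            "min_fs_fail",
            "min_sor_fail",
            "max_mqranksum_fail",
            "max_readposranksum_fail",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class FilterReport:
    """Counts of input, passed and per-criterion removed sites."""

    n_input: int
    n_passed: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_input == self.n_passed + sum(self.removed.values())


def allele_frequencies(panel: GenotypePanel, marker: str) -> dict[str, float]:
    """Allele frequencies at one marker over non-missing diploid calls.

    Each called genotype contributes two allele observations; returns an
    empty map for a marker with no calls.
    """
    j = panel.marker_index(marker)
    col = panel.calls[:, j, :].ravel()
    col = col[col >= 0]
    if col.size == 0:
        return {}
    counts = np.bincount(col, minlength=4)
    total = counts.sum()
    return {BASES[c]: counts[c] / total for c in range(4) if counts[c] > 0}


def _site_maf(panel: GenotypePanel, j: int) -> Optional[float]:
    col = panel.calls[:, j, :].ravel()
    col = col[col >= 0]
    if col.size == 0:
        return None
    counts = np.bincount(col, minlength=4)
    counts = np.sort(counts[counts > 0])[::-1]
    if counts.size == 1:
        return 0.0
    # MAF of a biallelic site = frequency of the second most common allele
    return float(counts[1] / counts.sum())


def _first_failure(panel: GenotypePanel, j: int, cfg: FilterConfig) -> Optional[str]:
    m = panel.markers[j]
    if m.depth_mean is not None and m.depth_mean < cfg.min_mean_depth:
        return "depth"
    maf = _site_maf(panel, j)
    if maf is None or maf < cfg.min_maf:
        return "maf"
    completeness = 1.0 - panel.missing_mask()[:, j].mean()
    if completeness < cfg.min_completeness:
        return "completeness"
    if m.qual is not None and m.qual < cfg.min_qual:
        return "qual"
    exclusions = (
        ("QD", lambda v: v < cfg.max_qd_fail),
        ("MQ", lambda v: v < cfg.max_mq_fail),
        ("FS", lambda v: v > cfg.min_fs_fail),
        ("SOR", lambda v: v > cfg.min_sor_fail),
        ("MQRankSum", lambda v: v < cfg.max_mqranksum_fail),
        ("ReadPosRankSum", lambda v: v < cfg.max_readposranksum_fail),
    )
    for key, fails in exclusions:
        v = m.annotations.get(key)
        if v is None:
            if cfg.missing_annotation_policy == "drop":
                return key
            continue
        if fails(v):
            return key
    return None


def apply_filters(
    panel: GenotypePanel, cfg: Optional[FilterConfig] = None
) -> tuple[GenotypePanel, FilterReport]:
    """Apply hard filters; returns the passing panel and a removal report.

    The sample set is unchanged and marker order is preserved. Filtering is
    idempotent: a second pass over the output removes nothing.
    """
    cfg = cfg or FilterConfig()
    keep: list[int] = []
    removed: dict[str, int] = {c: 0 for c in CRITERIA}
    removed_ids: dict[str, list[str]] = {c: [] for c in CRITERIA}
    for j in range(panel.n_markers):
        crit = _first_failure(panel, j, cfg)
        if crit is None:
            keep.append(j)
        else:
            removed[crit] += 1
            removed_ids[crit].append(panel.markers[j].id)
    out = panel.subset_markers([panel.markers[j].id for j in keep])
    report = FilterReport(
        n_input=panel.n_markers,
        n_passed=len(keep),
        removed={c: n for c, n in removed.items() if n},
        removed_ids={c: ids for c, ids in removed_ids.items() if ids},
    )
    return out, report


def report_to_tsv(report: FilterReport, path) -> None:
    import pandas as pd

    rows = [{"criterion": "input", "count": report.n_input},
            {"criterion": "passed", "count": report.n_passed}]
    rows += [{"criterion": c, "count": n} for c, n in report.removed.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
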