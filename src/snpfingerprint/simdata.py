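"""Synthetic genotype panels with the structure the analysis assumes.

The generator emulates a germplasm collection of ~39 varieties in four
subpopulations — three moderately drifted groups of one species plus one
strongly diverged outgroup species — genotyped at biallelic SNPs on nine
chromosomes. Subpopulation allele frequencies follow the Balding–Nichols
model: for ancestral frequency ``p`` and drift parameter ``F`` (≈ Fst),

    p_s ~ Beta(p (1 - F) / F,  (1 - p)(1 - F) / F),

and genotypes are drawn at Hardy–Weinberg proportions within each
subpopulation. F1 hybrids draw one gamete from each parent's realised
genotype; clonal replicates copy a parent sample and flip each call to a
random different genotype with a small per-call error rate (mimicking
call discrepancies between platforms or years). Site annotations (qual,
depth, QD, MQ, FS, SOR, rank sums) are drawn from configurable passing
distributions, with optional planted failures for filter testing.

Everything is driven by a single integer seed: identical configs produce
byte-identical panels.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .genotypes import (
    BASES,
    GenotypePanel,
    MarkerSite,
    MISSING_CODE,
    SampleMeta,
)


@dataclass
class AnnotationModel:
    """Distributions for passing site annotations (normal, clipped to the
    passing side of each filter threshold)."""

    qual_mean: float = 120.0
    qual_sd: float = 30.0
    depth_mean: float = 20.0
    depth_sd: float = 5.0
    qd_mean: float = 20.0
    qd_sd: float = 5.0
    mq_mean: float = 58.0
    mq_sd: float = 3.0
    fs_mean: float = 3.0
    fs_sd: float = 2.0
    sor_mean: float = 1.2
    sor_sd: float = 0.5
    ranksum_sd: float = 1.5


@dataclass
class SimConfig:
    """All parameters of the synthetic population generator.

    Defaults emulate the study design this package targets: 39 accessions
    in four subgroups (5 / 4 / 18 / 9 founders plus three F1 hybrids
    appended to the first subgroup), the second subgroup being a diverged
    outgroup species with elevated drift.
    """

    seed: int = 0
    n_chromosomes: int = 9
    n_markers: int = 5000
    chromosome_lengths: Optional[Sequence[int]] = None
    samples_per_subpop: Sequence[int] = (5, 4, 18, 9)
    fst: Sequence[float] = (0.1, 0.5, 0.1, 0.1)
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    hybrids: Sequence[tuple[str, str]] = (
        ("S01", "S02"),
        ("S02", "S01"),
        ("S02", "S01"),
    )
    n_replicate_clones: int = 0
    clone_of: Optional[str] = None
    replicate_error: float = 0.02
    missing_rate: float = 0.02
    annotations: AnnotationModel = field(default_factory=AnnotationModel)
    planted_failures: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fst) != len(self.samples_per_subpop):
            raise ValueError("fst must have one value per subpopulation")
        for f in self.fst:
            if not (0.0 < f < 1.0):
                raise ValueError("fst values must lie in (0, 1)")
        for p in (self.replicate_error, self.missing_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    subpop_labels: dict[str, int]
    ancestral_freq: np.ndarray
    subpop_freq: np.ndarray  # (n_subpops, n_markers) alt-allele frequencies
    hybrid_pedigree: dict[str, tuple[str, str]]
    clone_parent: dict[str, str]
    planted_failures: dict[str, str] = field(default_factory=dict)  # marker -> criterion
    planted_set: list[str] = field(default_factory=list)


def _draw_sites(rng: np.random.Generator, cfg: SimConfig) -> list[MarkerSite]:
    if cfg.chromosome_lengths is not None:
        lengths = np.asarray(cfg.chromosome_lengths, dtype=float)
        probs = lengths / lengths.sum()
    else:
        probs = np.full(cfg.n_chromosomes, 1.0 / cfg.n_chromosomes)
    chrom_idx = rng.choice(cfg.n_chromosomes, size=cfg.n_markers, p=probs)
    am = cfg.annotations
    sites = []
    positions: dict[int, set[int]] = {c: set() for c in range(cfg.n_chromosomes)}
    for j in range(cfg.n_markers):
        c = int(chrom_idx[j])
        pos = int(rng.integers(1, 10_000_000))
        while pos in positions[c]:
            pos = int(rng.integers(1, 10_000_000))
        positions[c].add(pos)
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            MarkerSite(
                id=f"M{j+1:05d}",
                chrom=f"chr{c+1}",
                pos=pos,
                ref=BASES[ref],
                alt=BASES[alt],
                qual=float(np.clip(rng.normal(am.qual_mean, am.qual_sd), 31, None)),
                depth_mean=float(
                    np.clip(rng.normal(am.depth_mean, am.depth_sd), 5.5, None)
                ),
                annotations={
                    "QD": float(np.clip(rng.normal(am.qd_mean, am.qd_sd), 2.5, None)),
                    "MQ": float(np.clip(rng.normal(am.mq_mean, am.mq_sd), 40.5, None)),
                    "FS": float(np.clip(rng.normal(am.fs_mean, am.fs_sd), 0, 59.5)),
                    "SOR": float(np.clip(rng.normal(am.sor_mean, am.sor_sd), 0, 5.9)),
                    "MQRankSum": float(
                        np.clip(rng.normal(0, am.ranksum_sd), -12.0, None)
                    ),
                    "ReadPosRankSum": float(
                        np.clip(rng.normal(0, am.ranksum_sd), -7.5, None)
                    ),
                },
            )
        )
    return sites


def _genotype_codes(site: MarkerSite, dose: int) -> tuple[int, int]:
    ref = BASES.index(site.ref)  # type: ignore[arg-type]
    alt = BASES.index(site.alt)  # type: ignore[arg-type]
    pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt)}[dose]
    return tuple(sorted(pair))  # type: ignore[return-value]


def simulate_panel(cfg: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a genotype panel under the configured population model.

    Sample ids run ``S01, S02, ...`` over founders subpop by subpop, then
    hybrids (``H..``), then replicate clones (``R..``).
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _draw_sites(rng, cfg)
    n_m = cfg.n_markers
    n_subpops = len(cfg.samples_per_subpop)

    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=n_m)
    # ancestral alt-allele frequency: either the MAF or its complement
    flip = rng.random(n_m) < 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    p_sub = np.empty((n_subpops, n_m))
    for s, f in enumerate(cfg.fst):
        a = p_anc * (1.0 - f) / f
        b = (1.0 - p_anc) * (1.0 - f) / f
        p_sub[s] = rng.beta(a, b)

    samples: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    labels: dict[str, int] = {}
    sid_counter = 0
    for s, n_s in enumerate(cfg.samples_per_subpop):
        for _ in range(n_s):
            sid_counter += 1
            sid = f"S{sid_counter:02d}"
            dose = rng.binomial(2, p_sub[s])  # HWE within subpop
            codes = np.array(
                [_genotype_codes(sites[j], int(dose[j])) for j in range(n_m)],
                dtype=np.int8,
            )
            rows.append(codes)
            labels[sid] = s + 1
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    variety_name=f"Variety {sid_counter}",
                    subgroup_label=f"G{s+1}",
                    variety_type="wild" if rng.random() < 0.25 else "cultivar",
                )
            )

    sid_index = {s.sample_id: i for i, s in enumerate(samples)}
    pedigree: dict[str, tuple[str, str]] = {}
    for h, (fem, male) in enumerate(cfg.hybrids, start=1):
        for pid in (fem, male):
            if pid not in sid_index:
                raise ValueError(f"hybrid parent id {pid!r} unknown")
        sid = f"H{h:02d}"
        pedigree[sid] = (fem, male)
        fg = rows[sid_index[fem]]
        mg = rows[sid_index[male]]
        gam_f = fg[np.arange(n_m), rng.integers(0, 2, size=n_m)]
        gam_m = mg[np.arange(n_m), rng.integers(0, 2, size=n_m)]
        codes = np.sort(np.stack([gam_f, gam_m], axis=1), axis=1).astype(np.int8)
        rows.append(codes)
        labels[sid] = labels[fem]
        samples.append(
            SampleMeta(
                sample_id=sid,
                variety_name=f"Hybrid {h}",
                variety_type="crossbreed",
                parents=(fem, male),
                subgroup_label=samples[sid_index[fem]].subgroup_label,
            )
        )
        sid_index[sid] = len(samples) - 1

    clone_parent: dict[str, str] = {}
    if cfg.n_replicate_clones:
        parent = cfg.clone_of or samples[0].sample_id
        if parent not in sid_index:
            raise ValueError(f"clone_of sample id {parent!r} unknown")
        pg = rows[sid_index[parent]]
        for r in range(1, cfg.n_replicate_clones + 1):
            sid = f"R{r:02d}"
            codes = pg.copy()
            flip_mask = rng.random(n_m) < cfg.replicate_error
            for j in np.nonzero(flip_mask)[0]:
                codes[j] = _random_other_genotype(rng, sites[j], tuple(codes[j]))
            rows.append(codes)
            labels[sid] = labels[parent]
            clone_parent[sid] = parent
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    variety_name=samples[sid_index[parent]].variety_name,
                    subgroup_label=samples[sid_index[parent]].subgroup_label,
                )
            )
            sid_index[sid] = len(samples) - 1

    calls = np.stack(rows, axis=0)  # (n_samples, n_markers, 2)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape[:2]) < cfg.missing_rate
        calls[miss] = MISSING_CODE

    truth = SimTruth(
        subpop_labels=labels,
        ancestral_freq=p_anc,
        subpop_freq=p_sub,
        hybrid_pedigree=pedigree,
        clone_parent=clone_parent,
    )
    panel = GenotypePanel(sites, samples, calls)
    if cfg.planted_failures:
        _plant_filter_failures(rng, panel, truth, cfg.planted_failures)
    return panel, truth


def _random_other_genotype(
    rng: np.random.Generator, site: MarkerSite, current: tuple[int, int]
) -> tuple[int, int]:
    choices = [_genotype_codes(site, d) for d in range(3)]
    others = [c for c in choices if c != tuple(current)]
    return others[int(rng.integers(0, len(others)))]


# ---------------------------------------------------------------------------
# Planted filter failures
# ---------------------------------------------------------------------------

#: How each criterion's planted failure is realised (all other properties
#: of the site remain passing, so attribution is unambiguous).
_PLANT_ORDER = (
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


def _plant_filter_failures(
    rng: np.random.Generator,
    panel: GenotypePanel,
    truth: SimTruth,
    planted: dict[str, int],
) -> None:
    unknown = set(planted) - set(_PLANT_ORDER)
    if unknown:
        raise ValueError(f"unknown filter criteria: {sorted(unknown)}")
    total = sum(planted.values())
    if total > panel.n_markers:
        raise ValueError("more planted failures than markers")
    # choose distinct victim sites deterministically from the rng
    victims = rng.choice(panel.n_markers, size=total, replace=False)
    vi = iter(victims)
    n = panel.n_samples
    for crit in _PLANT_ORDER:
        for _ in range(planted.get(crit, 0)):
            j = int(next(vi))
            m = panel.markers[j]
            _make_column_clean(panel, j)
            if crit == "depth":
                m.depth_mean = 2.0
            elif crit == "maf":
                # monomorphic homozygous-ref column -> MAF = 0
                panel.calls[:, j, :] = _genotype_codes(m, 0)
            elif crit == "completeness":
                k_missing = int(np.ceil(0.4 * n))
                panel.calls[:k_missing, j, :] = MISSING_CODE
            elif crit == "qual":
                m.qual = 20.0
            elif crit == "QD":
                m.annotations["QD"] = 1.5
            elif crit == "MQ":
                m.annotations["MQ"] = 35.0
            elif crit == "FS":
                m.annotations["FS"] = 70.0
            elif crit == "SOR":
                m.annotations["SOR"] = 7.0
            elif crit == "MQRankSum":
                m.annotations["MQRankSum"] = -13.0
            elif crit == "ReadPosRankSum":
                m.annotations["ReadPosRankSum"] = -9.0
            truth.planted_failures[m.id] = crit


def _make_column_clean(panel: GenotypePanel, j: int) -> None:
    """Force site j's genotype column to pass MAF and completeness, so a
    planted failure elsewhere is the site's only failing criterion."""
    m = panel.markers[j]
    n = panel.n_samples
    ref = _genotype_codes(m, 0)
    alt = _genotype_codes(m, 2)
    half = n // 2
    panel.calls[:half, j, :] = ref
    panel.calls[half:, j, :] = alt


def planted_filter_fixture(seed: int = 0) -> tuple[GenotypePanel, SimTruth]:
    """A 20-site fixture: 10 clean sites plus one planted failure per
    filter criterion, each failure independently attributable."""
    cfg = SimConfig(
        seed=seed,
        n_markers=20,
        samples_per_subpop=(10,),
        fst=(0.1,),
        hybrids=(),
        missing_rate=0.0,
        planted_failures={c: 1 for c in _PLANT_ORDER},
    )
    panel, truth = simulate_panel(cfg)
    # force the 10 clean sites to pass MAF/completeness regardless of the
    # random draw, so exactly the planted sites fail
    for j, m in enumerate(panel.markers):
        if m.id not in truth.planted_failures:
            _make_column_clean(panel, j)
    return panel, truth


# ---------------------------------------------------------------------------
# Planted minimal discriminating sets
# ---------------------------------------------------------------------------


def plant_minimal_set(
    cfg: SimConfig, set_size: int
) -> tuple[GenotypePanel, SimTruth]:
    """Build a panel whose unique minimum discriminating-set size is known.

    Construction: samples 1..set_size+1 form a "star": sample 1 is
    homozygous-ref everywhere on the planted set S; sample i+1 differs from
    sample 1 only at S's i-th marker. Each such critical pair is then
    distinguished only by that marker (or an exact duplicate of it), so any
    discriminating set needs one marker per critical pair: the minimum size
    is exactly ``set_size``. Extra samples receive distinct random profiles
    over S; markers outside S are duplicates of S columns, so they never
    reduce the minimum.
    """
    n_samples = sum(cfg.samples_per_subpop)
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if n_samples < set_size + 1:
        raise ValueError(
            f"need at least set_size+1={set_size+1} samples, have {n_samples}"
        )
    if set_size < np.ceil(np.log2(n_samples) / np.log2(3)):
        raise ValueError(
            f"set_size {set_size} cannot give {n_samples} distinct profiles"
        )
    if cfg.n_markers < set_size:
        raise ValueError("n_markers must be >= set_size")
    rng = np.random.default_rng(cfg.seed)
    sites = _draw_sites(rng, cfg)
    n_m = cfg.n_markers
    set_idx = sorted(rng.choice(n_m, size=set_size, replace=False).tolist())

    # dosage profiles over the planted set, per sample
    profiles = np.zeros((n_samples, set_size), dtype=np.int8)
    for i in range(1, set_size + 1):
        profiles[i, i - 1] = 2
    seen = {tuple(p) for p in profiles[: set_size + 1]}
    for i in range(set_size + 1, n_samples):
        # any distinct profile is safe: the critical pairs already force
        # one marker per planted coordinate into every discriminating set
        while True:
            prof = rng.integers(0, 3, size=set_size).astype(np.int8)
            if tuple(prof) not in seen:
                break
        profiles[i] = prof
        seen.add(tuple(prof))

    calls = np.zeros((n_samples, n_m, 2), dtype=np.int8)
    duplicate_of = [int(rng.integers(0, set_size)) for _ in range(n_m)]
    for j in range(n_m):
        if j in set_idx:
            sj = set_idx.index(j)
        else:
            sj = duplicate_of[j]
        for i in range(n_samples):
            calls[i, j] = _genotype_codes(sites[j], int(profiles[i, sj]))

    samples = [SampleMeta(sample_id=f"S{i+1:02d}") for i in range(n_samples)]
    panel = GenotypePanel(sites, samples, calls)
    truth = SimTruth(
        subpop_labels={s.sample_id: 1 for s in samples},
        ancestral_freq=np.zeros(n_m),
        subpop_freq=np.zeros((1, n_m)),
        hybrid_pedigree={},
        clone_parent={},
        planted_set=[sites[j].id for j in set_idx],
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Shipped validation-table fixtures
# ---------------------------------------------------------------------------

#: SHA-256 of the shipped hand-transcribed validation tables; guards
#: against transcription drift.
FIXTURE_CHECKSUMS = {
    "table5.tsv": "d8ddb415a1c28bf7cb7a29f6196d6947c04c427dc6f9fed348b9612452436fd4",
    "table6.tsv": "2fc1a0c614ca6d8777a7b1a989b66ccca8994911acadfd629d66e5a6e1e022ec",
    "table7.tsv": "9a6af956afa7fa920a34372f999bc5c223a6dd4e340dc1e768293ec53d90e590",
}


def fixture_path(name: str) -> Path:
    res = importlib.resources.files("snpfingerprint") / "data" / name
    with importlib.resources.as_file(res) as p:
        return Path(p)


def emit_fixture_tables(outdir: str | Path) -> list[Path]:
    """Copy the shipped validation tables to ``outdir``, verifying each
    against its frozen checksum."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, expect in FIXTURE_CHECKSUMS.items():
        src = fixture_path(name)
        digest = hashlib.sha256(src.read_bytes()).hexdigest()
        if digest != expect:
            raise RuntimeError(
                f"fixture {name} checksum mismatch: {digest} != {expect}"
            )
        dst = outdir / name
        shutil.copyfile(src, dst)
        written.append(dst)
    return written
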