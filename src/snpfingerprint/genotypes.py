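"""Core data model for diploid SNP genotypes.

Holds the in-memory containers used throughout the package (allele,
genotype, marker, sample metadata, genotype panel), VCF and genotype-table
readers/writers, and the two genotype encodings used for fingerprint
display: the IUPAC single-letter code (R = A/G, Y = C/T, M = A/C, K = G/T,
S = C/G, W = A/T) and a six-way display category (four homozygote classes,
heterozygote, missing).

Genotypes are *unordered* diploid allele pairs: phase is never recorded,
so A/G and G/A compare equal. Internally a panel stores calls as an
``int8`` array of shape ``(n_samples, n_markers, 2)`` with allele codes
A=0, C=1, G=2, T=3 sorted ascending within each pair and missing calls
stored as ``(-1, -1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("snpfingerprint")

# ---------------------------------------------------------------------------
# Alleles and genotypes
# ---------------------------------------------------------------------------

BASES = "ACGT"
MISSING_CODE = -1
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}

#: IUPAC ambiguity letters for the six heterozygous base pairs.
IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}
IUPAC_TO_PAIR = {v: tuple(sorted(k)) for k, v in IUPAC_HET.items()}

#: Annotation keys recognised on a marker (GATK site-level annotations).
ANNOTATION_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


class GenotypeCategory(Enum):
    """Display category of a call, as used in fingerprint heat-map grids."""

    HOM_A = "HOM_A"
    HOM_C = "HOM_C"
    HOM_G = "HOM_G"
    HOM_T = "HOM_T"
    HET = "HET"
    MISSING = "MISSING"


class FormatError(ValueError):
    """Raised when an input file or cell cannot be interpreted."""


@dataclass(frozen=True)
class Genotype:
    """An unordered diploid genotype, or a missing call.

    ``alleles`` is ``None`` for a missing call, otherwise a 2-tuple of
    bases sorted alphabetically, so equality is insensitive to the order
    alleles were supplied in.
    """

    alleles: Optional[tuple[str, str]]

    @classmethod
    def from_alleles(cls, a: str, b: str) -> "Genotype":
        for x in (a, b):
            if x not in _BASE_TO_CODE:
                raise FormatError(f"invalid allele {x!r}")
        return cls(tuple(sorted((a, b))))  # type: ignore[arg-type]

    @classmethod
    def missing(cls) -> "Genotype":
        return cls(None)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    def __str__(self) -> str:
        if self.alleles is None:
            return "./."
        return "/".join(self.alleles)


def iupac_encode(g: Genotype, missing_symbol: str = "N") -> str:
    """Single-letter encoding: homozygotes map to their base, heterozygotes
    to the IUPAC ambiguity letter, missing to ``missing_symbol``."""
    if g.is_missing:
        return missing_symbol
    a, b = g.alleles  # type: ignore[misc]
    if a == b:
        return a
    return IUPAC_HET[frozenset((a, b))]


def iupac_decode(letter: str) -> Genotype:
    """Inverse of :func:`iupac_encode` (``N`` and ``.`` decode to missing)."""
    if letter in ("N", "."):
        return Genotype.missing()
    if letter in _BASE_TO_CODE:
        return Genotype.from_alleles(letter, letter)
    if letter in IUPAC_TO_PAIR:
        return Genotype.from_alleles(*IUPAC_TO_PAIR[letter])
    raise FormatError(f"unknown IUPAC letter {letter!r}")


def category_encode(g: Genotype) -> GenotypeCategory:
    """Six-way display category (the colour mapping lives in plotting only)."""
    if g.is_missing:
        return GenotypeCategory.MISSING
    if g.is_het:
        return GenotypeCategory.HET
    return GenotypeCategory[f"HOM_{g.alleles[0]}"]  # type: ignore[index]


# ---------------------------------------------------------------------------
# Markers, samples, panels
# ---------------------------------------------------------------------------


@dataclass
class MarkerSite:
    """One biallelic SNP locus with its site-level quality annotations."""

    id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: Optional[str] = None
    alt: Optional[str] = None
    qual: Optional[float] = None
    depth_mean: Optional[float] = None
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref is not None and self.ref == self.alt:
            raise ValueError(f"marker {self.id}: ref == alt ({self.ref})")


@dataclass
class SampleMeta:
    """Metadata for one germplasm accession."""

    sample_id: str
    variety_name: str = ""
    species_label: str = ""
    origin_label: str = ""
    variety_type: str = "cultivar"  # cultivar | wild | crossbreed
    parents: Optional[tuple[str, str]] = None  # (female_id, male_id)
    subgroup_label: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.variety_type == "crossbreed") != (self.parents is not None):
            raise ValueError(
                f"sample {self.sample_id}: parents must be present iff "
                f"variety_type is 'crossbreed'"
            )


class GenotypePanel:
    """A samples x markers genotype matrix with marker and sample metadata.

    ``calls`` has shape ``(n_samples, n_markers, 2)``, dtype int8, allele
    codes sorted ascending within each pair, missing = ``(-1, -1)``.
    """

    def __init__(
        self,
        markers: Sequence[MarkerSite],
        samples: Sequence[SampleMeta],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(samples)}, {len(markers)}, 2)"
            )
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")
        sids = [s.sample_id for s in samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        # canonicalise: sort allele pair, force missing to (-1, -1)
        calls = np.sort(calls, axis=2)
        missing = (calls < 0).any(axis=2)
        calls[missing] = MISSING_CODE
        self.markers = list(markers)
        self.samples = list(samples)
        self.calls = calls
        self._marker_index = {m.id: j for j, m in enumerate(self.markers)}
        self._sample_index = {s.sample_id: i for i, s in enumerate(self.samples)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def genotype(self, sample: int | str, marker: int | str) -> Genotype:
        i = sample if isinstance(sample, int) else self.sample_index(sample)
        j = marker if isinstance(marker, int) else self.marker_index(marker)
        a, b = self.calls[i, j]
        if a < 0:
            return Genotype.missing()
        return Genotype(tuple(sorted((BASES[a], BASES[b]))))  # type: ignore[arg-type]

    def set_genotype(self, sample: int | str, marker: int | str, g: Genotype) -> None:
        i = sample if isinstance(sample, int) else self.sample_index(sample)
        j = marker if isinstance(marker, int) else self.marker_index(marker)
        self.calls[i, j] = genotype_to_codes(g)

    # -- derived views -------------------------------------------------------

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypePanel(
            [self.markers[j] for j in idx], self.samples, self.calls[:, idx].copy()
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypePanel(
            self.markers, [self.samples[i] for i in idx], self.calls[idx].copy()
        )

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_markers) mask of missing calls."""
        return self.calls[:, :, 0] < 0

    def dosage_matrix(self) -> np.ndarray:
        """Alternate-allele dosage (0/1/2), NaN where missing.

        Requires ref/alt on every marker.
        """
        alt_codes = []
        for m in self.markers:
            if m.alt is None:
                raise ValueError(f"marker {m.id} has no alt allele; cannot form dosage")
            alt_codes.append(_BASE_TO_CODE[m.alt])
        alt = np.asarray(alt_codes, dtype=np.int8)[None, :, None]
        dose = (self.calls == alt).sum(axis=2).astype(float)
        dose[self.missing_mask()] = np.nan
        return dose

    def to_frame(self) -> pd.DataFrame:
        """Genotype strings as a markers x samples DataFrame (table layout)."""
        data = {
            s.sample_id: [str(self.genotype(i, j)) for j in range(self.n_markers)]
            for i, s in enumerate(self.samples)
        }
        return pd.DataFrame(data, index=self.marker_ids)

    def __repr__(self) -> str:
        return f"GenotypePanel({self.n_samples} samples x {self.n_markers} markers)"


def genotype_to_codes(g: Genotype) -> tuple[int, int]:
    if g.is_missing:
        return (MISSING_CODE, MISSING_CODE)
    a, b = g.alleles  # type: ignore[misc]
    return (_BASE_TO_CODE[a], _BASE_TO_CODE[b])


# ---------------------------------------------------------------------------
# Genotype-table reading (fingerprint validation tables)
# ---------------------------------------------------------------------------


def parse_genotype_cell(cell: str) -> tuple[Genotype, Optional[str]]:
    """Parse one genotype-table cell into ``(genotype, reference_base)``.

    Two dialects occur in published fingerprint-validation tables:

    * plain two-base cells, ``"A/G"`` or ``"T/T"``: the unordered diploid
      genotype; no reference base recorded;
    * call-vs-reference cells containing one IUPAC ambiguity letter,
      ``"R/A"`` (or, order-transposed, ``"G/R"``): the ambiguity letter is
      the sample call (here the heterozygote A/G) and the plain base is the
      reference-genome base;
    * single letters, ``"R"`` or ``"T"`` or ``"N"``: IUPAC-decoded.

    Missing is spelled ``"./."``, ``"N"`` or ``"N/N"``.
    """
    cell = cell.strip()
    if cell in ("./.", "N", ".", "N/N", ""):
        return Genotype.missing(), None
    if "/" not in cell:
        return iupac_decode(cell), None
    parts = cell.split("/")
    if len(parts) != 2:
        raise FormatError(f"cannot parse genotype cell {cell!r}")
    a, b = parts[0].strip(), parts[1].strip()
    amb_a, amb_b = a in IUPAC_TO_PAIR, b in IUPAC_TO_PAIR
    if amb_a and amb_b:
        raise FormatError(f"two ambiguity letters in one cell: {cell!r}")
    if amb_a:
        return iupac_decode(a), (b if b in _BASE_TO_CODE else None)
    if amb_b:
        return iupac_decode(b), (a if a in _BASE_TO_CODE else None)
    return Genotype.from_alleles(a, b), None


def _normalise_marker_id(name: str) -> str:
    # "Marker 1" and "Marker1" refer to the same locus across printed tables
    return name.strip().replace(" ", "")


def _normalise_sample_id(name: str) -> str:
    # strip the "(REF/ALT)" suffix printed in table headers
    name = name.strip()
    if name.endswith("(REF/ALT)"):
        name = name[: -len("(REF/ALT)")].strip()
    return name


def read_genotype_table(path: str | Path) -> GenotypePanel:
    """Read a TSV/CSV genotype table (marker rows x sample columns).

    The first column holds marker names; remaining columns are samples.
    Cells follow :func:`parse_genotype_cell`. Marker names are normalised
    by removing internal spaces; a ``"(REF/ALT)"`` suffix on sample headers
    is stripped. The reference base, where a cell records one, is stored on
    the marker (first one seen wins).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str)
    marker_col = raw.columns[0]
    raw = raw.set_index(marker_col)
    marker_ids = [_normalise_marker_id(m) for m in raw.index]
    sample_ids = [_normalise_sample_id(c) for c in raw.columns]
    n_s, n_m = len(sample_ids), len(marker_ids)
    calls = np.full((n_s, n_m, 2), MISSING_CODE, dtype=np.int8)
    refs: list[Optional[str]] = [None] * n_m
    for j, (mid, row) in enumerate(zip(marker_ids, raw.itertuples(index=False))):
        for i, cell in enumerate(row):
            try:
                g, ref = parse_genotype_cell(str(cell))
            except FormatError as e:
                raise FormatError(
                    f"row {mid!r}, column {sample_ids[i]!r}: {e}"
                ) from None
            calls[i, j] = genotype_to_codes(g)
            if ref is not None and refs[j] is None:
                refs[j] = ref
    markers = [
        MarkerSite(id=mid, chrom="unknown", pos=j + 1, ref=refs[j], alt=None)
        for j, mid in enumerate(marker_ids)
    ]
    samples = [SampleMeta(sample_id=s) for s in sample_ids]
    return GenotypePanel(markers, samples, calls)


def write_genotype_table(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as a marker-rows x sample-columns TSV ("A/G" cells)."""
    df = panel.to_frame()
    df.index.name = "Marker"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF reading and writing (via pysam)
# ---------------------------------------------------------------------------

_MEAN_DEPTH_INFO = "DPM"


def read_vcf(
    path: str | Path,
    sample_subset: Optional[Sequence[str]] = None,
    multiallelic: str = "drop",
) -> GenotypePanel:
    """Read biallelic SNPs from a VCF into a :class:`GenotypePanel`.

    Non-SNP records (indels, symbolic alleles) are skipped with a logged
    count. Multi-allelic records are dropped by default or split into
    per-alt biallelic sites under ``multiallelic="split"`` (calls carrying
    a different alt become missing at the split site). Phase is discarded.
    """
    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        all_samples = list(vf.header.samples)
        if sample_subset is not None:
            missing = set(sample_subset) - set(all_samples)
            if missing:
                raise KeyError(f"samples not in VCF: {sorted(missing)}")
            use = list(sample_subset)
        else:
            use = all_samples
        sample_pos = {s: k for k, s in enumerate(all_samples)}
        markers: list[MarkerSite] = []
        cols: list[np.ndarray] = []
        n_skipped = 0
        counter = 0
        for rec in vf:
            alts = rec.alts or ()
            is_snp = (
                len(rec.ref or "") == 1
                and rec.ref in BASES
                and len(alts) >= 1
                and all(len(a) == 1 and a in BASES for a in alts)
            )
            if not is_snp:
                n_skipped += 1
                continue
            if len(alts) > 1:
                if multiallelic == "drop":
                    n_skipped += 1
                    continue
                split_alts = list(alts)
            else:
                split_alts = [alts[0]]
            if "GT" not in rec.format:
                raise FormatError(
                    f"record {rec.chrom}:{rec.pos} has no GT field"
                )
            # allele strings per sample
            sample_alleles: list[tuple] = []
            for s in use:
                sample_alleles.append(rec.samples[s].alleles)
            for alt in split_alts:
                counter += 1
                mid = rec.id if (rec.id and len(split_alts) == 1) else (
                    rec.id or f"{rec.chrom}_{rec.pos}"
                )
                if len(split_alts) > 1:
                    mid = f"{mid}_{alt}"
                ann = {
                    k: float(rec.info[k])
                    for k in ANNOTATION_KEYS
                    if k in rec.info and rec.info[k] is not None
                }
                depth_mean = _mean_depth(rec, use)
                markers.append(
                    MarkerSite(
                        id=mid,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=rec.qual,
                        depth_mean=depth_mean,
                        annotations=ann,
                    )
                )
                allowed = {rec.ref, alt}
                col = np.full((len(use), 2), MISSING_CODE, dtype=np.int8)
                for i, alleles in enumerate(sample_alleles):
                    if (
                        alleles is None
                        or len(alleles) != 2
                        or any(a is None for a in alleles)
                    ):
                        continue
                    if not set(alleles) <= allowed:
                        continue  # carries a different alt at a split site
                    col[i, 0] = _BASE_TO_CODE[alleles[0]]
                    col[i, 1] = _BASE_TO_CODE[alleles[1]]
                cols.append(col)
        if n_skipped:
            logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    calls = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((len(use), 0, 2), dtype=np.int8)
    )
    samples = [SampleMeta(sample_id=s) for s in use]
    return GenotypePanel(markers, samples, calls)


def _mean_depth(rec, sample_ids: Sequence[str]) -> Optional[float]:
    if _MEAN_DEPTH_INFO in rec.info:
        return float(rec.info[_MEAN_DEPTH_INFO])
    depths = []
    for s in sample_ids:
        fmt = rec.samples[s]
        if "DP" in fmt and fmt["DP"] is not None:
            depths.append(float(fmt["DP"]))
    if depths:
        return float(np.mean(depths))
    if "DP" in rec.info and rec.info["DP"] is not None:
        return float(rec.info["DP"]) / max(len(sample_ids), 1)
    return None


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as an uncompressed VCF 4.2 file.

    Round-trip guarantee: ``read_vcf(write_vcf(p))`` reproduces chrom, pos,
    ref, alt and genotype calls exactly. Site quality, mean depth and the
    site annotations are carried in QUAL and INFO.
    """
    if panel.n_markers == 0:
        raise ValueError("cannot write a VCF with no markers")
    for m in panel.markers:
        if m.ref is None or m.alt is None:
            raise ValueError(f"marker {m.id} lacks ref/alt alleles; cannot write VCF")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        f'##INFO=<ID={_MEAN_DEPTH_INFO},Number=1,Type=Float,'
        'Description="Mean per-sample depth">'
    )
    for k in ANNOTATION_KEYS:
        header.add_line(
            f'##INFO=<ID={k},Number=1,Type=Float,Description="Site annotation {k}">'
        )
    for chrom in dict.fromkeys(m.chrom for m in panel.markers):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in panel.sample_ids:
        header.add_sample(s)
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        order = sorted(
            range(panel.n_markers),
            key=lambda j: (panel.markers[j].chrom, panel.markers[j].pos),
        )
        for j in order:
            m = panel.markers[j]
            rec = out.new_record(
                contig=m.chrom, start=m.pos - 1, alleles=(m.ref, m.alt), id=m.id
            )
            rec.qual = m.qual
            if m.depth_mean is not None:
                rec.info[_MEAN_DEPTH_INFO] = m.depth_mean
            for k, v in m.annotations.items():
                rec.info[k] = v
            allele_to_index = {m.ref: 0, m.alt: 1}
            for i, s in enumerate(panel.sample_ids):
                g = panel.genotype(i, j)
                if g.is_missing:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    try:
                        gt = tuple(allele_to_index[a] for a in g.alleles)  # type: ignore[union-attr]
                    except KeyError:
                        raise ValueError(
                            f"call {g} at {m.id} not representable with "
                            f"ref={m.ref}, alt={m.alt}"
                        ) from None
                    rec.samples[s]["GT"] = gt
                rec.samples[s].phased = False
            out.write(rec)


def write_sample_metadata(panel: GenotypePanel, path: str | Path) -> None:
    rows = []
    for s in panel.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "variety_name": s.variety_name,
                "species_label": s.species_label,
                "origin_label": s.origin_label,
                "variety_type": s.variety_type,
                "female_parent": s.parents[0] if s.parents else "",
                "male_parent": s.parents[1] if s.parents else "",
                "subgroup_label": s.subgroup_label or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def combine_panels(a: GenotypePanel, b: GenotypePanel) -> GenotypePanel:
    """Stack the samples of two panels sharing the same marker ids."""
    if a.marker_ids != b.marker_ids:
        b = b.subset_markers(a.marker_ids)  # raises if any id is absent
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"duplicate sample ids across panels: {sorted(overlap)}")
    markers = []
    for ma, mb in zip(a.markers, b.markers):
        m = replace(ma)
        if m.ref is None:
            m.ref = mb.ref
        markers.append(m)
    return GenotypePanel(
        markers, a.samples + b.samples, np.concatenate([a.calls, b.calls], axis=0)
    )
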