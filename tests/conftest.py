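import numpy as np
import pytest

import snpfingerprint as sf


@pytest.fixture(scope="session")
def table5():
    return sf.read_genotype_table(sf.fixture_path("table5.tsv"))


@pytest.fixture(scope="session")
def table6():
    return sf.read_genotype_table(sf.fixture_path("table6.tsv"))


@pytest.fixture(scope="session")
def table7():
    return sf.read_genotype_table(sf.fixture_path("table7.tsv"))


@pytest.fixture(scope="session")
def combined_validation_panel(table5, table7):
    """The seven validation varieties over the 15 fingerprint markers."""
    return sf.combine_panels(table5, table7)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated panel: 39 samples (incl. hybrids), 300 markers."""
    cfg = sf.SimConfig(seed=11, n_markers=300)
    return sf.simulate_panel(cfg)


def tiny_panel(rows, sample_ids=None, chrom="chr1"):
    """Build a GenotypePanel from genotype-string rows (markers x samples).

    ``rows`` maps marker id -> list of cell strings ("A/G", "./.", ...).
    """
    marker_ids = list(rows)
    n_samples = len(next(iter(rows.values())))
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n_samples)]
    markers = [
        sf.MarkerSite(id=m, chrom=chrom, pos=j + 1) for j, m in enumerate(marker_ids)
    ]
    samples = [sf.SampleMeta(sample_id=s) for s in sample_ids]
    calls = np.full((n_samples, len(marker_ids), 2), -1, dtype=np.int8)
    from snpfingerprint.genotypes import genotype_to_codes

    for j, m in enumerate(marker_ids):
        for i, cell in enumerate(rows[m]):
            g, _ = sf.parse_genotype_cell(cell)
            calls[i, j] = genotype_to_codes(g)
    return sf.GenotypePanel(markers, samples, calls)
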