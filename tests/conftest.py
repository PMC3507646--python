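import numpy as np
import pandas as pd
import pytest

from planaflex.align import DEFAULT_SCHEME, LocalAlignment
from planaflex.io import RunConfig
from planaflex.profile import HomologPair, MatchProfile
from planaflex.synth import SubstitutionSpectrum


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture
def desk_config():
    """Filter settings scaled to short (100-codon) simulated genes."""
    return RunConfig(min_query_len_nt=150, max_evalue_pair=1e-30,
                     min_region_nt=80)


@pytest.fixture(scope="session")
def two_function_spectra():
    """Planted high- vs low-substitution regimes (expected ratios 0.7 / 0.9)."""
    return {
        "metabolism": SubstitutionSpectrum(0.63, 0.27, 0.10, length_codons=100),
        "information": SubstitutionSpectrum(0.81, 0.09, 0.10, length_codons=100),
    }


def make_pair(query_id="q", subject_id="s", i=20, h=5, m=2, g=1,
              evalue=1e-40, query_len_nt=900) -> HomologPair:
    """A HomologPair with prescribed metadata (no real alignment needed)."""
    cols = i + h + m + g
    aln = LocalAlignment(query_id, subject_id, "A" * cols, "A" * cols, 1,
                         evalue=evalue)
    profile = MatchProfile(i, h, m, g)
    ratio = i / (i + h) if i + h else None
    return HomologPair(query_id, subject_id, aln, profile, ratio, query_len_nt)


@pytest.fixture
def evidence_frame():
    return pd.DataFrame([
        {"gene_id": "g1", "dataset": "d1", "channel": "genome_map", "evalue": 1e-8},
        {"gene_id": "g1", "dataset": "d1", "channel": "predicted_proteins", "evalue": 1e-12},
        {"gene_id": "g2", "dataset": "d1", "channel": "genome_map", "evalue": 1e-2},
    ])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
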