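import numpy as np
import pandas as pd
import pytest

from mrpipe.harmonize import PAIR_COLUMNS, HarmonizedSet
from mrpipe.sumstats_io import SummaryStats
from mrpipe.synthetic import SimulationConfig, simulate_pair


def make_hset(gamma, Gamma, se_gamma=None, se_Gamma=None, eaf=0.3) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (unit SEs by default)."""
    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    n = len(gamma)
    se_gamma = np.full(n, 0.01) if se_gamma is None else np.asarray(se_gamma, float)
    se_Gamma = np.ones(n) if se_Gamma is None else np.asarray(se_Gamma, float)
    pairs = pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)],
        "chrom": "1", "pos": np.arange(n) * 100_000 + 1,
        "gamma": gamma, "se_gamma": se_gamma,
        "Gamma": Gamma, "se_Gamma": se_Gamma,
        "eaf": eaf, "palindromic": False, "action": "aligned",
    }, columns=PAIR_COLUMNS)
    return HarmonizedSet("exposure", "outcome", pairs)


def make_sumstats(rows, trait_id="trait", trait_type="microbe_taxon") -> SummaryStats:
    """SummaryStats from a list of dicts; unspecified fields get sane defaults."""
    defaults = {"chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "beta": 0.1, "se": 0.02, "pval": 1e-6, "n": 10_000.0}
    table = []
    for i, row in enumerate(rows):
        rec = {"variant_id": f"rs{i}", **defaults, **row}
        table.append(rec)
    df = pd.DataFrame(table)[["variant_id"] + list(defaults)]
    return SummaryStats(trait_id, trait_type, df)


@pytest.fixture
def simulated_pair():
    """A moderate simulated exposure/outcome pair with true effect 0.3."""
    cfg = SimulationConfig(n_variants=50, causal_beta=0.3, seed=1)
    return simulate_pair(cfg)


@pytest.fixture
def sumstats_file(tmp_path):
    """A 5-row valid summary-stats TSV on disk."""
    path = tmp_path / "sumstats.tsv"
    path.write_text(
        "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
        "rs1\t1\t1000\tA\tG\t0.30\t0.10\t0.02\t1e-6\t10000\n"
        "rs2\t1\t2000\tC\tT\t0.10\t-0.20\t0.05\t2e-5\t10000\n"
        "rs3\t2\t5000\tG\tA\t0.45\t0.05\t0.01\t0.5\t10000\n"
        "rs4\t3\t8000\tT\tC\tNA\t0.30\t0.10\t1e-3\tNA\n"
        "rs5\t4\t9000\tA\tC\t0.25\t0.15\t0.03\t5e-7\t10000\n"
    )
    return path
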