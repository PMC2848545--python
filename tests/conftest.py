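import pandas as pd
import pytest

from pathcom import FactorOrder, SyntheticConfig, generate_group_medians


@pytest.fixture(scope="session")
def assoc2() -> FactorOrder:
    """Two-factor assembly pathway A: TBP (T) first, then TFIIB (B)."""
    return FactorOrder("TB")


@pytest.fixture(scope="session")
def assoc3() -> FactorOrder:
    """Three-factor in-vitro assembly order: TBP, TFIIB, pol II."""
    return FactorOrder("TBP")


@pytest.fixture(scope="session")
def archetype3(assoc3) -> pd.DataFrame:
    """The eight three-factor H/L archetype groups (L = 5%, H = 40%)."""
    assoc, table = generate_group_medians(n_factors=3)
    assert assoc.codes == assoc3.codes
    return table


@pytest.fixture(scope="session")
def small_probe_config() -> SyntheticConfig:
    """Desk-scale synthetic probe design: full archetype structure, few genes."""
    return SyntheticConfig(
        n_factors=3,
        genes_per_pattern=40,
        n_genes_total=320,
        n_probes_total=1200,
        n_tt_probes=300,
        sigma=0.1,
        seed=11,
    )
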