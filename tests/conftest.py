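import numpy as np
import pandas as pd
import pytest

from rhizogwas.genotypes import GenotypeMatrix, filter_variants, mean_impute
from rhizogwas.lmm import kinship
from rhizogwas.simulate import SimConfig, simulate_genotypes

# small structured panel shared by the statistical tests: two replicons
# with contrasting block lengths, clonal clades, missingness and PAVs
SMALL_CONFIG = SimConfig(
    n_strains=80,
    n_clades=8,
    within_clade_mutations=10,
    replicon_spec=[("chromosome", 500_000, 250), ("pSymA", 150_000, 120)],
    ld_block_length={"chromosome": 50_000, "pSymA": 1_000},
    n_pav_genes=80,
    missing_rate=0.15,
    het_rate=0.01,
    seed=1234,
)


@pytest.fixture(scope="session")
def small_panel():
    G = filter_variants(simulate_genotypes(SMALL_CONFIG))
    return G


@pytest.fixture(scope="session")
def small_imputed(small_panel):
    return mean_impute(small_panel)


@pytest.fixture(scope="session")
def small_kinship(small_imputed):
    return kinship(small_imputed)


def toy_matrix(columns: dict[str, list], vtype="SNP", replicon="chromosome"):
    """Build a GenotypeMatrix from named dosage columns (None = missing)."""
    ids = list(columns)
    dosage = np.array(
        [[np.nan if v is None else float(v) for v in columns[c]] for c in ids]
    ).T
    variants = pd.DataFrame(
        {
            "id": ids,
            "vtype": vtype,
            "replicon": replicon,
            "position": pd.array(range(100, 100 + 100 * len(ids), 100),
                                 dtype="Int64"),
        }
    )
    strains = [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(strains, dosage, variants)
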