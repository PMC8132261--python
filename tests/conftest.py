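import io

import numpy as np
import pandas as pd
import pytest

from covcoloc.sumstats import AssocTable, StudyMeta, default_study_panel


def make_table(meta, rows):
    """Build an AssocTable from (chrom, pos, ref, alt, beta, se, p, eaf) rows."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                     "beta", "se", "p", "eaf"])
    return AssocTable(meta, df)


@pytest.fixture
def meta_a():
    return StudyMeta(study_id="C2_eur_with_ukbb", phenotype="C2",
                     ancestry="eur", controls="with_ukbb",
                     n_total=100_000, n_cases=5_000)


@pytest.fixture
def meta_b():
    return StudyMeta(study_id="C2_multi_with_ukbb", phenotype="C2",
                     ancestry="multi", controls="with_ukbb",
                     n_total=100_000, n_cases=5_000)


@pytest.fixture
def panel():
    return default_study_panel()


@pytest.fixture
def toy_gwas_tsv():
    """A 3-row HGI-dialect TSV stream."""
    text = (
        "#CHR\tPOS\tREF\tALT\tall_inv_var_meta_beta\tall_inv_var_meta_sebeta"
        "\tall_inv_var_meta_p\tall_meta_AF\tall_inv_var_meta_cases"
        "\tall_inv_var_meta_controls\n"
        "3\t101\tA\tG\t0.30\t0.10\t2.7e-3\t0.25\t5000\t95000\n"
        "3\t55\tC\tT\t-0.10\t0.10\t0.317\t0.40\t5000\t95000\n"
        "3\t200\tG\tA\t0.05\t0.10\t0.617\t0.10\t5000\t95000\n"
    )
    return io.StringIO(text)
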