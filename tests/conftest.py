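import numpy as np
import pandas as pd
import pytest

from modnet import synthio


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated study shared across read-only tests."""
    return synthio.simulate_study(
        n_genes=400, n_shared=600, n_unique_per_subject=120, n_planted=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    """The small bundle materialized on disk."""
    d = tmp_path_factory.mktemp("bundle")
    paths = small_bundle.write(d)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_variant_frame(rows):
    """Helper: build a variant record table from compact row dicts."""
    defaults = {
        "chrom": "chr1", "pos": 100, "ref": "A", "alt": "T",
        "gene_symbol": "GENE", "biotype": "protein_coding",
        "hgvsc": None, "hgvsp": None, "allele_frequency": None,
        "cadd_phred": 10.0, "pli": None, "zygosity": "het",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["pos"] = 100 + i
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out, columns=list(defaults))
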