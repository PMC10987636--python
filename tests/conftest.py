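import numpy as np
import pandas as pd
import pytest

import scartrace as st


def noise_free_config(seed=0, **overrides):
    """The noise-free benchmark scenario: no dropout/chimeras/doublets, no
    recurrent scar outcomes, no homozygous edits, noiseless UMI counts."""
    fields = dict(
        seed=seed,
        unique_scar_ids=True,
        allow_homozygous=False,
        p_allele_dropout=0.0,
        p_chimeric=0.0,
        doublet_rate=0.0,
        umi_count_distribution=("constant", 10.0),
    )
    fields.update(overrides)
    return st.SimConfig(**fields)


def run_pipeline(result, **kwargs):
    """filter + clone identification on a simulated dataset."""
    alleles = st.filter_alleles(result.scartable)
    wildtype_ids = {t: r.wildtype_id() for t, r in result.tree.references.items()}
    return alleles, st.identify_clones(alleles, wildtype_ids, **kwargs)


@pytest.fixture(scope="session")
def noise_free_result():
    return st.simulate_dataset(noise_free_config(seed=0))


@pytest.fixture(scope="session")
def noisy_result():
    return st.simulate_dataset(st.SimConfig(seed=0))


@pytest.fixture
def toy_reference():
    rng = np.random.default_rng(1234)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    return st.TargetReference(target="toy", sequence=seq, cut_site=50, primer=seq[:15])


def retained_table(rows):
    """Build an AlleleTable-like retained DataFrame from (cell, target, ids)."""
    out = []
    for cell, target, ids in rows:
        for i in ids:
            out.append((cell, target, i, 10))
    return pd.DataFrame(out, columns=["cell", "target", "seq_id", "umi_count"])
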