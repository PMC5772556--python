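import numpy as np
import pandas as pd
import pytest

from predcrp import (
    DescriptorSpec,
    SynthConfig,
    feature_matrix,
    generate_dataset,
)


@pytest.fixture(scope="session")
def synthetic_clean():
    """169-site noise-free dataset mirroring the curated CRP collection."""
    cfg = SynthConfig(n_sites=169, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def synthetic_features(synthetic_clean):
    dataset, truth = synthetic_clean
    return feature_matrix(dataset, DescriptorSpec()), dataset, truth


def make_site_table(path, rows):
    """Write a minimal RegulonDB-dialect TSV from row dicts."""
    cols = [
        "site_id", "tf_name", "gene", "left", "right", "tss",
        "strand", "sequence", "evidence", "role",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)
    return path


def site_row(i, *, tf="CRP", left=940, seq=None, tss=1000, strand="+",
             evidence="strong", role="activator"):
    seq = seq if seq is not None else "A" * 22
    return {
        "site_id": f"s{i}",
        "tf_name": tf,
        "gene": f"g{i}",
        "left": left,
        "right": left + len(seq) - 1,
        "tss": tss,
        "strand": strand,
        "sequence": seq,
        "evidence": evidence,
        "role": role,
    }
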