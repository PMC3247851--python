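import numpy as np
import pandas as pd
import pytest

from poolplan.io_beads import BEAD_COLUMNS, FrequencyTable


def make_beads(rows, array_id="a1", pool_id="p1", strip_id="s1", snp_id="rs1"):
    """Bead DataFrame from (green, red) pairs, all on one SNP by default."""
    return pd.DataFrame(
        {
            "array_id": array_id,
            "pool_id": pool_id,
            "strip_id": strip_id,
            "snp_id": snp_id,
            "green": [g for g, _ in rows],
            "red": [r for _, r in rows],
        },
        columns=BEAD_COLUMNS,
    )


def make_ft(array_id, freqs, pool_id=None, n_beads=17):
    """FrequencyTable from a mapping snp_id -> frequency (or a sequence)."""
    if not isinstance(freqs, dict):
        freqs = {f"snp{i:03d}": f for i, f in enumerate(freqs)}
    data = pd.DataFrame(
        {"freq": list(freqs.values()), "n_beads": n_beads},
        index=pd.Index(list(freqs.keys()), name="snp_id"),
    )
    return FrequencyTable(array_id=array_id, data=data, pool_id=pool_id)


def random_ft(array_id, n_snps, rng, pool_id=None):
    return make_ft(array_id, rng.uniform(0.05, 0.95, n_snps), pool_id=pool_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
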