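import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from auxiaa.seqio import SequenceRecord


@pytest.fixture()
def planted_motif_proteins():
    """20 random-background proteins, each with one planted VGWPPVKA."""
    rng = np.random.default_rng(5)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for i in range(20):
        bg = "".join(rng.choice(aa, size=60))
        pos = int(rng.integers(0, 52))
        records.append(
            SequenceRecord(f"s{i}", "protein", bg[:pos] + "VGWPPVKA" + bg[pos:])
        )
    return records


@pytest.fixture()
def canonical_protein():
    """A scaffold carrying all five motifs and intact NLSs."""
    from auxiaa.simulate import plant_motifs_and_nls

    return plant_motifs_and_nls(
        [frozenset({"m1", "m2", "m3", "m4", "m5"})], seed=7
    )[0]
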