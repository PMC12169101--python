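import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from forestdiv.data_model import StudyCommunity

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def toy_pair():
    """The worked managed/reference pair: ratios {0.5, 1, 0}, two shared species."""
    managed = StudyCommunity(
        study_id="s1", source_id="p1", system="AG",
        species_mean_abundance={"sp a": 5.0, "sp b": 10.0, "sp d": 4.0}, n_sites=1,
    )
    reference = StudyCommunity(
        study_id="s1", source_id="p1", system="REFERENCE",
        species_mean_abundance={"sp a": 10.0, "sp b": 5.0, "sp c": 2.0}, n_sites=1,
    )
    return managed, reference


@pytest.fixture
def abundance_frame():
    """Small valid site-level table: one study, 2 reference + 1 managed site."""
    return pd.DataFrame(
        {
            "source_id": ["p1"] * 5,
            "study_id": ["s1"] * 5,
            "site_id": ["r1", "r1", "r2", "m1", "m1"],
            "system": ["REFERENCE", "REFERENCE", "REFERENCE", "AG", "AG"],
            "taxon_name": ["Panthera onca", "Ara macao", "Panthera onca",
                           "Panthera onca", "Ara macao"],
            "taxon_group": ["mammals", "birds", "mammals", "mammals", "birds"],
            "abundance": [8.0, 4.0, 12.0, 5.0, 2.0],
        }
    )


def random_community_pair(rng):
    """A random managed/reference pair for oracle comparisons."""
    n_ref = rng.integers(1, 15)
    n_shared = rng.integers(0, n_ref + 1)
    n_novel = rng.integers(0, 6)
    ref = {f"sp{i}": float(rng.uniform(0.1, 20)) for i in range(n_ref)}
    man = {f"sp{i}": float(rng.uniform(0.05, 30)) for i in range(n_shared)}
    man.update({f"new{i}": float(rng.uniform(0.1, 10)) for i in range(n_novel)})
    managed = StudyCommunity("s", "p", "SC", man, 1)
    reference = StudyCommunity("s", "p", "REFERENCE", ref, 1)
    return managed, reference


def naive_metrics(man: dict, ref: dict):
    """Brute-force per-species reference implementation of the four metrics.

    Implements the definitions directly with explicit loops, independent of
    the package's batch code path.
    """
    ratios = []
    for sp, a_r in ref.items():
        a_m = man.get(sp, 0.0)
        r = a_m / a_r
        if r > 1:
            r = 1.0
        ratios.append(r)
    IN = sum(ratios) / len(ref)
    shared = 0
    for sp in ref:
        if sp in man and man[sp] > 0:
            shared += 1
    only_ref = len(ref) - shared
    only_man = sum(1 for sp in man if sp not in ref and man[sp] > 0)
    SI = (2 * shared) / (2 * shared + only_ref + only_man)
    s_m = sum(1 for sp in man if man[sp] > 0)
    SR = np.log(s_m / len(ref)) if s_m > 0 else None
    tot_m = sum(man.values())
    tot_r = sum(ref.values())
    TA = np.log(tot_m / tot_r) if tot_m > 0 and tot_r > 0 else None
    return IN, SI, SR, TA
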