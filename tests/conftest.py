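import itertools

import pytest

from dupevol.rates import PairwiseRates, RateMatrix


def matrix_from_ds(ds: dict, dn: dict | None = None,
                   family_id: str = "toy") -> RateMatrix:
    """Build a RateMatrix from {('a','b'): dS, ...} for selection tests."""
    ids = sorted({g for pair in ds for g in pair})
    pairs = {}
    for a, b in itertools.combinations(ids, 2):
        key = (a, b) if (a, b) in ds else (b, a)
        ds_v = ds[key]
        dn_v = (dn or {}).get(key, 0.1 * ds_v)
        pairs[frozenset((a, b))] = PairwiseRates(
            a, b, 100.0, 200.0, 0.0, 0.0, 100, 0.0, 0.0, ds_v, dn_v,
            saturated=ds_v != ds_v)  # NaN dS marks saturation in these toys
    return RateMatrix(family_id, ids, pairs)


@pytest.fixture(scope="session")
def small_truth():
    """One deterministic simulated duplication family shared across tests."""
    from dupevol.simulate import duplication_scenario

    return duplication_scenario(pair_depth=0.1, outgroup_depth=0.5,
                                omega=0.3, n_codons=600, seed=42)
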