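import pytest

from strtier.catalog import load_bundled_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_bundled_catalog()


@pytest.fixture(scope="session")
def fxn(catalog):
    return catalog["FXN"]


@pytest.fixture(scope="session")
def fmr1(catalog):
    return catalog["FMR1"]


def brute_force_cost(seq, motifs, interruption_penalty=1.0, switch_penalty=2.0):
    """Exhaustive minimal segmentation cost (independent of the DP)."""
    best = [float("inf")]

    def rec(i, last, cost):
        if cost >= best[0]:
            return
        if i == len(seq):
            best[0] = cost
            return
        rec(i + 1, last, cost + interruption_penalty)
        for m in motifs:
            if seq.startswith(m, i):
                rec(
                    i + len(m),
                    m,
                    cost + (switch_penalty if last is not None and m != last else 0.0),
                )

    rec(0, None, 0.0)
    return best[0]
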