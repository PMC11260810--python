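import numpy as np
import pytest

from cubkit.genetic_code import standard_code
from cubkit.simulate import SimulationConfig, simulate_corpus


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def small_corpus():
    """A small neutral corpus with all annotation channels populated."""
    cfg = SimulationConfig(n_yeasts=3, n_orfs_per_yeast=60, seed=7)
    return simulate_corpus(cfg)


def random_orf(rng: np.random.Generator, code, n_codons: int) -> str:
    """Random in-frame coding sequence over the sense codons."""
    sense = code.sense_codons
    return "".join(sense[i] for i in rng.integers(0, len(sense), n_codons))


def brute_force_rscu(seq: str, code) -> dict[str, float]:
    """Independent RSCU oracle: literal frequency / expected-frequency
    computation, written directly from the definition."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    out: dict[str, float] = {}
    for aa, fam in code.families.items():
        if len(fam) < 2:
            continue
        fam_counts = {c: codons.count(c) for c in fam}
        total = sum(fam_counts.values())
        for c in fam:
            if total == 0:
                out[c] = float("nan")
            else:
                freq = fam_counts[c] / total
                expected = 1.0 / len(fam)
                out[c] = freq / expected
    return out
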