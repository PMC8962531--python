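import numpy as np
import pytest

from wgsval.intervals import Interval, IntervalSet
from wgsval.variants import CallSet, Variant


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def region_100kb():
    return IntervalSet([Interval("chr1", 0, 100_000)])


def random_callset_pair(rng, n_truth=30, region_length=10_000, sample="S0",
                        fn_rate=0.2, fp_rate=0.1, gt_flip=0.1):
    """Small truth/eval pair of SNVs with injected discordance, for oracle
    comparisons.  Returns (truth, eval) CallSets sharing positions."""
    positions = rng.choice(np.arange(2, region_length), size=n_truth, replace=False)
    bases = "ACGT"
    truth, ev = [], []
    for pos in sorted(int(p) for p in positions):
        ref, alt = [bases[i] for i in rng.choice(4, size=2, replace=False)]
        gt = "het" if rng.random() < 0.6 else "hom_alt"
        v = Variant("chr1", pos, ref, alt, gt, sample)
        truth.append(v)
        r = rng.random()
        if r < fn_rate:
            continue
        if r < fn_rate + gt_flip:
            flipped = "hom_alt" if gt == "het" else "het"
            v = Variant("chr1", pos, ref, alt, flipped, sample)
        ev.append(v)
    n_fp = rng.binomial(n_truth, fp_rate)
    taken = {v.pos for v in truth}
    for _ in range(n_fp):
        pos = int(rng.integers(2, region_length))
        if pos in taken:
            continue
        taken.add(pos)
        ref, alt = [bases[i] for i in rng.choice(4, size=2, replace=False)]
        gt = "het" if rng.random() < 0.6 else "hom_alt"
        ev.append(Variant("chr1", pos, ref, alt, gt, sample))
    return (
        CallSet(sample=sample, variants=sorted(truth)),
        CallSet(sample=sample, variants=sorted(ev)),
    )
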