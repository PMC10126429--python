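import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from y2hseq import (
    BAIT,
    EMPTY,
    SimConfig,
    assign_reads,
    call_interactors,
    compute_fpkm,
    generate_library,
    simulate_screen,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def random_cds(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def demo_screen():
    """The default demonstration screen, run once end to end.

    500 genes, 5% interactors, 2% self-activators, 1200 colonies and 1e5
    reads per screen under stringent selection; shared by the recovery and
    invariant tests.
    """
    cfg = SimConfig(seed=0)
    library, truth = generate_library(cfg)
    reads = {label: simulate_screen(library, truth, cfg, label) for label in (BAIT, EMPTY)}
    counts = {label: assign_reads(reads[label], library) for label in (BAIT, EMPTY)}
    fpkm = {label: compute_fpkm(counts[label], library) for label in (BAIT, EMPTY)}
    calls = call_interactors(fpkm[BAIT], fpkm[EMPTY], counts[BAIT], counts[EMPTY])
    return {
        "config": cfg,
        "library": library,
        "truth": truth,
        "reads": reads,
        "counts": counts,
        "fpkm": fpkm,
        "calls": calls,
    }
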