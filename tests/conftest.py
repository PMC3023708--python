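import numpy as np
import pytest

from bcescan.topology import Topology


def topology_from_plan(seq_id, plan):
    """Build a Topology from [(kind, length), ...]."""
    segments = []
    pos = 1
    for kind, length in plan:
        segments.append((kind, pos, pos + length - 1))
        pos += length
    return Topology(seq_id=seq_id, length=pos - 1, segments=segments)


def random_topology(rng: np.random.Generator, seq_id="t") -> Topology:
    """A random valid topology, biased toward the boundary values the
    architecture rules test (TM counts near 2/10, loop lengths near the
    rule windows)."""
    n_tm = int(rng.choice([0, 1, 2, 2, 3, 9, 10, 10, 11, int(rng.integers(0, 13))]))
    plan = []
    side = "I" if rng.random() < 0.5 else "O"
    if rng.random() < 0.9:  # N-terminal tail usually present
        plan.append((side, int(rng.integers(1, 40))))
        side = "O" if side == "I" else "I"
    boundary_loops = [1, 12, 14, 20, 21, 99, 100, 170, 171, 400, 401]
    for k in range(n_tm):
        plan.append(("TM", int(rng.integers(15, 26))))
        if k < n_tm - 1:
            if rng.random() < 0.5:
                loop = int(rng.choice(boundary_loops))
            else:
                loop = int(rng.integers(1, 450))
            plan.append((side, loop))
            side = "O" if side == "I" else "I"
    if n_tm == 0 and not plan:
        plan.append((side, int(rng.integers(30, 800))))
    elif rng.random() < 0.9:  # C-terminal tail
        plan.append((side, int(rng.integers(1, 300))))
    return topology_from_plan(seq_id, plan)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
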