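import dataclasses

import numpy as np
import pytest

from chainsim.anchors import Anchor, ChainTask, GeneratorConfig, generate_tasks
from chainsim.chaining import UNBOUNDED, ChainingParams


@pytest.fixture
def params():
    return ChainingParams()


@pytest.fixture
def exact_params():
    return ChainingParams(H=UNBOUNDED)


@pytest.fixture
def relaxed_exact():
    return ChainingParams(H=UNBOUNDED, min_score=0.0, min_cnt=1)


def make_random_task(rng: np.random.Generator, n: int, coord_range: int = 20_000,
                     span: int = 15, task_id: str = "rand") -> ChainTask:
    """A fully random (non-planted) task: n unique anchors, uniform coords."""
    taken = set()
    anchors = []
    while len(anchors) < n:
        x = int(rng.integers(span - 1, coord_range))
        y = int(rng.integers(span - 1, coord_range))
        if (x, y) in taken:
            continue
        taken.add((x, y))
        anchors.append(Anchor(x, y, span))
    anchors.sort(key=lambda a: (a.x, a.y))
    return ChainTask(task_id=task_id, anchors=tuple(anchors))


@pytest.fixture
def random_task_factory():
    return make_random_task


@pytest.fixture
def planted_batch():
    """A small seeded batch of generator tasks with structure + noise."""
    cfg = GeneratorConfig(
        n_tasks=12, anchors_per_task=(40, 120), planted_chains_per_task=2,
        noise_fraction=0.3, coord_range=30_000, seed=42,
    )
    return generate_tasks(cfg)
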