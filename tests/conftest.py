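import numpy as np
import pytest

from cdrmap.synthetic_data import occupied_positions
from cdrmap.types import LoopRecord


def make_loop(
    loop_id: str,
    backbone,
    cdr: str = "L1",
    sequence: str | None = None,
    source: str = "predicted",
    annotation: str | None = None,
) -> LoopRecord:
    backbone = np.asarray(backbone, dtype=float).reshape(-1, 3, 3)
    length = backbone.shape[0]
    return LoopRecord(
        loop_id=loop_id,
        cdr=cdr,
        sequence=sequence or "A" * length,
        imgt_numbers=occupied_positions(cdr, length),
        backbone=backbone,
        source=source,
        annotation=annotation,
    )


def random_loop(rng: np.random.Generator, length: int, loop_id: str = "loop", **kw) -> LoopRecord:
    return make_loop(loop_id, rng.normal(scale=3.0, size=(length, 3, 3)), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_228)
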