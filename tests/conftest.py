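import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stylemorph.synthetic import ShapeParams, generate_outline


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def head_outlines():
    """A small bank of noise-free head+stylet outlines spanning the shape axes."""
    shapes = []
    for i, (rim, rel, thick, curv) in enumerate(
        [
            (0.0, 1.0, 0.12, 0.0),
            (-0.2, 1.0, 0.12, 0.1),
            (0.2, 0.7, 0.10, 0.2),
            (0.0, 1.8, 0.08, 0.0),
            (-0.1, 1.2, 0.25, 0.3),
            (0.1, 0.5, 0.18, -0.2),
        ]
    ):
        p = ShapeParams(
            posterior_rim_curvature=rim, stylet_rel_length=rel,
            stylet_thickness=thick, stylet_curvature=curv, tooth_count=2,
        )
        shapes.append(generate_outline(p, 256, specimen_id=f"head{i}"))
    return shapes
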