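"""Shared fixtures: small trained models and synthetic images.

Session-scoped training keeps the suite fast: one compact body/nucleus/dot
model serves every test that needs real network output.
"""

from __future__ import annotations

import numpy as np
import pytest

from somaquant.fcn import FCNConfig, build_fcn, train
from somaquant.synth import ImageSpec, generate_cell_image

CELL_CLASSES = ["background", "body", "nucleus", "dot"]


def cell_field_pairs(n_images: int, shape=(160, 160), n_cells: int = 6,
                     seed: int = 0, **spec_kw):
    """Rendered fields plus semantic masks and their ground truth."""
    out = []
    for i in range(n_images):
        spec = ImageSpec(shape=shape, n_cells=n_cells,
                         seed=seed * 1000 + i, **spec_kw)
        img, truth = generate_cell_image(spec)
        out.append((img, truth.semantic_mask(CELL_CLASSES), truth))
    return out


@pytest.fixture(scope="session")
def cell_model():
    """A compact 4-class model trained on synthetic fields.

    Classes: background, cell body, nucleus, RNAscope dot.  Accurate enough
    (held-out pixel error well under 1%) for segmentation-dependent tests.
    """
    triples = cell_field_pairs(8, seed=3)
    pairs = [(img, sem) for img, sem, _ in triples]
    cfg = FCNConfig(n_classes=4, patch_size=15, layer_widths=(8, 16, 16, 16),
                    kernel_sizes=(5, 5, 1, 5, 3), max_epochs=45, patience=8,
                    class_weighting=True, seed=3)
    net = build_fcn(cfg, in_channels=3)
    return train(net, pairs[:6], pairs[6:], cfg, class_names=CELL_CLASSES)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
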