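import numpy as np
import pytest

import reedcover as rc


@pytest.fixture(scope="session")
def default_corpus():
    """The default synthetic corpus: 20+20 source images of 64x64, tile 32."""
    reed, water = rc.make_training_corpus(n_per_class=20, image_size=64, seed=0)
    return rc.build_dataset(reed, water, tile_size=32, overlap=0.5)


@pytest.fixture(scope="session")
def default_split(default_corpus):
    return rc.shuffle_split(default_corpus, train_fraction=0.7, seed=0)


@pytest.fixture(scope="session")
def trained(default_corpus, default_split):
    """Model trained with the default 30-epoch schedule, plus its history."""
    model = rc.build_model(rc.ModelSpec(seed=0))
    return rc.train(model, default_corpus, default_split, epochs=30, seed=0)


def make_flat_tileset(n, tile=2, reed_every=2):
    """A lightweight corpus of n constant tiles for split/label bookkeeping."""
    img = np.zeros((tile, tile, 3), dtype=np.uint8)
    records = [
        rc.TileRecord(
            tile_id=f"t{i:04d}",
            source_image_id=f"src{i // 4:03d}",
            image=img,
            label="reed" if i % reed_every == 0 else "non_reed",
        )
        for i in range(n)
    ]
    return rc.LabelledTileSet(records)
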