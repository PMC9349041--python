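"""Shared fixtures: a small synthetic dataset and a model trained on it.

The tiny study conditions (5 proteins spanning 5 pattern families, 256 px
fields, 64 x 64 crops, a 32-code model) keep the full pipeline affordable on
one CPU while preserving the structure the larger method assumes.
"""

import numpy as np
import pytest

from vqcyto import imgprep, synthgen, trainer, vqmodel

TINY_FAMILIES = [
    synthgen.Family.NUCLEAR_DIFFUSE,
    synthgen.Family.CYTO_DIFFUSE,
    synthgen.Family.PUNCTATE,
    synthgen.Family.NUCLEOLAR,
    synthgen.Family.RETICULAR,
]


def tiny_synth_config(seed: int = 11, images_per_protein: int = 20):
    return synthgen.SynthConfig(
        n_proteins=5,
        images_per_protein=images_per_protein,
        family_of={
            f"prot{i:03d}": fam for i, fam in enumerate(TINY_FAMILIES)
        },
        fov_size=256,
        nuclei_per_fov=(2, 3),
        seed=seed,
    )


def tiny_model_config(**overrides) -> vqmodel.ModelConfig:
    kw = dict(
        n_classes=5,
        input_shape=(64, 64, 2),
        n_codes=32,
        code_dim=16,
        local_shape=(16, 16, 16),
        global_shape=(4, 4, 64),
        n_splits=4,
        classifier_hidden=64,
        width1=16,
        width2=32,
    )
    kw.update(overrides)
    return vqmodel.ModelConfig(**kw)


@pytest.fixture(scope="session")
def tiny_dataset() -> synthgen.SyntheticDataset:
    return synthgen.generate_dataset(tiny_synth_config())


@pytest.fixture(scope="session")
def tiny_crops(tiny_dataset) -> imgprep.CropSet:
    return imgprep.preprocess_dataset(
        tiny_dataset.fovs, tiny_dataset.protein_ids, crop_size=64
    )


@pytest.fixture(scope="session")
def trained_tiny(tiny_crops):
    """A tiny model trained for a fixed short budget, with its history and
    the partition used."""
    model = vqmodel.build_model(tiny_model_config(), seed=1)
    config = trainer.TrainConfig(batch_size=16, max_epochs=15, seed=2)
    assignment = trainer.split_dataset(
        tiny_crops, config.split_ratios, seed=config.seed
    )
    model, history = trainer.train(model, tiny_crops, config, assignment)
    return model, history, assignment


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
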