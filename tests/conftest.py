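import numpy as np
import pandas as pd
import pytest

from phenocount.annotations import (
    AnnotationDataset,
    SpecimenInfo,
)
from phenocount.synthetic_data import default_params, generate_dataset, generate_specimen


def make_manifest(tmp_path, rows):
    path = tmp_path / "manifest.csv"
    pd.DataFrame(
        rows, columns=["specimen_id", "image_path", "width", "height", "species", "genus"]
    ).to_csv(path, index=False)
    return path


def make_annotations_csv(tmp_path, rows, name="annotations.csv"):
    path = tmp_path / name
    pd.DataFrame(
        rows,
        columns=[
            "specimen_id", "annotator_id", "annotator_role",
            "organ", "x", "y", "species", "genus",
        ],
    ).to_csv(path, index=False)
    return path


def dataset_from_rows(ann_rows, specimen_ids, width=100, height=100):
    specimens = {
        sid: SpecimenInfo(sid, f"{sid}.png", width, height, "synthetica", "Synthanthus")
        for sid in specimen_ids
    }
    df = pd.DataFrame(
        ann_rows,
        columns=[
            "specimen_id", "annotator_id", "annotator_role",
            "organ", "x", "y", "species", "genus",
        ],
    )
    return AnnotationDataset(annotations=df, specimens=specimens)


def ann_row(sid, organ, annotator="E1", role="expert", x=10.0, y=10.0):
    return {
        "specimen_id": sid,
        "annotator_id": annotator,
        "annotator_role": role,
        "organ": organ,
        "x": x,
        "y": y,
        "species": "synthetica",
        "genus": "Synthanthus",
    }


@pytest.fixture(scope="session")
def small_sheets():
    """Twelve noiseless synthetic sheets with truth, generated once."""
    params = default_params()
    rng = np.random.default_rng(424242)
    pairs = []
    for i in range(12):
        img, truth = generate_specimen(
            params, seed=int(rng.integers(0, 2**31 - 1)), specimen_id=f"s{i:03d}"
        )
        pairs.append((img, truth))
    return pairs


@pytest.fixture(scope="session")
def simulated_dir(tmp_path_factory):
    """A small on-disk simulated dataset (manifest + annotations + truth)."""
    out = tmp_path_factory.mktemp("simdata")
    truths = generate_dataset(8, default_params(), seed=99, out_dir=out)
    return out, truths
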