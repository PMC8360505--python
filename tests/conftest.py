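import pandas as pd
import pytest

from wormwell import (
    EdgeConfig,
    SimulationConfig,
    edge_flag,
    generate_plate_set,
    select_models,
    set_flags,
)


def make_objects(rows):
    """Build a minimal canonical object table from (plate, well, oid, model, length) tuples."""
    return pd.DataFrame(
        [
            {
                "Metadata_Plate": p,
                "Metadata_Well": w,
                "primary_object_id": oid,
                "model_name": model,
                "centroid_x": 1000.0 + i,
                "centroid_y": 1000.0,
                "worm_length": length,
            }
            for i, (p, w, oid, model, length) in enumerate(rows)
        ]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One simulated plate of 24 wells; shared read-only across tests."""
    config = SimulationConfig(plates=1, wells_per_plate=24)
    objects, design, truth = generate_plate_set(config, seed=7)
    return config, objects, design, truth


@pytest.fixture(scope="session")
def flagged_small_sim(small_sim):
    config, objects, design, truth = small_sim
    selected = select_models(objects)
    edge = EdgeConfig(image_shape=(config.image_size_px, config.image_size_px))
    return set_flags(edge_flag(selected, edge))
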