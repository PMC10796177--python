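import numpy as np
import pytest

from renalwsi import fuse, synthdata, tiler


@pytest.fixture(scope="session")
def default_triple():
    """One default-sized slide triple with ground truth (seed 11)."""
    return synthdata.generate_slide_pair(synthdata.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(default_triple):
    """Full-pipeline result on the default triple with contract tile sizes."""
    he10, he40, pas40, _gt = default_triple
    return fuse.run_pipeline(he10, he40, pas40)


@pytest.fixture(scope="session")
def small_tile_configs():
    """Small windows so that multi-tile overlap is exercised on 640px slides."""
    return (tiler.TileConfig(n=256, stride=128, target_size=288),
            tiler.TileConfig(n=1024, stride=512, target_size=512))


@pytest.fixture(scope="session")
def small_pipeline_result(default_triple, small_tile_configs):
    he10, he40, pas40, _gt = default_triple
    tile10, tile40 = small_tile_configs
    return fuse.run_pipeline(he10, he40, pas40, tile_config_10x=tile10,
                             tile_config_40x=tile40)


def gt_instances_for_label(gt, result, label):
    """(detections, ground_truth) pair for one class of one slide."""
    if label == "nucleus":
        return result.nuclei_40x, gt.nuclei
    if label.endswith("_hyper"):
        return ([i for i in result.hyper_regions if i.label == label],
                [i for i in gt.hyper_regions if i.label == label])
    return ([i for i in result.structures if i.label == label],
            [i for i in gt.structures if i.label == label])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
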