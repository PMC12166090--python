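import numpy as np
import pytest

from crcimmune import PipelineConfig
from crcimmune.cells import cell_table_from_arrays
from crcimmune.pipeline import process_slide
from crcimmune.simulate import SlideSimSpec, simulate_slide


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_slide():
    """One simulated slide, deterministic, processed through every stage."""
    spec = SlideSimSpec(
        width_um=3000.0,
        height_um=1500.0,
        tumor_x0_um=1000.0,
        tumor_x1_um=1800.0,
        gap_um=200.0,
        rng_seed=7,
    )
    tmap, cells, truth = simulate_slide(spec, rng=np.random.default_rng(7))
    cells, front, flags = process_slide(cells, tmap, PipelineConfig())
    return {"spec": spec, "tmap": tmap, "cells": cells, "front": front,
            "flags": flags, "truth": truth}


def make_cells(points, slide_id="S1", **kw):
    """CellTable from a list of (x, y, raw_class) triples."""
    if not points:
        return cell_table_from_arrays([], [], [], slide_id=slide_id, **kw)
    xs, ys, cls = zip(*points)
    return cell_table_from_arrays(xs, ys, cls, slide_id=slide_id, **kw)
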