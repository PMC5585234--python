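import numpy as np
import pandas as pd
import pytest

import coralclim as cc
from coralclim.ann import AnnConfig


@pytest.fixture(scope="session")
def world():
    """The standard synthetic validation world (seed 42, ~130 ocean cells)."""
    return cc.build_world()


@pytest.fixture(scope="session")
def fast_ann_config():
    """Iteration-capped ANN config for desk-scale validation runs."""
    return AnnConfig(
        n_replicates=10, base_seed=42, max_iterations=200, gradient_tol=1e-5
    )


def _record(taxon, genus, lat, lon, depth, zoox, epoch="modern"):
    return {
        "taxon": taxon,
        "genus": genus,
        "rank": "species",
        "lat": lat,
        "lon": lon,
        "depth_m": depth,
        "epoch": epoch,
        "zooxanthellate": zoox,
    }


@pytest.fixture(scope="session")
def toy_records():
    """Ten hand-enumerable records exercising every filter branch.

    Three are too deep (60.1, 70, 80 m), two azooxanthellate, with one
    record in both classes -> exactly four drop, six survive.  The six
    survivors occupy four cells; only two of those cells hold >= 2 genera.
    """
    rows = [
        _record("spA", "genA", 12.7, -61.3, 10.0, True),    # keep, cell (12,-62)
        _record("spB", "genB", 12.7, -61.3, 59.9, True),    # keep, cell (12,-62)
        _record("spA", "genA", 12.0, -61.0, 60.0, True),    # keep (boundary incl.)
        _record("spC", "genC", 12.0, -61.0, 60.1, True),    # drop: deep
        _record("spD", "genD", -0.2, 0.0, 5.0, False),      # drop: azoox
        _record("spE", "genE", -0.2, 0.0, 70.0, False),     # drop: deep + azoox
        _record("spF", "genF", -0.2, 0.0, 80.0, True),      # drop: deep
        _record("spB", "genB", 12.0, -61.0, 30.0, True),    # keep, cell (12,-61)
        _record("spG", "genA", -0.2, 0.0, 25.0, True),      # keep, single-genus cell
        _record("spA", "genA", 5.5, 100.5, 12.0, True),     # keep, single-genus cell
    ]
    return pd.DataFrame(rows)


TOY_SURVIVOR_ROWS = [0, 1, 2, 7, 8, 9]
TOY_RETAINED_CELLS = {(12, -62), (12, -61)}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
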