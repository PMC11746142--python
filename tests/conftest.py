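import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from pspatools import synthetic


@pytest.fixture(scope="session")
def toy_monomer():
    return synthetic.default_toy_monomer()


@pytest.fixture(scope="session")
def small_field():
    """Noiseless vesicle field with nesting, shared across tests."""
    return synthetic.generate_vesicle_field(20, 0.3, seed=11)


def match_to_truth(records, truth):
    """Assign recovered vesicle records to ground-truth specs.

    Concentric vesicles share a centroid, so matching combines centroid
    distance with mean-radius difference and solves the assignment problem.
    Returns {record_index: truth_index}.
    """
    rec_cent = np.array([r.trace.points.mean(axis=0) for r in records])
    rec_rad = np.array(
        [np.linalg.norm(r.trace.points - c, axis=1).mean()
         for r, c in zip(records, rec_cent)]
    )
    truth_cent = np.array([v.center for v in truth])
    truth_rad = np.array([v.radius for v in truth])
    cost = cdist(rec_cent, truth_cent) + 3.0 * np.abs(rec_rad[:, None] - truth_rad[None, :])
    rows, cols = linear_sum_assignment(cost)
    return dict(zip(rows.tolist(), cols.tolist()))
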