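import warnings

import numpy as np
import pandas as pd
import pytest

import thromboquant as tq


def flood_fill_areas(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    """Independent connected-component oracle: iterative flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    areas = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            area = 0
            while stack:
                r, c = stack.pop()
                area += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            areas.append(area)
    return sorted(areas)


@pytest.fixture
def planted_panel():
    """Normalized 52×8 panel with a planted 3-type structure + its truth."""
    truth = tq.planted_matrix_truth(seed=101)
    _means, reps = tq.gen_parameter_matrix(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pm = tq.normalize_matrix(tq.aggregate_replicates(reps))
    return pm, truth


@pytest.fixture
def small_cohort():
    truth = tq.cohort_truth(seed=77)
    controls, patient, patient_runs = tq.gen_cohort(truth)
    return truth, controls, patient, patient_runs
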