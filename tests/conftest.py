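import numpy as np
import pandas as pd
import pytest

from congenic.expression import GROUP_INP, GROUP_IP, REGIONS, ExpressionMatrix


def make_matrix(values, groups, regions=None, detection=None, probe_ids=None):
    """Build a small ExpressionMatrix from a 2-D array and group labels.

    ``groups`` is a sequence of "ip"/"inp" per animal; one sample per animal
    per region (values repeated across regions unless a 3-D array is given).
    """
    values = np.asarray(values, dtype=float)
    regions = list(regions) if regions is not None else ["nucleus_accumbens"]
    n_animals = len(groups)
    if values.ndim == 2:
        values = np.repeat(values[:, :, None], len(regions), axis=2)
    G = values.shape[0]
    probe_ids = probe_ids or [f"ps{i:03d}" for i in range(G)]
    animals = [f"an{i:02d}" for i in range(n_animals)]
    sample_ids = [f"{a}_{r}" for a in animals for r in regions]
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "animal_id": np.repeat(animals, len(regions)),
            "group": np.repeat(
                [GROUP_IP if g == "ip" else GROUP_INP for g in groups], len(regions)
            ),
            "region": np.tile(regions, n_animals),
        }
    )
    flat = values.reshape(G, n_animals * len(regions))
    vdf = pd.DataFrame(flat, index=probe_ids, columns=sample_ids)
    det = None
    if detection is not None:
        det = np.asarray(detection, dtype=bool)
        if det.ndim == 2:
            det = np.repeat(det[:, :, None], len(regions), axis=2)
        det = pd.DataFrame(det.reshape(G, -1), index=probe_ids, columns=sample_ids)
    return ExpressionMatrix(vdf, sheet, det)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def five_regions():
    return list(REGIONS)
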