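import numpy as np
import pytest

from dimorphbone.config import load_cortex_fixture
from dimorphbone.phantom import generate_cortex_volume
from dimorphbone import (binarize, extract_cortical_porosity, label_pores,
                         select_separation_threshold, classify_pores)


@pytest.fixture(scope="session")
def small_wt_phantom():
    """WT-female-like cortex phantom at reduced axial extent (shared)."""
    spec = load_cortex_fixture("ct_wt_female", length_slices=120)
    spec.lacunae.count = 60
    volume, truth = generate_cortex_volume(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def small_wt_extraction(small_wt_phantom):
    """Porosity extraction + classified catalog for the shared phantom."""
    spec, volume, truth = small_wt_phantom
    bone = binarize(volume, 80)
    porosity, cortex = extract_cortical_porosity(bone, closing_radius_vox=15)
    catalog = label_pores(porosity, cortex)
    threshold = select_separation_threshold(catalog)
    catalog = classify_pores(catalog, threshold)
    return bone, porosity, cortex, catalog


def flood_fill_label(mask: np.ndarray) -> list[int]:
    """Independent 26-connectivity labelling oracle: BFS flood fill.

    Returns the sorted list of component sizes.
    """
    from collections import deque

    visited = np.zeros_like(mask, dtype=bool)
    sizes = []
    shape = mask.shape
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        queue = deque([start])
        visited[start] = True
        size = 0
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]
                        and 0 <= p[2] < shape[2]
                        and mask[p] and not visited[p]):
                    visited[p] = True
                    queue.append(p)
        sizes.append(size)
    return sorted(sizes)
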