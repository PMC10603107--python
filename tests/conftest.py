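import numpy as np
import pandas as pd
import pytest

from exoscreen import (
    AbundanceSimConfig,
    AbundanceStudy,
    PanelSimConfig,
    SampleMeta,
    generate_abundance_study,
    generate_marker_panel,
)


def build_study(unit_presence: dict, proteins: list[str]) -> AbundanceStudy:
    """Construct a study from a {(group, source, unit): {protein: [reps]}} map.

    ``[reps]`` lists intensities per replicate (NaN = not detected); every
    unit has as many replicates as the longest list it declares.
    """
    samples: list[SampleMeta] = []
    columns: dict[str, list[float]] = {}
    for (group, source, unit), presence in unit_presence.items():
        n_rep = max(len(v) for v in presence.values())
        for r in range(1, n_rep + 1):
            sid = f"{unit}_r{r}"
            samples.append(SampleMeta(sid, group, source, unit, r))
            col = []
            for p in proteins:
                vals = presence.get(p, [])
                col.append(vals[r - 1] if r <= len(vals) else np.nan)
            columns[sid] = col
    mat = pd.DataFrame(columns, index=proteins)
    return AbundanceStudy(intensities=mat, samples=samples)


@pytest.fixture(scope="session")
def study_flow():
    """Default synthetic abundance study with planted stage membership."""
    cfg = AbundanceSimConfig(seed=7)
    return generate_abundance_study(cfg)


@pytest.fixture(scope="session")
def chip_panel():
    """Default 10-case / 20-control seven-marker chip panel."""
    return generate_marker_panel(PanelSimConfig(seed=0))
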