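import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scnkit.atlas import RoiAtlas, desikan_killiany
from scnkit.io import ThicknessTable


@pytest.fixture(scope="session")
def dk_atlas():
    return desikan_killiany()


def small_atlas(n: int, prefix: str = "roi") -> RoiAtlas:
    """A tiny ad-hoc atlas for unit tests that do not need 68 regions."""
    return RoiAtlas(
        names=tuple(f"{prefix}{i:02d}" for i in range(n)),
        hemispheres=tuple("LH" if i % 2 == 0 else "RH" for i in range(n)),
    )


def make_table(values_by_condition: dict, atlas: RoiAtlas, groups=None) -> ThicknessTable:
    """Build a ThicknessTable from {condition: (n_subj, n_roi) array}."""
    frames = []
    for cond, x in values_by_condition.items():
        x = np.asarray(x, dtype=float)
        df = pd.DataFrame(x, columns=list(atlas.names))
        df.insert(0, "subject_id", [f"s{i:03d}" for i in range(x.shape[0])])
        df.insert(1, "condition", cond)
        df.insert(2, "group", (groups or ["all"] * x.shape[0]))
        frames.append(df)
    return ThicknessTable(pd.concat(frames, ignore_index=True), atlas)
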