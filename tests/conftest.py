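from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tissuespec import ClassificationConfig


@pytest.fixture
def brain_config() -> ClassificationConfig:
    return ClassificationConfig(target_tissue="brain")


def make_profile(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Gene x tissue profile from nested dicts, preserving insertion order."""
    frame = pd.DataFrame(rows).T
    frame.index.name = "gene_id"
    return frame


def atlas_row(target: float, others: dict[str, float] | None = None,
              n_tissues: int = 27, fill: float = 1.0,
              target_name: str = "brain") -> dict[str, float]:
    """A target-centric profile row padded with constant peripheral tissues."""
    others = dict(others or {})
    row = {target_name: target, **others}
    i = 0
    while len(row) < n_tissues:
        name = f"tissue{i:02d}"
        if name not in row:
            row[name] = fill
        i += 1
    return row


@pytest.fixture
def random_profiles():
    """Random tissue profiles with 4-10 tissues mixing flat, spiky and zero rows."""

    def _gen(n_profiles: int, seed: int = 0) -> list[dict[str, float]]:
        rng = np.random.default_rng(seed)
        profiles = []
        for _ in range(n_profiles):
            n = int(rng.integers(4, 11))
            tissues = [f"t{j:02d}" for j in range(n)]
            kind = rng.integers(0, 4)
            if kind == 0:  # heavy-tailed noise
                values = rng.lognormal(0.5, 1.5, size=n)
            elif kind == 1:  # planted group of raised tissues
                values = rng.lognormal(0.0, 0.5, size=n)
                k = int(rng.integers(1, min(8, n)))
                values[rng.choice(n, size=k, replace=False)] *= rng.uniform(3, 30)
            elif kind == 2:  # near-constant
                values = np.full(n, float(rng.uniform(0, 20)))
                values *= rng.uniform(0.95, 1.05, size=n)
            else:  # sparse with exact zeros
                values = rng.lognormal(1.0, 1.0, size=n)
                values[rng.random(n) < 0.5] = 0.0
            profiles.append(dict(zip(tissues, values.tolist())))
        return profiles

    return _gen
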