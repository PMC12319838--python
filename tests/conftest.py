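"""Shared fixtures: small synthetic cohorts and on-disk tool-table fixtures."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from t1qc.schemas import CAT12_MEASURES, MRIQC_METRICS
from t1qc.synthetic import SyntheticConfig, generate_cohort, simulate_tool_ratings

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_cohort():
    """3 sites x 80 scans, strong planted signal — cheap enough for unit tests."""
    cfg = SyntheticConfig(
        n_sites=3,
        n_per_site=80,
        reject_fraction=0.15,
        n_informative=10,
        effect_size=1.5,
        seed=42,
    )
    table, labels, latent = generate_cohort(cfg)
    return cfg, table, labels, latent


@pytest.fixture(scope="session")
def small_ratings(small_cohort):
    cfg, _, _, latent = small_cohort
    return simulate_tool_ratings(latent, cfg)


def write_tool_table(path: Path, schema, n_scans: int, seed: int = 0, sep: str = "\t") -> Path:
    """Write a fully numeric tool table (scan_id + full schema) to disk."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        rng.standard_normal((n_scans, len(schema))),
        columns=list(schema),
    )
    frame.insert(0, "scan_id", [f"sub-{i:03d}" for i in range(n_scans)])
    frame.to_csv(path, sep=sep, index=False)
    return path


@pytest.fixture()
def mriqc_tsv(tmp_path):
    return write_tool_table(tmp_path / "mriqc.tsv", MRIQC_METRICS, n_scans=3, seed=1)


@pytest.fixture()
def cat12_csv(tmp_path):
    return write_tool_table(tmp_path / "cat12.csv", CAT12_MEASURES, n_scans=5, seed=2, sep=",")
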