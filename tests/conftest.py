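import numpy as np
import pytest

from efdb.ef import ExpressionSeries

DATA_DIR_NAME = "data"


@pytest.fixture
def fold_table_path():
    """Repo-level TSV with the 24-gene x 5-profile conserved-fold matrix."""
    from pathlib import Path

    path = Path(__file__).resolve().parent.parent / DATA_DIR_NAME / "neuro_fold_profiles.tsv"
    assert path.exists(), f"missing data file {path}"
    return path


def make_series(values, series_id="S1", platform_id="PL", sample_ids=None,
                probe_ids=None):
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    return ExpressionSeries(
        series_id=series_id,
        platform_id=platform_id,
        sample_ids=sample_ids or [f"gsm{j}" for j in range(n_samples)],
        probe_ids=probe_ids or [f"p{i}" for i in range(n_probes)],
        values=values,
    )


@pytest.fixture
def small_series():
    # 3 probes x 2 samples from the rescaling worked example
    return make_series([[1, 4], [2, 4], [3, 4]])


def load_fold_table(path):
    """Return (profiles A..E as list of dicts, expected sign map)."""
    profiles = [dict() for _ in range(5)]
    expected = {}
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        assert header == ["gene", "expected", "f1", "f2", "f3", "f4", "f5"]
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            gene = parts[0]
            expected[gene] = int(parts[1])
            for i, token in enumerate(parts[2:7]):
                profiles[i][gene] = float(token)
    return profiles, expected
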