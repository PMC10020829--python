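import pandas as pd
import pytest

from bioblitz import synthdata


@pytest.fixture(scope="session")
def small_corpus():
    """A compact synthetic corpus shared by read-only tests."""
    return synthdata.generate(seed=42, n_projects=6, users_per_project=12)


@pytest.fixture()
def write_csv(tmp_path):
    """Write inline rows to a CSV file and return its path."""

    def _write(name: str, header: str, rows: list[str]) -> str:
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return str(path)

    return _write


def project_row(project_id="P1", start="2019-02-22T09:00:00", end="2019-02-23T09:00:00",
                title="BioBlitz"):
    return pd.Series({
        "project_id": project_id, "title": title,
        "start": pd.Timestamp(start), "end": pd.Timestamp(end),
    })
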