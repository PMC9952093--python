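import numpy as np
import pytest

from litmine.corpus import Corpus, Document
from litmine.preprocess import default_policy


@pytest.fixture(scope="session")
def policy():
    return default_policy()


@pytest.fixture()
def toy_corpus():
    return Corpus(
        [
            Document(
                id="d1",
                title="Antibacterial plants",
                abstract="The studies of species growth",
                year=2005,
                citations=12,
                open_access=True,
            ),
            Document(
                id="d2",
                title="Soil ecology",
                abstract="Seed germination after fires",
                year=2010,
                citations=3,
                open_access=False,
            ),
            Document(
                id="d3",
                title="Extract activity",
                abstract="",
                year=2015,
                citations=40,
                open_access=False,
            ),
        ],
        provenance="toy",
    )


def write_csv(path, header, rows):
    lines = [",".join(header)]
    for row in rows:
        cells = []
        for cell in row:
            cell = str(cell)
            if "," in cell or '"' in cell or "\n" in cell:
                cell = '"' + cell.replace('"', '""') + '"'
            cells.append(cell)
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture()
def scopus_csv(tmp_path):
    return write_csv(
        tmp_path / "scopus.csv",
        ["Title", "Year", "Abstract", "Cited by", "Open Access"],
        [
            ["Rockrose extracts", "2019", "Antibacterial activity of extracts", "10", "All Open Access; Gold"],
            ["Soil recovery", "2020", "Post-fire regeneration, seeds", "5", ""],
            ["Essential oils", "2021", "Composition of essential oils", "0", "Hybrid Gold"],
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
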