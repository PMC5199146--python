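import pytest

from dwctraits import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture
def csv_file(tmp_path):
    def _write(text, name="records.csv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
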