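import pytest

from hxfacs import datasets
from hxfacs.diagnostics import LabeledScores


@pytest.fixture(scope="session")
def surgical():
    return datasets.load_surgical()


@pytest.fixture(scope="session")
def biopsy():
    return datasets.load_biopsy()


def labeled(records, parameter, label="mutation") -> LabeledScores:
    vals, labs = datasets.scores(records, parameter, label)
    return LabeledScores.from_arrays(vals, labs, parameter)


@pytest.fixture(scope="session")
def surgical_scores(surgical):
    return {p: labeled(surgical, p) for p in ("double_pos", "egfr_pos", "hx103_pos")}


@pytest.fixture(scope="session")
def biopsy_scores(biopsy):
    return {p: labeled(biopsy, p) for p in ("double_pos", "egfr_pos", "hx103_pos")}


@pytest.fixture(scope="session")
def tki_scores(biopsy):
    return {
        p: labeled(biopsy, p, label="response")
        for p in ("double_pos", "egfr_pos", "hx103_pos")
    }
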