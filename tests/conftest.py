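import pytest

from resuslearn.io import default_item_bank
from resuslearn.types import ResponseSheet


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture
def make_sheet(bank):
    """Build a written-test sheet with given correct/incorrect/null counts."""

    def _make(n_correct, n_incorrect, n_null, learner_id="L001", timepoint="test0",
              equipment=frozenset()):
        assert n_correct + n_incorrect + n_null == bank.n_questions
        states = (["correct"] * n_correct + ["incorrect"] * n_incorrect
                  + ["null"] * n_null)
        return ResponseSheet(learner_id=learner_id, timepoint=timepoint,
                             answers=dict(zip(bank.question_ids, states)),
                             equipment_selected=frozenset(equipment))

    return _make


@pytest.fixture
def select_items(bank):
    """First n item ids of a category, for equipment-score fixtures."""

    def _select(**counts):
        picked = []
        for cat, n in counts.items():
            items = bank.items_in_category(cat)
            assert n <= len(items)
            picked.extend(e.id for e in items[:n])
        return frozenset(picked)

    return _select
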