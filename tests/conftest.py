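import pytest

from vitroscreen.classifier import LabeledCorpus
from vitroscreen.corpus_io import Record
from vitroscreen.regex_screener import build_term_pattern, default_ogd_terms


@pytest.fixture(scope="session")
def ogd_pattern():
    return build_term_pattern(default_ogd_terms())


@pytest.fixture
def five_records():
    """2 conference abstracts, 1 without abstract, 2 eligible."""
    return [
        Record(id="r1", title="A conference talk", abstract="Some text", is_conference_abstract=True),
        Record(id="r2", title="Another talk", abstract=None, is_conference_abstract=True),
        Record(id="r3", title="No abstract here", abstract=None),
        Record(id="r4", title="Eligible one", abstract="OGD in PC-12 cells", full_text="full body"),
        Record(id="r5", title="Eligible two", abstract="control experiment"),
    ]


def make_separable_corpus(n_per_class: int = 30) -> LabeledCorpus:
    """Disjoint topic vocabularies: linearly separable by construction."""
    records, labels = [], {}
    for i in range(n_per_class):
        rid_pos, rid_neg = f"pos{i:03d}", f"neg{i:03d}"
        records.append(Record(id=rid_pos, title=f"culture assay {i}",
                              abstract=f"cells lysate plate incubation replicate{i % 5} viability"))
        labels[rid_pos] = True
        records.append(Record(id=rid_neg, title=f"cohort survey {i}",
                              abstract=f"patients ward registry followup{i % 5} questionnaire"))
        labels[rid_neg] = False
    return LabeledCorpus(records=records, labels=labels)


@pytest.fixture
def separable_corpus():
    return make_separable_corpus()
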