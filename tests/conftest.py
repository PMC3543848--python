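import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper module

from hedgekit.corpus import Corpus, DocumentRecord
from hedgekit.synth import GeneratorConfig, generate_corpus


def make_record(doc_id, **kwargs):
    defaults = dict(source_dbs={"EMBASE"}, relevant=False)
    defaults.update(kwargs)
    return DocumentRecord(doc_id=doc_id, **defaults)


@pytest.fixture
def tiny_corpus():
    """Hand-built corpus with known field contents for semantic checks."""
    records = [
        make_record(
            "d1",
            title="Off-label prescribing of antipsychotics in dementia",
            abstract="We review off-label use in elderly patients.",
            subject_headings=["off label drug use", "antipsychotic agent"],
            pub_year=2008,
            relevant=True,
        ),
        make_record(
            "d2",
            title="Stent placement outcomes",
            abstract="Drug eluting stents compared with bare metal stents.",
            pub_year=2005,
        ),
        make_record(
            "d3",
            title="Veterinary antibiotics survey",
            abstract="Extra-label use of antimicrobials in cattle.",
            pub_year=1995,
        ),
        make_record(
            "d4",
            title="Unlicensed medicines in paediatrics",
            abstract="Many children receive unlicensed or off licence prescriptions.",
            pub_year=2010,
            source_dbs={"EMBASE", "MEDLINE"},
            relevant=True,
        ),
        make_record(
            "d5",
            title="Pharmacokinetics of a novel agent",
            abstract="An off-license formulation was tested in volunteers.",
            pub_year=2003,
            relevant=True,
        ),
        make_record(
            "d6",
            title="Letter regarding drug labels",
            abstract="",
            pub_type="letter",
            pub_year=2011,
            subject_headings=["drug labeling"],
        ),
        make_record(
            "d7",
            title="Off label drug use in oncology",
            abstract="Unapproved use of cytotoxics for new indications.",
            pub_year=2002,
            source_dbs={"MEDLINE"},
            relevant=True,
        ),
    ]
    return Corpus(records=records, name="tiny")


@pytest.fixture
def tiny_gold(tiny_corpus):
    return tiny_corpus.gold_standard("EMBASE")


@pytest.fixture(scope="session")
def planted():
    """Mid-size exact-counts synthetic corpus shared across tests."""
    config = GeneratorConfig(n_docs=800, seed=20260926)
    corpus, gold, manifest = generate_corpus(config)
    return config, corpus, gold, manifest
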