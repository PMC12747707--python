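import numpy as np
import pytest

from fscnlp.corpus_io import Corpus, Letter


def make_letter(
    id="L1",
    text="The boy had jerks and drooled during the episode.",
    site="site_A",
    sex="male",
    age=4.5,
    initial_dx="unclear",
    final_dx="epilepsy",
) -> Letter:
    return Letter(
        id=id,
        site=site,
        anamnesis_text=text,
        sex=sex,
        age_years=age,
        initial_dx=initial_dx,
        final_dx=final_dx,
    )


def make_corpus(texts_and_labels, **kwargs) -> Corpus:
    """Corpus from (text, final_dx) pairs; ids are positional."""
    letters = tuple(
        make_letter(id=f"L{i:03d}", text=text, final_dx=final_dx, **kwargs)
        for i, (text, final_dx) in enumerate(texts_and_labels)
    )
    return Corpus(letters)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
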