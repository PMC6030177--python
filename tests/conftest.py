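import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from morphex.annotator import Annotator  # noqa: E402
from morphex.glossary import Glossary  # noqa: E402
from morphex.tagging import Lexicon  # noqa: E402

QUERCUS_CLAUSE = (
    "hojas simples, alternas, 4-10 (-14) x 1-3.3 cm., elípticas, "
    "ápice acuminado, caudado o agudo, base caudada u obtusa, "
    "glabras o a veces con tricomas dispersos a lo largo de la vena central "
    "por el envés."
)

HYDRANGEA_CLAUSE = (
    "lámina 3-12 (-13) x 2-6 (-7) cm, oblonga o elíptica, "
    "obtusa o redondeada en la base, aguda o cortamente acuminada en el ápice, "
    "muy espaciadamente serrada a subentera o entera, "
    "esparcidamente pubescente con tricomas rojos (raramente crema rojizo), "
    "usualmente con puntuaciones negras en el envés."
)


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon.default()


@pytest.fixture(scope="session")
def glossary() -> Glossary:
    return Glossary()


@pytest.fixture(scope="session")
def annotator() -> Annotator:
    return Annotator()
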