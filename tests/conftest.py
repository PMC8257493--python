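from __future__ import annotations

import importlib.resources

import pytest
from hypothesis import HealthCheck, settings

from scn2a_pheno.harmonize import harmonize_cohort
from scn2a_pheno.ontology import parse_obo, term_frequencies
from scn2a_pheno.variants import ProteinTopology, TopologyFeature

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mini_ontology():
    """The bundled 30-term neurology-flavored mini ontology."""
    ref = importlib.resources.files("scn2a_pheno.data") / "mini_hpo.obo"
    with importlib.resources.as_file(ref) as path:
        return parse_obo(str(path))


@pytest.fixture(scope="session")
def mini_cohort(mini_ontology):
    """Six hand-written individuals on the mini ontology, harmonized."""
    import pandas as pd

    rows = [
        ("P1", "HP:0012469", "positive"), ("P1", "HP:0002521", "positive"),
        ("P1", "HP:0002072", "positive"),
        ("P2", "HP:0012469", "positive"), ("P2", "HP:0002521", "positive"),
        ("P2", "HP:0002072", "positive"),
        ("P3", "HP:0000717", "positive"), ("P3", "HP:0000733", "positive"),
        ("P3", "HP:0001250", "negative"),
        ("P4", "HP:0007359", "positive"), ("P4", "HP:0001263", "positive"),
        ("P5", "HP:0000238", "positive"),
        ("P6", "HP:0002197", "positive"), ("P6", "HP:0010851", "positive"),
        ("P6", "HP:0002342", "positive"),
    ]
    ann = pd.DataFrame(rows, columns=["individual_id", "term", "polarity"])
    return harmonize_cohort(mini_ontology, ann)


@pytest.fixture(scope="session")
def mini_freqs(mini_cohort):
    """Propagated positive frequencies of the six-individual mini cohort."""
    return term_frequencies({i: a.prop_pos for i, a in mini_cohort.items()})


@pytest.fixture(scope="session")
def toy_topology():
    """A 100-residue, one-domain toy channel topology."""
    return ProteinTopology([
        TopologyFeature(None, "Cytoplasmic", None, 1, 20),
        TopologyFeature("I", "Transmembrane", "S1", 21, 30),
        TopologyFeature("I", "Transmembrane", "S4", 31, 40),
        TopologyFeature("I", "Transmembrane", "S5", 41, 50),
        TopologyFeature("I", "Extracellular", None, 51, 60),
        TopologyFeature("I", "Pore-forming", None, 61, 70),
        TopologyFeature("I", "Transmembrane", "S6", 71, 80),
        TopologyFeature(None, "Cytoplasmic", None, 81, 100),
    ])
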