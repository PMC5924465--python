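import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ctenomito import MOLD, GenomeSpec, extract_feature_sequence, generate_genome, translate
from ctenomito.simulate import SMALL_GENE_MODELS


@pytest.fixture(scope="session")
def small_genome():
    """A scaled-down synthetic genome with its annotation and truth ledger."""
    spec = GenomeSpec(gene_models=SMALL_GENE_MODELS, n_urfs=1, seed=42)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def small_refs(small_genome):
    """Identity references (the planted proteins/rRNAs themselves)."""
    genome, ann, _ = small_genome
    prot = {
        f.label: translate(extract_feature_sequence(genome, f), MOLD)[:-1]
        for f in ann
        if f.kind == "protein"
    }
    rrna = {f.label: extract_feature_sequence(genome, f) for f in ann if f.kind == "rRNA"}
    return prot, rrna
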