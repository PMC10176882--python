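import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from morfkit.go import GoOntology, GoTerm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def toy_ontology() -> GoOntology:
    """Four-term MF ontology: root R; X is_a R; Y is_a R; Z is_a X."""
    return GoOntology(
        terms={
            "R": GoTerm("R", "root", "MF", ()),
            "X": GoTerm("X", "x", "MF", (("R", "is_a"),)),
            "Y": GoTerm("Y", "y", "MF", (("R", "is_a"),)),
            "Z": GoTerm("Z", "z", "MF", (("X", "is_a"),)),
        }
    )


def random_dag_ontology(rng: np.random.Generator, n_terms: int) -> GoOntology:
    """Random single-namespace DAG; term i may only point at terms < i."""
    terms = {"T000": GoTerm("T000", "root", "MF", ())}
    for i in range(1, n_terms):
        n_parents = int(rng.integers(1, min(i, 3) + 1))
        parent_ids = rng.choice(i, size=n_parents, replace=False)
        parents = tuple(
            (f"T{int(p):03d}", "is_a" if rng.random() < 0.8 else "part_of")
            for p in parent_ids
        )
        terms[f"T{i:03d}"] = GoTerm(f"T{i:03d}", f"t{i}", "MF", parents)
    return GoOntology(terms=terms)


def make_hit(
    query="q1",
    target="t1",
    database="afdb",
    bits=100.0,
    evalue=1e-10,
    ident=0.3,
    aln=100,
):
    from morfkit.hits import StructureHit

    return StructureHit(
        query_id=query,
        target_id=target,
        database=database,
        seq_identity=ident,
        aln_length=aln,
        mismatches=10,
        gap_opens=1,
        q_start=1,
        q_end=aln,
        t_start=1,
        t_end=aln,
        e_value=evalue,
        bit_score=bits,
    )
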