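import pytest

from hgflow.io_model import GeneAlignment, ROLES, RoleMap


def make_alignment(gene_id="geneX", **columns_by_role):
    """Build a GeneAlignment from per-role sequence strings."""
    return GeneAlignment(gene_id=gene_id, sequences=dict(columns_by_role))


def alignment_from_columns(columns, gene_id="geneX"):
    """Build a GeneAlignment from a list of 5-tuples ordered like ROLES."""
    seqs = {role: "".join(col[i] for col in columns) for i, role in enumerate(ROLES)}
    return GeneAlignment(gene_id=gene_id, sequences=seqs)


@pytest.fixture
def exact_roles():
    return RoleMap.exact()


@pytest.fixture
def uniform_alignment():
    """All five sequences identical (no variation at all)."""
    seq = "ACGTACGTACGT"
    return GeneAlignment(gene_id="uniform", sequences={r: seq for r in ROLES})
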