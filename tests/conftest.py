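import pytest

from zfpkit.synthetic_data import (
    generate_expression,
    generate_gene_order,
    generate_proteome,
    medicago_like_spec,
)

SEED = 7


@pytest.fixture(scope="session")
def study_spec():
    return medicago_like_spec(SEED)


@pytest.fixture(scope="session")
def study_truth(study_spec):
    """The full reference-scenario synthetic proteome (500 records)."""
    return generate_proteome(study_spec)


@pytest.fixture(scope="session")
def study_gene_order(study_spec, study_truth):
    return generate_gene_order(study_spec, study_truth.all_family_ids)


@pytest.fixture(scope="session")
def study_expression(study_spec, study_truth):
    return generate_expression(study_spec, study_truth.all_family_ids)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory, study_spec, study_truth, study_gene_order, study_expression):
    """The synthetic bundle written to disk, as the pipeline consumes it."""
    from zfpkit.synthetic_data import write_truth_fasta

    out = tmp_path_factory.mktemp("bundle")
    write_truth_fasta(study_truth, out / "proteome.faa")
    with open(out / "tfiiia.faa", "w") as fh:
        fh.write(f">{study_truth.tfiiia.id}\n{study_truth.tfiiia.sequence}\n")
    with open(out / "keep_drop.tsv", "w") as fh:
        for pid, verdict in sorted(study_truth.keep_drop.items()):
            fh.write(f"{pid}\t{verdict}\n")
    _, table, _ = study_gene_order
    table.to_csv(out / "gene_order.tsv", sep="\t", index=False)
    matrix, gene_map, _, _ = study_expression
    matrix.to_csv(out / "expression.tsv", sep="\t")
    with open(out / "gene_map.tsv", "w") as fh:
        for probeset, gene in sorted(gene_map.items()):
            fh.write(f"{gene}\t{probeset}\n")
    return out
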