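import pytest

from hspkit import expression, synthetic

SEED = 1


@pytest.fixture(scope="session")
def config():
    return synthetic.default_config(SEED)


@pytest.fixture(scope="session")
def proteome_fixture(config):
    return synthetic.generate_proteome(config)


@pytest.fixture(scope="session")
def promoter_fixture(config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("promoters")
    return synthetic.generate_promoters(config, outdir)


@pytest.fixture(scope="session")
def expression_fixture(config):
    return synthetic.generate_expression(config)


@pytest.fixture(scope="session")
def expr_matrix(expression_fixture):
    return expression.ExpressionMatrix(
        expression_fixture.fpkm, expression_fixture.samples
    )


@pytest.fixture(scope="session")
def fc_table(expr_matrix):
    return expression.fold_change_table(expr_matrix)
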