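import pytest

from causalnet import FixtureSpec, generate
from causalnet.pipeline import RunConfig

SMALL_SPEC = dict(n_tox=40, n_nontox=60, n_targets=50, n_pathways=10, n_decoy_edges=120)


def make_config(fixture_dir, outdir) -> RunConfig:
    return RunConfig(
        mechanisms=str(fixture_dir / "mechanisms.tsv"),
        assays=str(fixture_dir / "assays.tsv"),
        iuphar=str(fixture_dir / "iuphar.tsv"),
        drugbank=str(fixture_dir / "drugbank.tsv"),
        tox_compounds=str(fixture_dir / "tox_compounds.txt"),
        nontox_compounds=str(fixture_dir / "nontox_compounds.txt"),
        expression=str(fixture_dir / "expression.tsv"),
        string_edges=str(fixture_dir / "string_edges.tsv"),
        signor=str(fixture_dir / "signor.tsv"),
        pathways=str(fixture_dir / "pathways.gmt"),
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """One small generated data set shared across the session."""
    outdir = tmp_path_factory.mktemp("fixture")
    truth = generate(FixtureSpec(seed=11, **SMALL_SPEC), outdir)
    return outdir, truth
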