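import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table2_bundle(tmp_path_factory):
    """The bundled nine-MAG worked-example input bundle, written once per session."""
    from magtriage.fixtures import table2_fixture

    outdir = tmp_path_factory.mktemp("table2")
    table2_fixture(outdir)
    return outdir


@pytest.fixture()
def run_config_factory():
    """Build a RunConfig for a bundle directory laid out by the fixture generator."""
    from magtriage.cli import RunConfig

    def _make(bundle, **overrides):
        kwargs = dict(
            quality=bundle / "quality.tsv",
            ani=bundle / "ani.tsv",
            aai=bundle / "aai.tsv",
            taxonomy=bundle / "taxonomy.tsv",
            materials=bundle / "materials.tsv",
            out=bundle / "out",
        )
        for optional in ("pairwise_ani.tsv",):
            if (bundle / optional).exists():
                kwargs["pairwise_ani"] = bundle / optional
        if (bundle / "tblout").exists():
            kwargs["tblout"] = bundle / "tblout"
        kwargs.update(overrides)
        return RunConfig(**kwargs)

    return _make
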