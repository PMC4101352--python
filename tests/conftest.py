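import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from drugrepo import (
    GeneratorConfig,
    PhenotypePlan,
    RunConfig,
    TargetAssociation,
    generate_study,
    merge_sources,
    run_pipeline,
)
from drugrepo.ingest import DrugRecord, canonical_drug_key

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_unified(rows):
    """Build a UnifiedDrugTable from (drug, gene, source, indications, status) tuples."""
    assoc = []
    drugs = {}
    for drug, gene, source, indications, status in rows:
        key = canonical_drug_key(drug)
        assoc.append(
            TargetAssociation(
                drug_key=key,
                gene=gene,
                source=source,
                indications=frozenset(indications),
                status=status,
            )
        )
        rec = DrugRecord(drug_key=key, names={drug}, status=status, sources={source})
        if key in drugs:
            drugs[key].merge(rec)
        else:
            drugs[key] = rec
    return merge_sources([(assoc, drugs)])


@pytest.fixture
def mini_unified():
    """Small drug–target table with one replicated and several novel targets."""
    return make_unified(
        [
            ("Rosiglitazone", "PPARG", "ttd", {"Diabetes mellitus"}, "approved"),
            ("Pirenzepine", "CHRM1", "ttd", {"Peptic ulcer disease"}, "approved"),
            ("Aleglitazar", "PPARA", "ttd", {"Type 2 diabetes"}, "clinical"),
            ("Orphandrug", "GHR", "drugbank", set(), "approved"),
            ("Gemfibrozil", "LPL", "ttd", {"Hyperlipidemia"}, "approved"),
        ]
    )


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, rows, columns):
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    return _write


SMALL_CONFIG = GeneratorConfig(
    genome_size=2000,
    n_targets=400,
    phenotypes=(
        PhenotypePlan("T2D", 100, 0.30, 0.2, 4),
        PhenotypePlan("CD", 80, 0.25, 0.0, 0),
    ),
    space_multipliers=(2, 3, 4, 5, 7, 10),
    pred_fractions=(0.3, 0.45, 0.6, 0.75, 0.9, 1.0),
)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact two-phenotype study plus its pipeline bundle."""
    out = tmp_path_factory.mktemp("small_study") / "study"
    truth = generate_study(SMALL_CONFIG, seed=11, outdir=out)
    bundle = run_pipeline(RunConfig.from_json(out / "run.json"))
    return out, truth, bundle


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """The full seven-phenotype demo study plus its pipeline bundle."""
    out = tmp_path_factory.mktemp("demo_study") / "study"
    truth = generate_study(GeneratorConfig(), seed=7, outdir=out)
    bundle = run_pipeline(RunConfig.from_json(out / "run.json"))
    return out, truth, bundle
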