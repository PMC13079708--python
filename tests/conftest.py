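import warnings

import pytest

from pars.components import components_frame
from pars.synth import SynthConfig, generate_cohort, generate_knowledge_base

# constant components on small synthetic cohorts are expected and handled
warnings.filterwarnings("ignore", message="constant component")


@pytest.fixture(scope="session")
def small_sim():
    """A 150-patient synthetic cohort with its knowledge base (seeded)."""
    cfg = SynthConfig(n_patients=150)
    kb = generate_knowledge_base(cfg, seed=43)
    cohort, truth = generate_cohort(cfg, seed=42, kb=kb)
    return cfg, kb, cohort, truth


@pytest.fixture(scope="session")
def small_components(small_sim):
    _, kb, cohort, _ = small_sim
    return components_frame(cohort, kb)


@pytest.fixture()
def kb_dir(tmp_path):
    """A tiny hand-written knowledge-base directory."""
    (tmp_path / "ddi.csv").write_text(
        "drug_a,drug_b,severity\n"
        "Quetiapine,Haloperidol,major\n"
        "quetiapine,sertraline,moderate\n"
        "Quetiapine,Sertraline,moderate\n"  # duplicate of the row above
        "diazepam,sertraline,minor\n"
    )
    (tmp_path / "azcert.csv").write_text(
        "drug,category\nHaloperidol,Known\nclozapine,possible\nsertraline,conditional\n"
    )
    (tmp_path / "acb.csv").write_text(
        "drug,score\nclozapine,3\nhaloperidol,2\ndiazepam,1\nalprazolam,1\n"
    )
    (tmp_path / "sero.csv").write_text("drug\nsertraline\ntrazodone\n")
    return tmp_path
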