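import numpy as np
import pytest

from phageprofiler.readproc import ExtractionTemplate, SampleSpec, tally_peptides
from phageprofiler.simulate import (
    CleavageMotifModel,
    NNKLibraryConfig,
    SequencingConfig,
    simulate_experiment,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory):
    """Small planted P1-Arg experiment shared across tests.

    3000 clones, 4 samples x 50k pairs, motif: Arg at position 4
    (weight 4, intercept -3, ~15-fold probability contrast).
    """
    outdir = tmp_path_factory.mktemp("planted_run")
    lib_cfg = NNKLibraryConfig(n_clones=3000, abundance_log_sd=1.0, seed=101)
    planted = CleavageMotifModel.planted(position=4, residue="R", weight=4.0, intercept=-3.0)
    seq_cfg = SequencingConfig(n_read_pairs=50_000, per_base_error=0.001, seed=202)
    library, samples = simulate_experiment(lib_cfg, planted, seq_cfg, str(outdir))
    tmpl = ExtractionTemplate.from_library_config(lib_cfg)
    specs = [SampleSpec(s.name, s.r1, s.r2, s.role, s.replicate) for s in samples]
    table, qc = tally_peptides(specs, tmpl)
    return {
        "library": library,
        "motif": planted,
        "samples": samples,
        "specs": specs,
        "template": tmpl,
        "table": table,
        "qc": qc,
        "outdir": outdir,
    }


@pytest.fixture(scope="session")
def planted_records(planted_run):
    from phageprofiler.enrichment import run_enrichment

    return run_enrichment(planted_run["table"])


def random_peptides(n, rng, length=6):
    return ["".join(rng.choice(list(AA), length)) for _ in range(n)]
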