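import pandas as pd
import pytest

from mirmethyl.io import load_mature_mirnas
from mirmethyl.simulate import SimulationConfig, generate_methylation_dataset


@pytest.fixture(scope="session")
def mir199b():
    return load_mature_mirnas()["miR-199b-5p"]


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort with hosts and guaranteed co-methylation."""
    cfg = SimulationConfig(
        n_probes=400,
        n_mirna_genes=80,
        frac_hyper=0.3,
        frac_hypo=0.1,
        effect_size=2.5,
        noise_sd=0.5,
        host_probes_per_gene=4,
        frac_comethylated=1.0,
        seed=11,
    )
    return generate_methylation_dataset(cfg)


def toy_annotation(rows):
    """Annotation frame from (probe_id, mirna_gene, region, host, rel, ctx, host_region) tuples."""
    from mirmethyl.annotation import ANNOTATION_COLUMNS, validate_annotation

    return validate_annotation(pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)))
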