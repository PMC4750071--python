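import numpy as np
import pytest

from capture_qc import (
    generate_design,
    generate_reference,
    read_alignments,
    simulate_run,
    spike_variants,
)
from capture_qc.dedup import mark_duplicates
from capture_qc.simulate import PRESETS


@pytest.fixture(scope="session")
def toy_reference():
    return generate_reference(n_contigs=2, contig_length=60_000, gc_landscape=0.5, seed=11)


@pytest.fixture(scope="session")
def toy_design(toy_reference):
    return generate_design(
        toy_reference, n_regions=40, region_length_range=(150, 250), seed=12
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, toy_reference, toy_design):
    """One modest NimbleGen-preset run with spiked variants, fragments marked."""
    out = tmp_path_factory.mktemp("small_run")
    variants = spike_variants(
        toy_design, toy_reference, n_snv=40, n_indel=4, het_fraction=0.5, seed=13
    )
    truth = simulate_run(
        toy_reference,
        toy_design,
        PRESETS["nimblegen"],
        seed=14,
        out_dir=out,
        n_pairs=4000,
        variants=variants,
    )
    fragments, skipped = read_alignments(truth.files["sam"])
    mark_duplicates(fragments)
    return {
        "reference": toy_reference,
        "design": toy_design,
        "truth": truth,
        "fragments": fragments,
        "skipped": skipped,
        "dir": out,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
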