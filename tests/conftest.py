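import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from panatlas.config import PipelineConfig
from panatlas.database import PanDatabase, build_pan_database
from panatlas.records import ProteoformRecord, Source


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig(core_proteome_id="S01", random_seed=7)


def make_db(entries: list[tuple[str, str, str]]) -> PanDatabase:
    """Build a target database from (accession, sequence, strain) triples."""
    records = [
        ProteoformRecord(
            accession=acc,
            sequence=seq,
            source=Source.STRAIN,
            strain_ids=frozenset([strain]),
        )
        for acc, seq, strain in entries
    ]
    return build_pan_database(records)


@pytest.fixture(scope="session")
def synth_small():
    """A small seeded synthetic scenario shared by read-only tests."""
    from panatlas.simulate import SynthParams, generate_pan_proteome, simulate_psm_tables

    params = SynthParams(
        seed=11, n_strains=3, n_core=8, n_accessory=4, n_orphan_per_strain=2,
        n_runs=2, psms_per_run=500,
    )
    proteomes, truth = generate_pan_proteome(params)
    closed, open_, spectra, truth, db = simulate_psm_tables(proteomes, truth, params)
    return {
        "params": params,
        "proteomes": proteomes,
        "truth": truth,
        "closed": closed,
        "open": open_,
        "spectra": spectra,
        "db": db,
    }
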