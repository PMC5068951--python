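import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from barseqfit import (
    FitnessModel,
    SimulationConfig,
    generate_library,
    make_sample_sheet,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_design():
    return generate_library(30, barcode_length=20, seed=7)


@pytest.fixture(scope="session")
def small_fitness():
    # 3 planted strong, 3 medium, 3 weak effects among 30 mutants
    return FitnessModel.with_planted_classes(30, n_low=3, n_medium=3, n_high=3, seed=13)


@pytest.fixture(scope="session")
def small_sheet():
    return make_sample_sheet(["control", "toxin"], n_batches=1)


@pytest.fixture(scope="session")
def small_counts(small_design, small_fitness, small_sheet):
    config = SimulationConfig(n_mutants=30, reads_per_sample=20_000, seed=42)
    return simulate_experiment(small_design, {"toxin": small_fitness}, config, small_sheet)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="session")
def brute_force_counter():
    """Quadratic oracle: scan every (read, catalog) pair with plain Hamming distances."""

    def count(reads, catalog, sample_sheet, layout, max_mismatch):
        sheet = sample_sheet
        counts = pd.DataFrame(
            0,
            index=pd.Index(catalog.mutants, name="mutant_id"),
            columns=list(sheet["sample_id"]),
            dtype=np.int64,
        )
        for seq in reads:
            seq = seq.upper()
            sample = None
            for row in sheet.itertuples(index=False):
                if seq.startswith(row.index_seq.upper()):
                    sample = row
                    break
            if sample is None:
                continue
            offset = len(sample.index_seq) + len(layout.spacer)
            barcode = seq[offset : offset + layout.barcode_length]
            if len(barcode) < layout.barcode_length:
                continue
            dists = {
                mutant: hamming(barcode, bc)
                for mutant, bc in catalog.barcodes(sample.tag_class).items()
            }
            dmin = min(dists.values())
            if dmin > max_mismatch:
                continue
            winners = [m for m, d in dists.items() if d == dmin]
            if len(winners) == 1:
                counts.at[winners[0], sample.sample_id] += 1
        return counts

    return count
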