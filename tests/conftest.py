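import hypothesis
import numpy as np
import pytest

from shsweep.io import Alignment, SampleInfo, SequenceRecord, SpeciesMap
from shsweep.simulate import albonigra_like_model, default_locus, evolve_sequences, simulate_genealogy

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def toy_alignment():
    """Two species, three members each; planted diagnostic columns.

    Column 4 separates A (G) from B (T); column 9 separates B (C) from A (A);
    everything else is invariant.
    """
    base = list("ACGTGACGTA" * 2)  # 20 columns
    records = []
    for k in range(3):
        records.append(SequenceRecord(f"A{k + 1}", "".join(base)))
    other = list(base)
    other[4] = "T"
    other[9] = "C"
    for k in range(3):
        records.append(SequenceRecord(f"B{k + 1}", "".join(other)))
    return Alignment(records, {"ITS1": (0, 10), "ITS2": (10, 20)})


@pytest.fixture
def toy_species_map(toy_alignment):
    return SpeciesMap(
        {r.id: SampleInfo(species=r.id[0]) for r in toy_alignment.records}
    )


@pytest.fixture(scope="session")
def complex_dataset():
    """Clean simulated five-species complex: genealogy + alignment + map."""
    model = albonigra_like_model()
    genealogy = simulate_genealogy(model, {l: 4 for l in model.leaf_labels()}, 7)
    alignment = evolve_sequences(genealogy, default_locus(), 8)
    species_map = SpeciesMap(
        {t.id: SampleInfo(species=genealogy.tip_species[t.id]) for t in genealogy.tips()}
    )
    return model, genealogy, alignment, species_map


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
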