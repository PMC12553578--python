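import numpy as np
import pandas as pd
import pytest

from obsbias.synth import SynthConfig, generate_species_table, generate_occurrences


@pytest.fixture(scope="session")
def small_community():
    """A compact synthetic community with moderate counts, for pipeline tests."""
    cfg = SynthConfig(
        n_species=120,
        n_orders=8,
        seed=11,
        count_model="lognormal",
        lognormal_mu=2.2,
        lognormal_sigma=1.1,
        effort_weight=0.8,
        subspecies_frac=0.05,
    )
    table, truth = generate_species_table(cfg)
    occ = generate_occurrences(table, truth, cfg)
    return cfg, table, truth, occ


@pytest.fixture()
def synthetic_files(tmp_path, small_community):
    """Occurrence + trait CSVs on disk, as the ingest stage reads them."""
    _, table, truth, occ = small_community
    traits = tmp_path / "traits.csv"
    occs = tmp_path / "occurrences.csv"
    table.drop(columns=["n_obs"]).to_csv(traits, index=False)
    occ.to_csv(occs, index=False)
    return occs, traits, table, truth


@pytest.fixture()
def toy_occurrences(tmp_path):
    df = pd.DataFrame(
        {
            "species": [
                "Odocoileus virginianus clavium",
                "Canis latrans",
                "Felis catus",
                "Felis catus",
                "Puma concolor",
            ],
            "taxonRank": ["subspecies", "species", "species", "species", "species"],
            "order": ["Artiodactyla", "Carnivora", "Carnivora", "Carnivora", "Carnivora"],
            "eventDate": [
                "2024-06-01T14:30:00",
                "2024-06-02",
                "2024-06-03T23:15:00",
                "2024-06-04T08:00:00",
                "2024-06-05T06:30:00",
            ],
            "realm": ["Nearctic", "Nearctic", "Nearctic", "Nearctic", "Neotropical"],
        }
    )
    path = tmp_path / "occ.csv"
    df.to_csv(path, index=False)
    return path
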