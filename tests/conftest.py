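import numpy as np
import pandas as pd
import pytest

from microstrata.datatypes import AsvTable, TaxonomyTable, validate_metadata
from microstrata.simulate import SyntheticConfig, generate_study


def make_metadata(rows):
    return validate_metadata(pd.DataFrame(rows))


def sample_row(sample_id, participant="P01", cohort="HC", status="HC",
               depth="surface", tp=1, location="volar_forearm", oscorad=None,
               filaggrin=None, negative=False):
    if negative:
        return {
            "sample_id": sample_id, "participant_id": "", "cohort": "",
            "skin_status": "", "depth": "", "timepoint": None,
            "body_location": "", "oscorad": None, "filaggrin_mutation": None,
            "is_negative_control": True,
        }
    return {
        "sample_id": sample_id, "participant_id": participant,
        "cohort": cohort, "skin_status": status, "depth": depth,
        "timepoint": tp, "body_location": location, "oscorad": oscorad,
        "filaggrin_mutation": filaggrin, "is_negative_control": False,
    }


@pytest.fixture
def toy_filter_fixture():
    """Hand-built preprocessing fixture: 20 samples + 12 negatives, 10 ASVs.

    Planted removals: C1 (11/12 negatives) and C2 (10/12) by the
    negative-control filter; R1 (4 samples) by the prevalence filter; X1
    (Chloroplast lineage) by the taxonomy filter. G1..G6 survive.
    """
    asv_ids = ["G1", "G2", "G3", "G4", "G5", "G6", "C1", "C2", "R1", "X1"]
    samples = [f"S{i:02d}" for i in range(1, 21)]
    negatives = [f"N{i:02d}" for i in range(1, 13)]
    values = np.zeros((32, 10))
    values[:20, 0:6] = 10.0            # G1..G6 everywhere
    values[:15, 6] = 5.0               # C1 in 15 samples
    values[:10, 7] = 5.0               # C2 in 10 samples
    values[:4, 8] = 7.0                # R1 in 4 samples only
    values[:20, 9] = 8.0               # X1 everywhere (chloroplast)
    values[20:31, 6] = 50.0            # C1 in 11 negatives
    values[20:30, 7] = 30.0            # C2 in exactly 10 negatives
    table = AsvTable(samples + negatives, asv_ids, values)

    meta_rows = []
    for i, sid in enumerate(samples):
        meta_rows.append(
            sample_row(sid, participant=f"P{i // 2 + 1:02d}", tp=i % 2 + 1)
        )
    for sid in negatives:
        meta_rows.append(sample_row(sid, negative=True))
    meta = make_metadata(meta_rows)

    lineages = {}
    for a in asv_ids:
        lineages[a] = {
            "domain": "Bacteria", "phylum": "Firmicutes", "class": "Bacilli",
            "order": "Lactobacillales", "family": "Streptococcaceae",
            "genus": "Streptococcus", "species": "",
        }
    lineages["X1"] = {
        "domain": "Bacteria", "phylum": "Cyanobacteria", "class": "Cyanobacteriia",
        "order": "Chloroplast", "family": "", "genus": "", "species": "",
    }
    tax = TaxonomyTable(pd.DataFrame.from_dict(lineages, orient="index"))

    expected = {
        "negative_control": {"C1", "C2"},
        "prevalence": {"R1"},
        "taxonomy": {"X1"},
        "survivors": {"G1", "G2", "G3", "G4", "G5", "G6"},
    }
    return table, meta, tax, expected


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured simulated study (deterministic)."""
    cfg = SyntheticConfig(
        seed=42, n_participants_ad=5, n_participants_hc=5, n_timepoints=4,
        n_asvs_global=300, reads_mean=5000.0, n_contaminant_asvs=15,
        n_negatives=12, n_core_asvs_per_participant=20, n_pathobiont_asvs=5,
        depth_retention_fraction=0.5, status_effect=0.25,
    )
    return generate_study(cfg)
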