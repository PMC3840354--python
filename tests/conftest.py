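import pandas as pd
import pytest

from mpnpipe.catalog import Catalog, CatalogEntry, HitRecord, hits_to_frame
from mpnpipe.functional import profile_kos
from mpnpipe.partition import partition
from mpnpipe.simulate import default_scenario, simulate


def make_entry(
    subject_id,
    taxon="TaxonA",
    order="OrderA",
    ko=None,
    length=300,
    family=None,
    entry_class="protein",
    species=None,
):
    return CatalogEntry(
        subject_id=subject_id,
        taxon_id=taxon,
        lineage=("Bacteria", "PhylumX", "ClassX", order, species or taxon),
        entry_class=entry_class,
        ko_id=ko,
        protein_length=length,
        family=family,
    )


def hits(rows, catalog="protein"):
    """rows: iterable of (read_id, subject_id, bit_score[, pident])."""
    records = []
    for row in rows:
        read, subj, score = row[0], row[1], row[2]
        pid = row[3] if len(row) > 3 else 90.0
        records.append(HitRecord(read, subj, pid, score, catalog))
    return hits_to_frame(records)


@pytest.fixture(scope="session")
def default_sim():
    """One full default-scenario simulation shared across the session."""
    return simulate(default_scenario(seed=101, reads_per_library=20000))


@pytest.fixture(scope="session")
def default_parts(default_sim):
    return {
        m.library_id: partition(default_sim.hit_tables[m.library_id], m)
        for m in default_sim.manifests
    }


@pytest.fixture(scope="session")
def rna_ko_profiles(default_sim, default_parts):
    out = {}
    for m in default_sim.manifests:
        if m.molecule != "RNA":
            continue
        out[m.library_id] = profile_kos(
            default_sim.hit_tables[m.library_id]["kegg"],
            default_sim.catalog,
            partition=default_parts[m.library_id],
            library_id=m.library_id,
        )
    return out
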