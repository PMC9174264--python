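import numpy as np
import pandas as pd
import pytest

from periobiome.synth import StudyDesign, generate_study
from periobiome.tables import AbundanceTable, CountTable


@pytest.fixture(scope="session")
def default_study():
    """One default 8-group x 6-mouse synthetic study, shared read-only."""
    design = StudyDesign(seed=11)
    table, meta, markers, truth = generate_study(design)
    return {"design": design, "counts": table, "meta": meta, "markers": markers, "truth": truth}


def make_count_table(counts, groups=None, level="species", kingdom="bacteria"):
    """Small hand-built CountTable from a dict {taxon: [counts per sample]}."""
    data = pd.DataFrame(counts).T
    data.columns = [f"s{i + 1}" for i in range(data.shape[1])]
    taxa = pd.DataFrame(
        {"name": data.index, "level": level, "kingdom": kingdom}, index=data.index
    )
    samples = pd.DataFrame(index=data.columns)
    if groups is not None:
        samples["group"] = groups
    return CountTable(data=data, taxa=taxa, samples=samples)


def make_abundance_table(values, groups=None, level="species", kingdom="bacteria"):
    """Small hand-built AbundanceTable from {taxon: [RPM per sample]}."""
    data = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()}).T
    data.columns = [f"s{i + 1}" for i in range(data.shape[1])]
    if isinstance(kingdom, dict):
        kingdoms = [kingdom[t] for t in data.index]
    else:
        kingdoms = kingdom
    taxa = pd.DataFrame(
        {"name": data.index, "level": level, "kingdom": kingdoms}, index=data.index
    )
    samples = pd.DataFrame(index=data.columns)
    if groups is not None:
        samples["group"] = groups
    return AbundanceTable(data=data, taxa=taxa, samples=samples)
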