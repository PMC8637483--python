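import numpy as np
import pandas as pd
import pytest

from contamscope.simulate import SimulationConfig, generate_study
from contamscope.tables import FeatureTable, SampleMetadata

#: The one study seed used by the end-to-end fixtures.
STUDY_SEED = 7


def random_table_with_controls(rng, max_taxa=20, max_samples=12, max_controls=3):
    """Small random count table plus metadata with 1-3 negative controls."""
    n_taxa = rng.integers(2, max_taxa + 1)
    n_controls = rng.integers(1, max_controls + 1)
    n_specimens = rng.integers(2, max_samples - n_controls + 1)
    n = n_specimens + n_controls
    counts = rng.integers(0, 50, size=(n_taxa, n))
    # guard against zero-total samples (relative mode precondition)
    for j in range(n):
        if counts[:, j].sum() == 0:
            counts[rng.integers(0, n_taxa), j] = 1
    ids = [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{j}" for j in range(n)]
    roles = ["specimen"] * n_specimens + ["negative_control"] * n_controls
    table = FeatureTable(pd.DataFrame(counts, index=ids, columns=samples))
    md = SampleMetadata(pd.DataFrame(
        {"role": roles, "replicate": "r1"}, index=samples))
    return table, md


def brute_force_major_flags(table, metadata, mode, tau=0.8):
    """Independent per-taxon evaluation of the two major-contaminant
    criteria; abundance means compared in exact rational arithmetic."""
    from fractions import Fraction

    md = metadata.data.loc[table.sample_ids]
    specs = [s for s in table.sample_ids if md.loc[s, "role"] == "specimen"]
    ctrls = [s for s in table.sample_ids if md.loc[s, "role"] == "negative_control"]
    flags = {}
    totals = {s: int(sum(table.data[s])) for s in table.sample_ids}
    for t in table.taxon_ids:
        present = sum(1 for s in specs if table.data.at[t, s] > 0)
        prevalence = present / len(specs)
        if mode == "relative":
            vals_c = [Fraction(int(table.data.at[t, s]), totals[s]) for s in ctrls]
            vals_s = [Fraction(int(table.data.at[t, s]), totals[s]) for s in specs]
        else:
            vals_c = [Fraction(int(table.data.at[t, s])) for s in ctrls]
            vals_s = [Fraction(int(table.data.at[t, s])) for s in specs]
        mean_c = sum(vals_c) / len(vals_c)
        mean_s = sum(vals_s) / len(vals_s)
        flags[t] = (prevalence >= tau) and (mean_c > mean_s)
    return flags


def brute_force_prevalence_flags(table, metadata, threshold=0.5):
    md = metadata.data.loc[table.sample_ids]
    specs = [s for s in table.sample_ids if md.loc[s, "role"] == "specimen"]
    ctrls = [s for s in table.sample_ids if md.loc[s, "role"] == "negative_control"]
    flags = {}
    for t in table.taxon_ids:
        p_c = sum(1 for s in ctrls if table.data.at[t, s] > 0) / len(ctrls)
        p_s = sum(1 for s in specs if table.data.at[t, s] > 0) / len(specs)
        ratio = p_c / (p_c + p_s) if (p_c + p_s) > 0 else 0.0
        flags[t] = ratio > threshold
    return flags


@pytest.fixture(scope="session")
def default_study():
    cfg = SimulationConfig(seed=STUDY_SEED)
    return cfg, generate_study(cfg)


@pytest.fixture()
def toy_table_metadata():
    """5 specimens + 2 controls, equal totals; taxa A/B/C exercise the
    major-contaminant decision boundary."""
    #             s1  s2  s3  s4  s5   c1  c2
    counts = [
        [50, 50, 50, 50, 50, 90, 90],   # A: everywhere, enriched in controls
        [30, 30, 0, 0, 0, 5, 5],        # B: prevalence 0.4, control mean higher
        [20, 20, 50, 50, 50, 5, 5],     # C: everywhere, lower in controls
    ]
    pad = np.array([[0, 0, 0, 0, 0, 0, 0]])
    arr = np.vstack([np.array(counts), pad])
    # make every column sum to 100 via a filler taxon
    filler = 100 - arr.sum(axis=0)
    arr = np.vstack([arr[:3], filler])
    samples = ["s1", "s2", "s3", "s4", "s5", "c1", "c2"]
    table = FeatureTable(pd.DataFrame(arr, index=["A", "B", "C", "D"],
                                      columns=samples))
    md = SampleMetadata(pd.DataFrame(
        {"role": ["specimen"] * 5 + ["negative_control"] * 2,
         "replicate": ["r1"] * 7}, index=samples))
    return table, md
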