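"""Shared fixtures: simulated libraries, databases, and small trained models.

Expensive simulations are session-scoped and seeded so every test sees the
same study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ndegron import (
    MotifDatabase,
    database_from_counts_df,
    model as stab,
    simulate as sim,
)

RECOVERY_SEED = 11
RECOVERY_N_MOTIFS = 20_000
RECOVERY_TOTAL_READS = 4_000_000  # ~200 reads per motif


@pytest.fixture(scope="session")
def recovery_pair() -> dict[str, MotifDatabase]:
    """WT and ClpS-knockout databases simulated from a model whose only
    effect is a ClpS-dependent (F, P1) = -1.0 destabilization."""
    rng = np.random.default_rng(RECOVERY_SEED)
    library = sim.build_library(rng, RECOVERY_N_MOTIFS)
    effects = sim.single_effect_model("F", 1, -1.0, clps_dependent=True)
    sort = sim.SortModel()
    out = {}
    for genotype in ("WT", "CLPS_KO"):
        counts, _ = sim.simulate_bin_counts(
            library, effects, sort, genotype, rng, total_reads=RECOVERY_TOTAL_READS
        )
        out[genotype] = database_from_counts_df(counts, genotype)
    return out


@pytest.fixture(scope="session")
def additive_sim():
    """A WT database simulated from the purely additive effect preset,
    together with its generating model and ground truth."""
    rng = np.random.default_rng(RECOVERY_SEED)
    library = sim.build_library(rng, RECOVERY_N_MOTIFS)
    effects = sim.example_effect_model(include_pairs=False)
    sort = sim.SortModel()
    counts, truth = sim.simulate_bin_counts(
        library, effects, sort, "WT", rng, total_reads=RECOVERY_TOTAL_READS
    )
    return {
        "db": database_from_counts_df(counts, "WT"),
        "effects": effects,
        "truth": truth,
    }


def make_formula_db(
    motifs, psi_fn, genotype: str = "WT", total: int = 100
) -> MotifDatabase:
    """A database whose PSI is a deterministic function of the motif —
    convenient ground truth for analytics that are pure functions of the
    (motif, psi) table."""
    records = pd.DataFrame({"motif": sorted(set(motifs))})
    records["psi"] = records["motif"].map(psi_fn).clip(1.0, 4.0)
    for col in ("count_b1", "count_b2", "count_b3", "count_b4"):
        records[col] = total // 4
    records["total"] = total
    return MotifDatabase(genotype=genotype, records=records)


@pytest.fixture(scope="session")
def random_motifs() -> list[str]:
    rng = np.random.default_rng(5)
    return stab.sample_motifs(rng, 4000)


@pytest.fixture(scope="session")
def small_model(random_motifs):
    """A quick-to-train model on noise-free additive labels, for unit tests
    of prediction, selection, and attribution mechanics."""
    effects = sim.example_effect_model(include_pairs=False)
    labels = np.array([sim.true_stability(m, effects, "WT") for m in random_motifs])
    config = stab.ModelConfig(
        n_estimators=150, max_depth=6, min_reads=0, split_seed=3, training_seed=3
    )
    data = stab.encode(random_motifs, labels)
    rng = np.random.default_rng(3)
    order = rng.permutation(len(random_motifs))
    cut = int(0.8 * len(order))

    def take(idx):
        return stab.EncodedDataset(
            features=data.features[idx],
            labels=data.labels[idx],
            motifs=[data.motifs[i] for i in idx],
        )

    model = stab.train(take(order[:cut]), take(order[cut:]), config)
    return {"model": model, "effects": effects}
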