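import numpy as np
import pandas as pd
import pytest

from notchscore import (
    EvidenceVector,
    PathwayModel,
    ProbesetEntry,
    ProbesetMap,
    freeze,
    load_config,
    make_panel,
)


@pytest.fixture(scope="session")
def shipped():
    """(panel, probeset_map) of the shipped Notch configuration."""
    return load_config()


def build_model(
    genes,
    probesets_per_gene=1,
    a=0.9,
    b=0.1,
    c=0.8,
    d=0.2,
    prior=0.5,
    thresholds=7.0,
    frozen=True,
):
    """Small hand-built model: uniform CPTs, synthetic probeset ids."""
    panel = make_panel(genes)
    entries = tuple(
        ProbesetEntry(f"{g}_ps{k}", g, True)
        for g in genes
        for k in range(1, probesets_per_gene + 1)
    )
    pmap = ProbesetMap(entries=entries)
    model = PathwayModel(
        panel=panel,
        probeset_map=pmap,
        prior_active=prior,
        gene_cpt={g: (a, b) for g in genes},
        probeset_cpt={e.probeset_id: (c, d) for e in entries},
        thresholds={e.probeset_id: float(thresholds) for e in entries},
    )
    return freeze(model) if frozen else model


def random_model(rng: np.random.Generator, max_genes=5, max_probesets=3):
    """Random small model respecting the CPT ordering invariants."""
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = [f"G{i+1}" for i in range(n_genes)]
    panel = make_panel(genes)
    entries = []
    gene_cpt, probeset_cpt, thresholds = {}, {}, {}
    for g in genes:
        b = float(rng.uniform(0.02, 0.45))
        a = float(rng.uniform(b + 0.05, 0.98))
        gene_cpt[g] = (a, b)
        for k in range(int(rng.integers(1, max_probesets + 1))):
            j = f"{g}_ps{k+1}"
            entries.append(ProbesetEntry(j, g, True))
            d = float(rng.uniform(0.02, 0.45))
            c = float(rng.uniform(d + 0.05, 0.98))
            probeset_cpt[j] = (c, d)
            thresholds[j] = float(rng.uniform(5, 9))
    model = PathwayModel(
        panel=panel,
        probeset_map=ProbesetMap(entries=tuple(entries)),
        prior_active=float(rng.uniform(0.1, 0.9)),
        gene_cpt=gene_cpt,
        probeset_cpt=probeset_cpt,
        thresholds=thresholds,
    )
    return freeze(model)


def random_evidence(model: PathwayModel, rng: np.random.Generator, p_missing=0.2):
    calls = {}
    for j in model.all_active_probesets():
        u = rng.random()
        calls[j] = "missing" if u < p_missing else ("high" if u < (1 + p_missing) / 2 else "low")
    if all(v == "missing" for v in calls.values()):
        calls[next(iter(calls))] = "high"
    return EvidenceVector(sample_id="s", calls=calls)


def auc(pos, neg):
    """Rank-based AUC (probability a positive outscores a negative)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    both = np.concatenate([pos, neg])
    ranks = pd.Series(both).rank().to_numpy()
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))
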