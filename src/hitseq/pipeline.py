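"""End-to-end convenience drivers: landscape -> reads -> counts -> affinities."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .affinity import AffinityTable, relative_affinity
from .reads import CountTable, count_reads, normalize_counts
from .simulate import (
    AffinityLandscape,
    ConstructLayout,
    SimulationConfig,
    sample_reads,
    simulate_equilibrium,
)


def run_simulation(
    landscape: AffinityLandscape, config: SimulationConfig
) -> tuple[CountTable, pd.DataFrame]:
    """Simulate reads and count them; returns (counts, libraries table)."""
    layout = ConstructLayout()
    composition = simulate_equilibrium(landscape, config)
    reads = sample_reads(composition, layout, config)
    libraries = config.libraries()
    index_table = dict(zip(libraries["index"], libraries["label"]))
    counts = count_reads(
        reads, index_table, layout, control_label=libraries["label"][0]
    )
    return counts, libraries


def estimate_affinities(
    counts: CountTable,
    libraries: pd.DataFrame,
    reference: str = "UGCAUGU",
    ref_k_half: float = 1.6,
    pseudocount: float = 0.5,
    which: str = "raw",
    estimator: str = "median",
) -> AffinityTable:
    """Counts -> control-normalised depletion -> K_A,rel."""
    normalized = normalize_counts(counts, pseudocount=pseudocount, which=which)
    concs = dict(zip(libraries["label"], libraries["conc_nM"]))
    return relative_affinity(
        normalized, concs, reference=reference, ref_k_half=ref_k_half,
        estimator=estimator, counts=counts.table(which),
    )


def exact_affinities(
    landscape: AffinityLandscape,
    config: SimulationConfig,
    reference: str = "UGCAUGU",
    ref_k_half: float | None = None,
    estimator: str = "median",
) -> AffinityTable:
    """Noise-free path: estimate K_A,rel from exact equilibrium compositions.

    Uses the landscape's true reference Kd as the concentration unit when
    ``ref_k_half`` is None, so the estimator should return kd_ref/kd exactly.
    """
    composition = simulate_equilibrium(landscape, config)
    control = config.labels[0]
    # frequency-normalise exactly as the count path does, so the pool
    # renormalisation factor seen by the estimators matches the observable
    freqs = composition / composition.sum(axis=0)
    normalized = freqs.div(freqs[control], axis=0)
    concs = dict(zip(config.labels, config.protein_concs))
    if ref_k_half is None:
        ref_k_half = landscape.kd_of(reference)
    return relative_affinity(
        normalized, concs, reference=reference, ref_k_half=ref_k_half,
        estimator=estimator,
    )


def informative_mask(
    landscape: AffinityLandscape, config: SimulationConfig
) -> np.ndarray:
    """Variants whose Kd lies between the smallest and largest protein concs."""
    nonzero = [c for c in config.protein_concs if c > 0]
    return (landscape.kd >= min(nonzero)) & (landscape.kd <= max(nonzero))
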