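"""Shared fixtures: small synthetic datasets and a cached full DE run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deprofiler.io import AnalysisConfig, CountMatrix, SampleMeta
from deprofiler.simulate import default_scenario, generate_counts
from deprofiler import de as de_mod


@pytest.fixture(scope="session")
def small_counts() -> tuple[CountMatrix, list[SampleMeta]]:
    """A tiny deterministic 6-gene x 8-sample 2x2 dataset."""
    rng = np.random.default_rng(7)
    genes = [f"gene{i}" for i in range(6)]
    samples, metas = [], []
    for geno in ("wt", "ko"):
        for tg in ("nontg", "tg"):
            for r in (1, 2):
                sid = f"{geno}_{tg}_{r}"
                samples.append(sid)
                metas.append(SampleMeta(sid, geno, tg))
    counts = rng.poisson(50, size=(6, 8))
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    return cm, metas


@pytest.fixture(scope="session")
def ad_like_run():
    """One full DE run on the ad_like scenario (seed 3), shared read-only.

    Expensive (~10 s); session-scoped so recovery, clustering and signature
    tests reuse it.
    """
    scenario = default_scenario("ad_like", seed=3)
    cm, metas, truth = generate_counts(scenario)
    config = AnalysisConfig(base_seed=3)
    de, norm, disp = de_mod.run_de(cm, metas, config)
    return {
        "scenario": scenario,
        "counts": cm,
        "metas": metas,
        "truth": truth,
        "config": config,
        "de": de,
        "norm": norm,
        "dispersion": disp,
    }
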