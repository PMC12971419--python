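"""Over-representation enrichment, combined-score ranking, and signature panels.

Enrichment follows the Enrichr recipe: each gene-set term is tested for
over-representation of the DEG list in a fixed universe with the
hypergeometric upper tail, BH-adjusted across terms, and ranked with a
combined score c = -ln(p) x z. The z-score here is the analytic
standardization of the overlap under the hypergeometric null,
z = (x - nK/N) / sd(x) — a deterministic stand-in for Enrichr's
simulation-derived rank z with the same monotone intent.

Signature panels ship marker lists for microglial states (homeostatic,
stage-1/2 disease-associated microglia, the core interferon-responsive
signature, and nucleic-acid sensors) for per-contrast fold-change scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisConfig, GeneSetLibrary, InputError
from .de import DEResult, bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    """One term's over-representation statistics."""

    term: str
    overlap: int  # x
    set_size: int  # K (after universe intersection)
    list_size: int  # n
    universe_size: int  # N
    p: float
    fdr: float
    z: float
    combined: float
    genes: tuple[str, ...] = ()


def fisher_term_test(
    deg_list: Sequence[str], term_genes: Sequence[str], universe: Sequence[str]
) -> tuple[int, int, int, int, float]:
    """Hypergeometric upper-tail over-representation test for one term.

    Returns (x, K, n, N, p) where p = P(X >= x) under
    Hypergeom(N, K, n). The term is intersected with the universe first;
    the DEG list must be a subset of the universe.
    """
    uni = set(universe)
    degs = set(deg_list)
    if not degs:
        raise InputError("no DEGs to test")
    outside = degs - uni
    if outside:
        raise InputError(f"DEGs outside the universe: {sorted(outside)[:5]}")
    term = set(term_genes) & uni
    x = len(degs & term)
    K = len(term)
    n = len(degs)
    N = len(uni)
    if K == 0:
        return 0, 0, n, N, 1.0
    p = float(stats.hypergeom.sf(x - 1, N, K, n))
    return x, K, n, N, min(p, 1.0)


def enrichment_z(x: int, K: int, n: int, N: int) -> float:
    """Standardized overlap deviation under the hypergeometric null.

    z = (x - nK/N) / sqrt(n (K/N)(1 - K/N)(N - n)/(N - 1)); defined as 0
    when the null variance vanishes.
    """
    if N <= 1:
        return 0.0
    mean = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
    if var <= 0:
        return 0.0
    return float((x - mean) / math.sqrt(var))


def combined_score(p: float, z: float) -> float:
    """Enrichr-style combined score c = -ln(p) x z."""
    if not (0 < p <= 1):
        raise InputError(f"p-value {p} outside (0, 1]")
    return float(-math.log(p) * z)


def enrich_library(
    deg_list: Sequence[str],
    library: GeneSetLibrary,
    universe: Sequence[str],
    include_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Test every library term against the DEG list; rank by FDR.

    Terms with zero overlap (or empty after universe intersection) are
    excluded from testing and BH correction unless ``include_zero_overlap``.
    Output columns: term, overlap, set_size, list_size, universe_size, p,
    fdr, z, combined, neg_log10_fdr, genes — sorted by FDR ascending, then
    p, then term name.
    """
    if len(library) == 0:
        raise InputError("empty gene-set library")
    if len(set(universe)) == 0:
        raise InputError("empty universe")
    uni = set(universe)
    degs = set(deg_list)
    rows = []
    skipped = []
    for term, genes in library.sets.items():
        x, K, n, N, p = fisher_term_test(deg_list, genes, universe)
        if (x == 0 or K == 0) and not include_zero_overlap:
            skipped.append(term)
            continue
        z = enrichment_z(x, K, n, N)
        rows.append(
            {
                "term": term,
                "overlap": x,
                "set_size": K,
                "list_size": n,
                "universe_size": N,
                "p": p,
                "z": z,
                "combined": combined_score(p, z),
                "genes": ",".join(sorted(degs & set(genes) & uni)),
            }
        )
    if skipped:
        logger.info("terms with no overlap skipped: %d", len(skipped))
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "overlap", "set_size", "list_size", "universe_size",
                "p", "fdr", "z", "combined", "neg_log10_fdr", "genes",
            ]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"])
    df["neg_log10_fdr"] = -np.log10(df["fdr"])
    df = df.sort_values(
        ["fdr", "p", "term"], kind="mergesort"
    ).reset_index(drop=True)
    cols = [
        "term", "overlap", "set_size", "list_size", "universe_size",
        "p", "fdr", "z", "combined", "neg_log10_fdr", "genes",
    ]
    return df[cols]


def bubble_table(enrichment: pd.DataFrame, top: int = 10) -> pd.DataFrame:
    """Bubble-plot input: term, -log10 FDR, combined score, overlap size."""
    return enrichment.head(top)[
        ["term", "neg_log10_fdr", "combined", "overlap"]
    ].reset_index(drop=True)


# ---------------------------------------------------------------------------
# signature panels


@dataclass
class SignaturePanel:
    """A named marker-gene panel for per-contrast scoring."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"signature panel {self.name!r} is empty")
        self.genes = list(dict.fromkeys(self.genes))


def default_panels() -> list[SignaturePanel]:
    """Shipped microglial-state marker panels.

    Homeostatic and stage-1/2 disease-associated microglia (DAM) markers
    follow the established staging (stage 1 Trem2-independent, stage 2
    Trem2-dependent); the interferon-responsive microglia (IRM) core list
    and the nucleic-acid sensor list cover the canonical type-I IFN
    signature and pattern-recognition receptors.
    """
    return [
        SignaturePanel(
            "homeostatic",
            ["C1qa", "C1qb", "C1qc", "Csf1r", "P2ry12", "Tmem119", "Cx3cr1",
             "Hexb"],
        ),
        SignaturePanel(
            "dam_stage1",
            ["Apoe", "Tyrobp", "B2m", "Ctsb", "Trem2", "Fth1", "Lyz2"],
        ),
        SignaturePanel(
            "dam_stage2",
            ["Clec7a", "Axl", "Csf1", "Cst7", "Itgax", "Gpnmb", "Lpl"],
        ),
        SignaturePanel(
            "irm_core",
            ["Ifnar2", "Stat2", "Oas1a", "Oas2", "Oas3", "Irf7", "Gbp2",
             "Isg15", "Irf9", "Mx1", "Ifit3", "Ifitm3", "Usp18"],
        ),
        SignaturePanel(
            "nucleic_acid_sensors",
            ["Tlr3", "Ifih1", "Ddx58", "Ifi204", "Ifi209", "Ifi211", "Zbp1"],
        ),
    ]


def signature_table(
    de: DEResult,
    panels: Sequence[SignaturePanel],
    contrast_name: str,
    fdr_star: float = 0.05,
    fdr_hash: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Per-gene fold changes and per-panel summaries for one contrast.

    Significance tiers mirror heatmap annotation conventions: ``*`` for
    FDR < 0.05 and ``##`` for FDR < 0.001. Panel genes missing from the
    results are reported in the returned ``missing`` mapping, never dropped
    silently.

    Returns (gene_table, panel_summary, missing).
    """
    if contrast_name not in de.pairwise:
        raise InputError(f"contrast {contrast_name!r} not in DE results")
    tab = de.pairwise[contrast_name]
    rows = []
    missing: dict[str, list[str]] = {}
    summaries = []
    for panel in panels:
        present = [g for g in panel.genes if g in tab.index]
        absent = [g for g in panel.genes if g not in tab.index]
        if absent:
            missing[panel.name] = absent
        sub = tab.loc[present]
        for gene in present:
            fdr = float(sub.loc[gene, "fdr"])
            tier = "##" if fdr < fdr_hash else ("*" if fdr < fdr_star else "")
            rows.append(
                {
                    "panel": panel.name,
                    "gene": gene,
                    "log2fc": float(sub.loc[gene, "log2fc"]),
                    "fdr": fdr,
                    "tier": tier,
                }
            )
        summaries.append(
            {
                "panel": panel.name,
                "n_genes": len(panel.genes),
                "n_present": len(present),
                "n_missing": len(absent),
                "mean_log2fc": float(sub["log2fc"].mean()) if present else np.nan,
                "frac_significant": float((sub["fdr"] < fdr_star).mean())
                if present
                else np.nan,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(summaries), missing


def volcano_table(
    de: DEResult, contrast_name: str, config: AnalysisConfig
) -> pd.DataFrame:
    """Volcano-plot input: log2fc, -log10 FDR, up/down/ns category.

    up: FDR < deg_fdr and log2FC > deg_abs_log2fc; down: FDR < deg_fdr and
    log2FC < -deg_abs_log2fc; ns otherwise.
    """
    if contrast_name not in de.pairwise:
        raise InputError(f"contrast {contrast_name!r} not in DE results")
    tab = de.pairwise[contrast_name]
    fdr = tab["fdr"].to_numpy(float)
    lfc = tab["log2fc"].to_numpy(float)
    category = np.where(
        (fdr < config.deg_fdr) & (lfc > config.deg_abs_log2fc),
        "up",
        np.where(
            (fdr < config.deg_fdr) & (lfc < -config.deg_abs_log2fc), "down", "ns"
        ),
    )
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "neg_log10_fdr": -np.log10(np.maximum(fdr, 1e-300)),
            "category": category,
        },
        index=tab.index,
    )
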