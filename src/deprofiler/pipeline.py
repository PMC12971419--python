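"""End-to-end orchestration: simulate/load -> DE -> clustering -> enrichment.

A run writes per-stage TSV outputs plus a machine-readable JSON report
(resolved config, seeds, per-stage summaries, package version). Identical
config + seed gives identical outputs; only the timestamp differs.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from . import __version__
from .io import (
    AnalysisConfig,
    CountMatrix,
    GeneSetLibrary,
    InputError,
    align_meta,
    read_counts,
    read_meta,
    write_counts,
    write_meta,
)
from . import de as de_mod
from . import clustering as cl_mod
from . import enrichment as en_mod
from .simulate import default_scenario, generate_counts

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """Structured record of one pipeline run."""

    config: dict
    seed: int | None
    stages: dict = field(default_factory=dict)
    complete: bool = False
    version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "timestamp": self.timestamp,
                "seed": self.seed,
                "complete": self.complete,
                "config": self.config,
                "stages": self.stages,
            },
            indent=2,
            default=str,
        )


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    scenario: str | None = None,
    counts_path: str | Path | None = None,
    meta_path: str | Path | None = None,
    gmt: GeneSetLibrary | None = None,
    seed: int | None = None,
) -> RunReport:
    """Run simulate/load -> DE -> profile clustering -> enrichment/signatures.

    Inputs are either a synthetic scenario name or counts+metadata paths.
    A stage failure aborts the run but still writes a partial report marked
    incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.base_seed
    report = RunReport(config=config.to_dict(), seed=seed)
    report.timestamp = datetime.datetime.now().isoformat()

    try:
        try:
            if scenario is not None:
                sc = default_scenario(scenario, seed=seed)
                cm, metas, truth = generate_counts(sc)
                write_counts(cm, out / "counts.tsv")
                write_meta(metas, out / "meta.tsv")
                truth.to_csv(out / "truth.tsv", sep="\t")
                report.stages["input"] = {
                    "source": f"scenario:{scenario}",
                    "n_genes": cm.n_genes,
                    "n_samples": cm.n_samples,
                }
            elif counts_path is not None and meta_path is not None:
                cm = read_counts(counts_path)
                metas = read_meta(meta_path)
                align_meta(cm, metas)
                report.stages["input"] = {
                    "source": str(counts_path),
                    "n_genes": cm.n_genes,
                    "n_samples": cm.n_samples,
                }
            else:
                raise InputError(
                    "provide either a scenario name or counts+meta paths"
                )
        except Exception as e:  # noqa: BLE001
            raise StageError("input", e) from e

        try:
            de, norm, disp = de_mod.run_de(cm, metas, config)
            deg_summary = {}
            for cname, tab in de.pairwise.items():
                degs = de_mod.call_degs(de, cname, config)
                tab.to_csv(out / f"de_{cname}.tsv", sep="\t")
                degs["enrichment"].to_csv(out / f"degs_{cname}.tsv", sep="\t")
                deg_summary[cname] = {
                    "n_deg_fdr": int(len(degs["fdr_only"])),
                    "n_up": degs["n_up"],
                    "n_down": degs["n_down"],
                    "n_deg_enrichment": int(len(degs["enrichment"])),
                }
            de.interaction.to_csv(out / "interaction.tsv", sep="\t")
            log_expr = de_mod.log_norm_expression(
                CountMatrix(cm.counts.loc[de.gene_ids]), norm
            )
            coords, var_frac = de_mod.pca_embedding(log_expr)
            coords.to_csv(out / "pca.tsv", sep="\t")
            report.stages["de"] = {
                "n_genes_tested": len(de.gene_ids),
                "n_filtered_all_zero": len(de.filtered_genes),
                "common_dispersion": disp.common,
                "tmm_factors": {
                    s: float(f) for s, f in norm.factors.items()
                },
                "deg_counts": deg_summary,
                "pca_variance_fractions": [float(v) for v in var_frac[:4]],
            }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("de", e) from e

        try:
            genes = cl_mod.select_cluster_genes(de, config.cluster_gene_fdr)
            profiles = cl_mod.build_profiles(
                de,
                genes,
                [c.name for c in config.contrasts],
                sd_scope=config.sd_scope,
            )
            profiles.values.to_csv(out / "profiles.tsv", sep="\t")
            ksel, result = cl_mod.select_k(profiles, config, base_seed=seed)
            ksel.table.to_csv(out / "k_selection.tsv", sep="\t", index=False)
            result.assignments.to_csv(out / "clusters.tsv", sep="\t")
            report.stages["clustering"] = {
                "n_genes_clustered": len(genes),
                "k_star": ksel.k_star,
                "selection_rule": ksel.selection_rule,
                "mean_distance_curve": {
                    int(r.k): (None if pd.isna(r.mean_distance) else float(r.mean_distance))
                    for r in ksel.table.itertuples()
                },
            }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("clustering", e) from e

        try:
            primary = config.contrasts[0].name
            panels = en_mod.default_panels()
            gene_tab, panel_tab, missing = en_mod.signature_table(
                de, panels, primary
            )
            gene_tab.to_csv(out / "signature_genes.tsv", sep="\t", index=False)
            panel_tab.to_csv(out / "signature_panels.tsv", sep="\t", index=False)
            volcano = en_mod.volcano_table(de, primary, config)
            volcano.to_csv(out / f"volcano_{primary}.tsv", sep="\t")
            report.stages["signatures"] = {
                "contrast": primary,
                "panels_missing_genes": {k: len(v) for k, v in missing.items()},
                "volcano_counts": volcano["category"].value_counts().to_dict(),
            }
            if gmt is not None:
                degs = de_mod.call_degs(de, primary, config)
                deg_list = list(degs["enrichment"].index)
                if deg_list:
                    enr = en_mod.enrich_library(deg_list, gmt, de.gene_ids)
                    enr.to_csv(out / f"enrichment_{primary}.tsv", sep="\t", index=False)
                    report.stages["enrichment"] = {
                        "contrast": primary,
                        "n_terms_tested": int(len(enr)),
                        "top_terms": enr.head(5)["term"].tolist(),
                    }
                else:
                    report.stages["enrichment"] = {
                        "contrast": primary,
                        "n_terms_tested": 0,
                        "top_terms": [],
                    }
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("signatures", e) from e

        report.complete = True
    finally:
        (out / "report.json").write_text(report.to_json())
    return report
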